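region_id,ie
Aksu,0.70
Aletai,0.62
Bazhou,0.65
Bozhou,0.60
Changji,0.70
Hami,0.66
Hotan,0.72
Kashgar,0.63
Kezhou,0.60
Karamay,0.79
Shihezi,0.71
Tacheng,0.69
Turpan,0.79
Urumqi,0.78
Yili,0.73
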