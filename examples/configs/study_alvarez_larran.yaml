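label: Alvarez-Larran 2016
median_age: 64
burden_pct: 64
follow_up_years: 6.4
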