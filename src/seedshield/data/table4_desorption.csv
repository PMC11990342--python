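biofilm,D_x1e6_mm2_per_day,K_x1e3_per_day,F_x1e5_g_per_day_per_cm2
CB3C-1,1.15,0.79,0.50
CB3C-2,0.76,0.52,2.00
CB3C-3,1.53,1.05,1.73
CB3C-4,0.15,0.10,0.13
CB3C-5,3.82,2.62,3.00
CB3C-6,2.67,1.83,2.00
CB3C-7,1.91,1.31,2.38
CB3C-8,0.76,0.52,2.75
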