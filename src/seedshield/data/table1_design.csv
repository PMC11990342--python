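biofilm,A,B,C,pLD50_SL,pLD50_BP
CB3C-1,-1,-1,-1,4.17,4.26
CB3C-2,1,-1,-1,4.12,4.32
CB3C-3,-1,1,-1,4.12,4.28
CB3C-4,1,1,-1,4.08,4.22
CB3C-5,-1,-1,1,4.56,4.59
CB3C-6,1,-1,1,4.44,4.52
CB3C-7,-1,1,1,4.41,4.50
CB3C-8,1,1,1,4.36,4.51
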