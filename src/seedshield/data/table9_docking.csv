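target,affinity_kcal_per_mol
8Z9Z,-10.3
4F7F,-7.9
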