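zone_code,baseline_16plus
E08000002,144258
E08000003,364549
E08000004,170259
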