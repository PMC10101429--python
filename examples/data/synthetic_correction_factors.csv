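decade,region,factor
1980s,demo-region,1.25
1990s,demo-region,1.15
2000s,demo-region,1.08
2010s,demo-region,1.03
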