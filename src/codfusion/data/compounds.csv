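name,m,nH,l,Mr,alpha_measured
tyrosine,9,11,3,181.189,1.31
phenylalanine,9,11,2,165.19,1.48
tryptophan,11,12,2,204.32,1.42
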