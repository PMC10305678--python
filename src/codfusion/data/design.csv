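id,tyrosine,phenylalanine,tryptophan,cod_printed
1,5,0,2,9.34
2,10,0,4,18.78
3,15,0,6,28.17
4,0,20,2,29.60
5,5,20,0,36.15
6,0,40,4,64.88
7,10,40,0,72.30
8,0,80,6,126.92
9,15,80,0,136.05
10,15,80,6,146.57
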