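# synthetic seed alignment for the RHS profile
# stand-in sequences generated from a random consensus; not from any curated toxin family
>rhs_seed_1
VGNHSERAVYVSEEPMHTTMGVANGNATTAIMPVKFHFLAPSELG
>rhs_seed_2
VWNHSQRAVYVSEEGMHEMMGVANGSVTTAIYNVKSHFLAPSELG
>rhs_seed_3
VGNHSERAVYVSQEPMHTTMGVANGSVTTAIMPVKFHFLAPSELG
>rhs_seed_4
VGNHSERAVYVSEEPMHTTMGVANGSVTTAINPVKPHFLAPSELP
>rhs_seed_5
VGNHSEFACYVSEEPMHTTPGVANGSVTTAIMPVKFHFWAPSELG
>rhs_seed_6
VGNKSERAVAVSEEPMHTTMGVANGSVTTAIMPVKFSFLAPSELG
>rhs_seed_7
VGNHSERAVYVSECPMHTTMGWANGSVTTAIMPVKFHFLAPSELG
>rhs_seed_8
VGNHHERAVYVSEEPMHTTMIVANGSVTTAKMPVKFHFLAPSELG
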