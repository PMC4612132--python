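# synthetic seed alignment for the CPD profile
# stand-in sequences generated from a random consensus; not from any curated toxin family
>cpd_seed_1
AYQALWPTSNEWVYGWSGAKSGDVPANPRGFRFRTNGVKVAIAIA
>cpd_seed_2
AYQALKPTSNELVYGWSGSKNGDVPANPRGFRFEYNGVFVAIAIA
>cpd_seed_3
AYQALKPTSGEQVYGWSGAKAGDVAANGRGFRFETNGVKVAIAIW
>cpd_seed_4
AYQALKPTSNEQVYGWSGAKSGDVPANPRGFRFETNTVKVAIAIA
>cpd_seed_5
AYWALVPTSNEQVYGWSGAKSGDVPANPRGWRFETNGVKVFIAIL
>cpd_seed_6
LYQALKPTSNEQVYIWLGAKSGDVPENPWGGRFETNGVKVAIAIA
>cpd_seed_7
AYQALKPTSNFQVYGWSGAKHGIVPAGPRGFRWLTNGVFVAIAFA
>cpd_seed_8
AYQALEPTSNEQVHKWSGAKSGDVPANPRGFRFFTNGVKVAIAIA
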