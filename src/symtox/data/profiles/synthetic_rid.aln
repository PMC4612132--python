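# synthetic seed alignment for the RID profile
# stand-in sequences generated from a random consensus; not from any curated toxin family
>rid_seed_1
DKLICASNICNKTAAIEDQPMLKCLTVIKKSLNERIYFTSLYISSSLSDN
>rid_seed_2
DKLICASNICNKTAAIEDQPMLKCLTVIKKSLNERIYFTSLYITSSDSDE
>rid_seed_3
DKLICASNICNKKAKIEDQPMLKCLTVCIKSENECIYFTSRYIMSSDSDE
>rid_seed_4
DKLICASNICNKTAAIEDQPMLKCLTVIKKSLNWTIYFFSLYITSSDSDE
>rid_seed_5
DKLICESNICNKTAADEDQIMLKCLTVIKKSLYERIYFTSLYITSSDSDA
>rid_seed_6
DKLLCASNICNKTAAIEDQPMAKCLTRNKKSLNERIYFTSLYITSSDSDE
>rid_seed_7
DKLTCASNIKNKTAAIEDQPMLKCLTVIKKSLNERIYFTSLYITSSDSDE
>rid_seed_8
DKLICASNICNKTAAIEDQPSLKCLTVIDVSLKERIYFTSLYITSSDSDE
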