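# synthetic seed alignment for the ACD profile
# stand-in sequences generated from a random consensus; not from any curated toxin family
>acd_seed_1
AHPLANLRFLNSEVKSVGEDGCFDFLDDVLKLDQRTEYNLTVYLSFCDDG
>acd_seed_2
AEPLACLCFHPSEVKSVGEDGCIDFLDDVLELDQRTEYNLTVYKSFYDDG
>acd_seed_3
MEPLANLRNHKSEVPSVGEDGEIDFLDDSLILDQRTEYNLTVYLSFHDDG
>acd_seed_4
GEPLNNLRFHKSEVKSVGEDGCIDFLDDVKILDQRTEYNLTVYLMFYDDG
>acd_seed_5
ANPLANLRAHYSEVKSVGEHGCIDFLDDVMILDQRTEYNLTVYLSFFDVG
>acd_seed_6
ASPLANLRFVKSEVKSVGEDGCIDFLDDVLILDQRTEYNLTVYLSFYDDG
>acd_seed_7
AEPLANLRFHKSMVKSVGEDGCIDCLDCVLILDQRQEYNLTVYLSFYDDG
>acd_seed_8
AEPLANLRFHNSEDKSVGEDQCIDFLDDVPILDQRTEYNLTVYASFPDDN
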