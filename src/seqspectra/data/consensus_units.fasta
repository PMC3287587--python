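>chr1_head relpos=0.0179-0.0383 repetitions=622.8 unit_nt=21
CTTAACTAACATAGGTCTTAA
>chr1_tail relpos=0.965-0.997 repetitions=994.3 unit_nt=21
AGTTAGTTAAGTTAAGACCTA
>chr2_head relpos=0.0146-0.0223 repetitions=348.2 unit_nt=21
ACTAACTTAGGTCTTAACTTA
>chr2_tail relpos=0.981-0.986 repetitions=264.3 unit_nt=20 short_unit=yes
TTAGTTAAGTTAAGACCTAA
>chr3_head_a relpos=0.0126-0.0236 repetitions=552.2 unit_nt=20 short_unit=yes
GGTCTTACTTCACTAACATA
>chr3_head_b relpos=0.0157-0.0234 repetitions=417.6 unit_nt=21
ATAGGTCTTAACTTAACTAAC
>chr3_head_c relpos=0.0121-0.0283 repetitions=817.5 unit_nt=20 short_unit=yes
TAGGTCTTAATTAACTAACT
>chr3_tail relpos=0.986-0.988 repetitions=78.6 unit_nt=21
TAAGACCTAAGTTAGTGAAGT
>chr4_head relpos=0.0139-0.0221 repetitions=472.4 unit_nt=20 short_unit=yes
AGGTCTTACTTCACTAACTT
>chr4_tail relpos=0.986-0.991 repetitions=238.2 unit_nt=21
TTAGTTAAGTTAAGACCTAAG
>chr5_head relpos=0.0087-0.0129 repetitions=269.8 unit_nt=20 short_unit=yes
ACTAACATAGGTCTTACTTC
>chr6_tail_a relpos=0.977-0.979 repetitions=152.7 unit_nt=20 short_unit=yes
TAAGACCTATGTTAGTAAAG
>chr6_tail_b relpos=0.982-0.990 repetitions=581.6 unit_nt=21
AAAGTTAAGACCTAAGTTAGT
>chr7_tail relpos=0.991-0.999 repetitions=543.8 unit_nt=21
TTAAGACCTAAGTTAGTGAAG
>chr8_head relpos=0.0077-0.0119 repetitions=269.6 unit_nt=20 short_unit=yes
ACTAGGTCTTAACTTAACTA
>chr8_tail relpos=0.988-0.991 repetitions=185.4 unit_nt=20 short_unit=yes
AAGACCTAAGTTAGTAAGTT
>chr9_tail_a relpos=0.978-0.985 repetitions=551.6 unit_nt=20 short_unit=yes
GACCTATGTTAGTAAAGTAA
>chr9_tail_b relpos=0.987-0.993 repetitions=413.4 unit_nt=20 short_unit=yes
TAAGACCTAAGTTAGTGAAG
>chr10_head relpos=0.0073-0.0116 repetitions=344.4 unit_nt=21
TAGGTCTTACTTTAACTAACT
>chr10_tail relpos=0.981-0.990 repetitions=737.5 unit_nt=21
GACCTATATTAGTTAAGTTAA
>chr11_head relpos=0.0072-0.0093 repetitions=202.3 unit_nt=20 short_unit=yes
TTACTAACATAGGTCTTAAC
>chr12_head relpos=0.0049-0.0055 repetitions=67.5 unit_nt=21
TAACTTAGGTCTTAACTTCAC
>chr12_tail relpos=0.991-0.995 repetitions=354.0 unit_nt=21
TATGTTAGTTAAGTTAAGACC
>chr13_head relpos=0.0049-0.0069 repetitions=269.8 unit_nt=20 short_unit=yes
ACTAACATAGGTCTTACTTC
>chr13_tail_a relpos=0.990-0.991 repetitions=192.5 unit_nt=20 short_unit=yes
AGTAAGACCTTAGTTAGTGA
>chr13_tail_b relpos=0.991-0.993 repetitions=345.2 unit_nt=21
GACCTATGTTAGTGAAGTTAA
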