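>kno-let-7
UGAGGUAGUAGGUUGUAUAGUU
>kno-mir-1
UGGAAUGUAAAGAAGUAUGUAU
>kno-mir-305
AUUGUACUUCAUCAGGUGCUCU
>kno-mir-9
UCUUUGGUUAUCUAGCUGUAUG
>kno-mir-34
UGGCAGUGUGGUUAGCUGGUUG
>kno-mir-7
UGGAAGACUAGUGAUUUUGUUG
>kno-mir-8
UAAUACUGUCAGGUAAAGAUGU
>kno-mir-14
UCAGUCUUUUUCUCUCUCCUAU
>kno-mir-2
UAUCACAGCCAUUUUGACGAGU
>kno-mir-252
CUAAGUACUAGUGCCGCAGGAG
>kno-mir-263
AAUGGCACUGGAAGAAUUCACG
>kno-mir-276
UAGGAACUUCAUACCGUGCUCU
>kno-mir-279
UGACUAGAUCCACACUCAUUAA
>kno-mir-92
UAUUGCACUUGUCCCGGCCUGU
>kno-mir-124
UAAGGCACGCGGUGAAUGCCAA
>kno-mir-137
UUAUUGCUUAAGAAUACGCGUA
>kno-mir-184
UGGACGGAGAACUGAUAAGGGC
>kno-mir-210
CUGUGCGUGUGACAGCGGCUGA
>kno-mir-275
UCAGGUACCUGAAGUAGCGCGC
>kno-mir-317
UGAACACAGCUGGUGGUAUCUCAGU
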