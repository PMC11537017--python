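label,or_total,or_step1,or_step2
PWY-6708 ubiquinol-8 biosynthesis -> 4-hydroxyphenylacetate -> chronic gastritis,1.149,1.112,1.214
Odoribacter -> palmitoleate (16:1n7) -> chronic gastritis,1.260,1.128,1.143
Odoribacter -> phosphate/alanine ratio -> chronic gastritis,1.260,1.137,1.153
Coprococcus sp. ART55/1 -> X-12839 -> chronic gastritis,1.125,1.103,1.107
Coprococcus sp. ART55/1 -> phosphate/alanine ratio -> chronic gastritis,1.125,1.092,1.153
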