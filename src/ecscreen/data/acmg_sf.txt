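# ACMG secondary-findings gene list (subset relevant to the bundled panel,
# extensible: one gene symbol per line).
TTN
FLNC
TMEM127
BRCA2
MYH7
KCNQ1
SCN5A
RYR2
LDLR
APOB
PCSK9
BRCA1
MLH1
MSH2
MSH6
PMS2
APC
RET
SDHB
SDHD
TP53
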