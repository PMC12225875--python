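# 27-specimen C. atrox venom survey: region relative to the Continental
# Divide and Western-blot phenotype of MPO1 (detected / weak / undetected).
# Cohort counts are as published (west: 7/8 low or undetected; east: 4/19);
# identifiers of individuals not named in the published text are positional
# placeholders — the association statistic depends only on the counts.
specimen_id	region	mpo1_blot
AZ1	west	weak
AZ2	west	undetected
AZ3	west	undetected
AZ4	west	undetected
AZ5	west	weak
AZ6	west	undetected
AZ7	west	detected
AZ8	west	weak
NM1	east	detected
NM2	east	detected
NM3	east	detected
NM4	east	detected
NM5	east	detected
NM6	east	detected
NM7	east	undetected
TX1	east	detected
TX2	east	detected
TX3	east	detected
TX4	east	undetected
TX5	east	weak
TX6	east	undetected
TX7	east	detected
TX8	east	detected
TX9	east	detected
TX10	east	detected
TX11	east	detected
TX12	east	detected
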