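name	pattern	category	source
STRE	AGGGG	stress	study-reported
ABRE	ACGTG	hormone	study-reported
AE-box	AGAAACAA	growth/light	study-reported
ARE	AAACCA	stress	study-reported
MYB	TAACCA	stress	study-reported
as-1	TGACG	hormone	study-reported
TGACG-motif	TGACG	hormone	study-reported
CGTCA-motif	CGTCA	hormone	curated, not from paper
LTR	CCGAAA	stress	curated, not from paper
MBS	CAACTG	stress	curated, not from paper
WUN-motif	AAATTTCCT	stress	curated, not from paper
ERE	ATTTCAAA	hormone	curated, not from paper
Box4	ATTAAT	growth/light	curated, not from paper
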