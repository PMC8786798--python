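name	iupac_pattern	category	subclass
TE2F2NTPCNA	ATTCCCGC	growth_development
EBOX	CANNTG	growth_development
RYREPEAT4	CATGCAT	growth_development
RAV1AAT	CAACA	growth_development
POLLEN1LEAAT52	AGAAA	growth_development
GT1CONSENSUS	GRWAAW	light
GATA	GATA	light
GBOXLERBCS	MCACGTGGC	light
BOXII	ATAGAA	light
IBOXCORE	GATAA	light
DPBFCOREDCD3	ACACNNG	hormone	abscisic_acid
ARFAT	TGTCTC	hormone	auxin
ARR1	NGATT	hormone	cytokinin
ERELEE4	AWTTCAAA	hormone	ethylene
GARE10OSREP1	TAACAGA	hormone	gibberellin
DRE2COREZMRAB17	ACCGAC	stress	dehydration
ASF1	TGACG	stress	salicylic_acid
BIHD1	TGTCA	stress	disease_resistance
CBFHV	RYCGAC	stress	dehydration
CGCGBOX	VCGCGB	stress	calcium_signaling
GCCCORE	GCCGCC	stress	ethylene_jasmonate
LTRECOREATCOR15	CCGAC	stress	low_temperature
MYBCORE	CNGTTR	stress	drought
MYCCONSENSUS	CANNTG	stress	dehydration_cold
WRKY1	TGACY	stress	pathogen
WBOX	TTGACC	stress	pathogen
TGBOX	AACGTG	stress	jasmonate
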