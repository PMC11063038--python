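# Bundled restriction-enzyme table: common commercial type II endonucleases.
# Columns: name, recognition site (IUPAC, written 5'->3' on the top strand),
# top-strand cut offset measured from the 5' end of the site (AT^TAAT -> 2).
# name	site	cut_offset
AluI	AGCT	2
ApaI	GGGCCC	5
AseI	ATTAAT	2
BamHI	GGATCC	1
BglII	AGATCT	1
ClaI	ATCGAT	2
DraI	TTTAAA	3
EcoRI	GAATTC	1
EcoRV	GATATC	3
HaeIII	GGCC	2
HindIII	AAGCTT	1
HinfI	GANTC	1
HpaII	CCGG	1
KpnI	GGTACC	5
MseI	TTAA	1
NcoI	CCATGG	1
NdeI	CATATG	2
NheI	GCTAGC	1
NotI	GCGGCCGC	2
PstI	CTGCAG	5
PvuII	CAGCTG	3
RsaI	GTAC	2
SacI	GAGCTC	5
SalI	GTCGAC	1
Sau3AI	GATC	0
ScaI	AGTACT	3
SmaI	CCCGGG	3
SpeI	ACTAGT	1
SphI	GCATGC	5
SspI	AATATT	3
TaqI	TCGA	1
XbaI	TCTAGA	1
XhoI	CTCGAG	1
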