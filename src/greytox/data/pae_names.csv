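abbreviation,full_name
DEHP,Bis (2-ethylhexyl) phthalate
BBP,Benzyl butyl phthalate
DBP,Dibutyl phthalate
DIBP,Diisobutyl phthalate
BMPP,Bis (4-methyl-2-pentyl) phthalate
DAP,Diallyl phthalate
DMEP,Bis (2-methoxyethyl) phthalate
DPrP,Dipropyl phthalate
DIPP,Diisopentyl phthalate
DNP,Dinonyl phthalate
DUP,Diundecyl phthalate
DTDP,Ditridecyl phthalate
DEP,Diethyl phthalate
DOP,Dinoctyl phthalate
DMP,Dimethyl phthalate
DIDP,Diisodecyl phthalate
DHXP,Dihexyl phthalate
DIHXP,Diisohexyl phthalate
DPP,Dipentyl phthalate
DINP,Diisononyl phthalate
DIPrP,Diisopropyl phthalate
DIHP,Diheptyl phthalate
DIOP,Di-isooctyl phthalate
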