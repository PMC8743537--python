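cluster_id	role	taxon_rank	taxon_name	parent_order
CP_A	CP	family	Fiersviridae	Norzivirales
CP_B	CP	family	Fiersviridae	Norzivirales
CP_H	CP	family	Fiersviridae	Norzivirales
CP_C	CP	family	Atkinsviridae	Norzivirales
AP205-like	CP	family	Duinviridae	Norzivirales
CP_G	CP	family	Solspiviridae	Norzivirales
CP_E	CP	family	Blumeviridae	Timlovirales
CP_D	CP	family	Steitzviridae	Timlovirales
CP_F	CP	family	Steitzviridae	Timlovirales
RdRP_A	RdRP	order	Norzivirales
RdRP_B	RdRP	order	Timlovirales
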