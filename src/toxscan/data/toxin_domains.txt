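# Illustrative curated toxin (Pfam) accession list, one accession per line.
# Edit or replace to extend the curated set; lines starting with # ignored.
PF01845	CcdB
PF02452	PemK_toxin
PF05016	ParE_toxin
PF01850	PIN
PF06769	YoeB_toxin
PF02661	Fic
PF06414	Zeta_toxin
PF07927	HicA_toxin
PF05973	Gp49
PF13958	ParE-like_toxin
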