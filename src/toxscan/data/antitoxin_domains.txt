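# Illustrative curated antitoxin/immunity (Pfam) accession list.
# Edit or replace to extend the curated set; lines starting with # ignored.
PF02604	PhdYeFM_antitox
PF04221	RelB
PF07362	CcdA
PF05534	HicB
PF04014	MazE_antitoxin
PF09957	VapB_antitoxin
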