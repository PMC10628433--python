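foreign_id	reaction_ids
KEGG:R00086	RHEA:13065
KEGG:R00315	RHEA:11352
EC:2.7.1.1	RHEA:17825
EC:6.3.1.2	RHEA:16169
KEGG:R00112	RHEA:11692
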