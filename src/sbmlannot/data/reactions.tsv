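reaction_id	participants
RHEA:13065	CHEBI:30616|CHEBI:15377|CHEBI:456216|CHEBI:15378|CHEBI:43474
RHEA:11352	CHEBI:30089|CHEBI:30616|CHEBI:22191|CHEBI:456216|CHEBI:15378
RHEA:17825	CHEBI:4167|CHEBI:30616|CHEBI:58225|CHEBI:456216|CHEBI:15378
RHEA:16169	CHEBI:29985|CHEBI:28938|CHEBI:30616|CHEBI:58359|CHEBI:456216|CHEBI:43474|CHEBI:15378
RHEA:11692	CHEBI:16474|CHEBI:15846|CHEBI:18009|CHEBI:16908
RHEA:14280	CHEBI:15377|CHEBI:15378|CHEBI:16234
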