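term_id	name	synonyms	formula
CHEBI:30616	ATP	adenosine 5'-triphosphate|adenosine triphosphate	C10H16N5O13P3
CHEBI:456216	ADP	adenosine 5'-diphosphate|adenosine diphosphate	C10H15N5O10P2
CHEBI:15377	water	H2O|dihydrogen oxide	H2O
CHEBI:15378	hydron	H+|proton	H+
CHEBI:43474	phosphate	hydrogenphosphate|Pi	HPO42-
CHEBI:30089	acetate	CH3COO-|acetate ion	C2H3O2
CHEBI:22191	acetyl phosphate	acetylphosphate|acetyl-P	C2H5O5P
CHEBI:61404	dATP	2'-deoxy-ATP|deoxyadenosine triphosphate	C10H16N5O12P3
CHEBI:16761	AMP	adenosine 5'-monophosphate|adenosine monophosphate	C10H14N5O7P
CHEBI:4167	D-glucose	D(+)-glucose|dextrose|grape sugar	C6H12O6
CHEBI:58225	glucose 6-phosphate	D-glucose 6-phosphate|G6P	C6H11O9P2-
CHEBI:16526	carbon dioxide	CO2|carbonic anhydride	CO2
CHEBI:15379	dioxygen	O2|molecular oxygen	O2
CHEBI:17925	alpha-D-glucose	alpha-D-glucopyranose	C6H12O6
CHEBI:29985	L-glutamate	L-glutamate(1-)|glutamate	C5H8NO4
CHEBI:58359	L-glutamine	glutamine|Gln	C5H10N2O3
CHEBI:15846	NAD(+)	NAD+|nicotinamide adenine dinucleotide	C21H26N7O14P2
CHEBI:16908	NADH	reduced nicotinamide adenine dinucleotide	C21H27N7O14P2
CHEBI:16474	NADPH	reduced nicotinamide adenine dinucleotide phosphate	C21H26N7O17P3
CHEBI:18009	NADP(+)	NADP+	C21H25N7O17P3
CHEBI:16234	hydroxide	OH-|hydroxide ion	HO-
CHEBI:28938	ammonium	NH4+|azanium	H4N+
CHEBI:33019	diphosphate	PPi|pyrophosphate	HP2O73-
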