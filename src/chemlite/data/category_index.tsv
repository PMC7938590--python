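# Reference annotation-category index (frozen snapshot for reproducible builds).
# One row per fingerprint bit.  Columns: bit, top_name, short_name, sub_name.
# Top-category rows have an empty sub_name; subcategory rows repeat their
# top category's names.  Bit positions are contiguous from 0, least
# significant bit first in the hex serialization.
bit	top_name	short_name	sub_name
0	Agrochemical Information	AgroChemInfo
1	Agrochemical Information	AgroChemInfo	Agrochemical Category
2	Agrochemical Information	AgroChemInfo	EPA Pesticide Chemical Code
3	Agrochemical Information	AgroChemInfo	Agrochemical Transformations
4	Agrochemical Information	AgroChemInfo	Reported Fatal Dose
5	Agrochemical Information	AgroChemInfo	Maximum Residue Limits
6	Drug and Medication Information	DrugMedicInfo
7	Drug and Medication Information	DrugMedicInfo	Drug Indication
8	Drug and Medication Information	DrugMedicInfo	Drug Classes
9	Drug and Medication Information	DrugMedicInfo	Therapeutic Uses
10	Drug and Medication Information	DrugMedicInfo	Drug Warnings
11	Food Additives and Ingredients	FoodRelated
12	Food Additives and Ingredients	FoodRelated	Food Additive Classes
13	Food Additives and Ingredients	FoodRelated	Evaluations of the JECFA
14	Food Additives and Ingredients	FoodRelated	Associated Foods
15	Pharmacology and Biochemistry	PharmacoInfo
16	Pharmacology and Biochemistry	PharmacoInfo	Pharmacodynamics
17	Pharmacology and Biochemistry	PharmacoInfo	Absorption, Distribution and Excretion
18	Pharmacology and Biochemistry	PharmacoInfo	Metabolism/Metabolites
19	Pharmacology and Biochemistry	PharmacoInfo	Mechanism of Action
20	Pharmacology and Biochemistry	PharmacoInfo	Human Metabolite Information
21	Safety and Hazards	SafetyInfo
22	Safety and Hazards	SafetyInfo	Hazards Identification
23	Safety and Hazards	SafetyInfo	First Aid Measures
24	Safety and Hazards	SafetyInfo	Exposure Control and Personal Protection
25	Safety and Hazards	SafetyInfo	Regulatory Information
26	Toxicity	ToxicityInfo
27	Toxicity	ToxicityInfo	Toxicological Information
28	Toxicity	ToxicityInfo	Ecological Information
29	Toxicity	ToxicityInfo	Carcinogen Classification
30	Use and Manufacturing	KnownUse
31	Use and Manufacturing	KnownUse	Uses
32	Use and Manufacturing	KnownUse	Methods of Manufacturing
33	Use and Manufacturing	KnownUse	Consumption Patterns
34	Use and Manufacturing	KnownUse	General Manufacturing Information
35	Biomolecular Interactions and Pathways	BioPathway
36	Biomolecular Interactions and Pathways	BioPathway	Pathways
37	Biomolecular Interactions and Pathways	BioPathway	Protein Bound 3D Structures
38	Biomolecular Interactions and Pathways	BioPathway	Chemical-Gene Interactions
39	Biomolecular Interactions and Pathways	BioPathway	Drug-Drug Interactions
40	Identification	Identification
41	Identification	Identification	Analytic Laboratory Methods
42	Identification	Identification	Clinical Laboratory Methods
43	Identification	Identification	GC-MS
44	Associated Disorders and Diseases	DisorderDisease
45	Associated Disorders and Diseases	DisorderDisease	Associated Disorders and Diseases
46	Associated Disorders and Diseases	DisorderDisease	Drug Induced Liver Injury
47	Chemical and Physical Properties	ChemPhysProp
48	Chemical and Physical Properties	ChemPhysProp	Experimental Properties
49	Chemical and Physical Properties	ChemPhysProp	Computed Properties
50	Spectral Information	SpectralInfo
51	Spectral Information	SpectralInfo	Mass Spectrometry
52	Spectral Information	SpectralInfo	NMR Spectra
53	Literature	Literature
54	Literature	Literature	Consolidated References
55	Literature	Literature	NLM Curated PubMed Citations
56	Patents	Patents
57	Patents	Patents	Depositor-Supplied Patent Identifiers
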