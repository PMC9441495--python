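# Example ECS panel: the most prevalent AR genes, the X-linked genes carried
# by women, and the autosomal-dominant secondary-findings genes of a large
# Chinese ART-couple screening programme.  carrier_freq values are the
# observed per-individual carrier fractions; variant spectra are the printed
# hotspot alleles with relative allele shares (a residual allele absorbs the
# unprinted remainder of each spectrum).
# G6PD is X-linked (it is sometimes tabulated with the AR block because its
# carrier frequency is computed over the whole cohort like the AR genes).
symbol	omim_id	disease	inheritance	severity	carrier_freq	variants
GJB2	121011	GJB2-related hearing loss	AR	moderate	0.2017	c.109G>A:P:0.8845:NM_004004.6;c.235delC:P:0.0810:NM_004004.6;c.508_511dup:P:0.0345:NM_004004.6
CFTR	602421	Cystic fibrosis	AR	severe	0.1018	c.1210-11T>G:P:0.7736:NM_000492.4;c.2909G>A:LP:0.2264:NM_000492.4
DUOX2	606759	Thyroid dyshormonogenesis 6	AR	moderate	0.0718	c.1588A>T:P:0.3769:NM_001363711.2;c.2654G>T:P:0.2243:NM_001363711.2;c.3329G>A:LP:0.3988:NM_001363711.2
SERPINB7	603357	Palmoplantar keratoderma nagashima type	AR	mild	0.0374	c.796C>T:P:0.7365:NM_003784.4;c.455-1G>A:P:0.2635:NM_003784.4
IL36RN	605507	Pustular psoriasis generalized	AR	moderate	0.0284	c.115+6T>C:P:0.9921:NM_012275.3;c.227C>T:P:0.0079:NM_012275.3
GALC	606890	Krabbe disease	AR	profound	0.0210	c.1901T>C:P:0.968:NM_000153.4;c.1583A>G:LP:0.032:NM_000153.4
CD36	173510	Platelet glycoprotein IV deficiency	AR	moderate	0.0188	c.329_330delAC:P:1.0:NM_000072.3
HBB	141900	Beta-thalassemia	AR	severe	0.0181	c.126_129delCTTT:P:0.6:NM_000518.5;c.52A>T:P:0.4:NM_000518.5
USH2A	608400	Usher syndrome type 2A	AR	severe	0.0172	c.2802T>G:P:0.55:NM_206933.4;c.8559-2A>G:P:0.45:NM_206933.4
MYORG	618255	Idiopathic basal ganglia calcification-7	AR	moderate	0.0166	c.40dupC:P:1.0:NM_020702.5
C9	120940	Complement component 9 deficiency	AR	mild	0.0157	c.346C>T:P:1.0:NM_001737.5
G6PD	305900	Glucose 6 phosphate dehydrogenase deficiency	XL	mild	0.0090	c.1388G>A:P:0.7:NM_001042351.3;c.1376G>T:P:0.3:NM_001042351.3
DMD	300377	Duchenne muscular dystrophy	XL	profound	0.0022	c.9100C>T:P:1.0:NM_004006.3
CACNA1F	300110	Congenital stationary night blindness type 2A	XL	mild	0.0011	c.2234T>C:P:1.0:NM_005183.4
TTN	188840	Dilated cardiomyopathy-1G	AD	unclassified	0.0058	c.490del:P:1.0:NM_001267550.2
FLNC	102565	Dilated cardiomyopathy	AD	unclassified	0.0011	c.5791C>T:LP:1.0:NM_001458.5
TMEM127	613403	Hereditary paraganglioma-pheochromocytoma syndrome	AD	unclassified	0.0002	c.245G>A:P:1.0:NM_017849.4
BRCA2	600185	Hereditary breast and ovarian cancer	AD	unclassified	0.0002	c.5946del:P:1.0:NM_000059.4
PAX6	607108	Aniridia	AD	unclassified	0.0002	c.718C>T:P:1.0:NM_000280.5
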