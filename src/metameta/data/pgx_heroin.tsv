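gene	variant	association_text	p_value	drugs	significant	phenotype
BDNF	rs16917234	Genotype TT is associated with decreased age at onset of Heroin Dependence due to heroin as compared to genotypes CC + CT.	0.012	heroin	True	Heroin Dependence
BDNF	rs6265	Genotype TT is associated with decreased age at onset of Heroin Dependence due to heroin as compared to genotypes CC + CT.	0.032	heroin	True	Heroin Dependence
DRD1	rs5326	Genotype TT is associated with increased dose of methadone in people with Heroin Dependence as compared to genotypes CC + CT.	0.01	methadone	True	Heroin Dependence
DRD2	rs1076560	Allele A is associated with increased likelihood of Heroin Dependence due to heroin as compared to allele C.	0.021	heroin	True	Heroin Dependence
DRD2	rs12364283	Allele G is associated with increased risk of Heroin Dependence due to heroin as compared to allele A.	8.89E-06	heroin	True	Heroin Dependence
DRD2	rs1799978	Genotype CC is associated with decreased dose of methadone in people with Heroin Dependence as compared to genotype TT.	0.01	methadone	True	Heroin Dependence
DRD2	rs6275	Genotype AA is associated with decreased dose of methadone in people with Heroin Dependence as compared to genotype GG.	0.002	methadone	True	Heroin Dependence
OPRM1	rs10457090	Allele G is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele A.	0.004	cotinine	True	Heroin Dependence
OPRM1	rs1074287	Allele G is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele A.	0.002	cotinine	True	Heroin Dependence
OPRM1	rs12209447	Allele T is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele C.	0.009	cotinine	True	Heroin Dependence
OPRM1	rs1799971	Allele G is associated with increased risk of Heroin Dependence due to heroin as compared to allele A.	0.016	heroin	True	Heroin Dependence
OPRM1	rs2075572	Allele G is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele C.	0.03	cotinine	True	Heroin Dependence
OPRM1	rs3778150	Allele C is associated with increased risk of Heroin Dependence due to heroin as compared to allele T.	4.3E-08	heroin	True	Heroin Dependence
OPRM1	rs3778151	Allele C is associated with increased risk of Heroin Dependence due to heroin as compared to allele T.	2.4E-07	heroin	True	Heroin Dependence
OPRM1	rs3778152	Allele G is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele A.	0.006	cotinine	True	Heroin Dependence
OPRM1	rs3798676	Allele T is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele C.	0.007	cotinine	True	Heroin Dependence
OPRM1	rs3823010	Allele A is associated with increased risk of Heroin Dependence due to heroin as compared to allele G.	2.7E-08	heroin	True	Heroin Dependence
OPRM1	rs495491	Allele G is associated with increased risk of Heroin Dependence due to heroin as compared to allele A.	0.00018	heroin	True	Heroin Dependence
OPRM1	rs510769	Allele T is associated with increased risk of Heroin Dependence due to heroin as compared to allele C.	0.0007	heroin	True	Heroin Dependence
OPRM1	rs511435	Allele T is associated with increased risk of Heroin Dependence due to heroin as compared to allele C.	0.000003	heroin	True	Heroin Dependence
OPRM1	rs524731	Allele A is associated with increased risk of Heroin Dependence due to heroin as compared to allele C.	1.2E-06	heroin	True	Heroin Dependence
OPRM1	rs553202	Allele T is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele C.	0.02	cotinine	True	Heroin Dependence
OPRM1	rs562859	Allele C is associated with increased risk of Heroin Dependence due to heroin as compared to allele T.	0.0043	heroin	True	Heroin Dependence
OPRM1	rs563649	Allele T is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele C.	0.006	cotinine	True	Heroin Dependence
OPRM1	rs589046	Allele T is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele C.	0.001	cotinine	True	Heroin Dependence
OPRM1	rs62638690	Allele T is associated with decreased likelihood of Cocaine-Related Disorders or Heroin Dependence due to cocaine or heroin as compared to allele G.	0.02	cocaine;heroin	True	Heroin Dependence
OPRM1	rs6912029	Allele T is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele G.	0.01	cotinine	True	Heroin Dependence
OPRM1	rs7748401	Allele G is associated with increased concentrations of cotinine in people with Heroin Dependence as compared to allele T.	0.006	cotinine	True	Heroin Dependence
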