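gene_set	category	term	N	B	n	b	fold
met	biological_process	response to stimulus	24410	5797	6216	1688	1.14
met	biological_process	response to chemical stimulus	24410	3325	6216	1011	1.19
met	biological_process	response to abiotic stimulus	24410	2269	6216	711	1.23
met	biological_process	response to abscisic acid stimulus	24410	484	6216	172	1.40
met	biological_process	organ development	24410	363	6216	130	1.41
met	biological_process	drug transmembrane transport	24410	62	6216	32	2.03
met	biological_process	response to ethylene stimulus	24410	300	6216	110	1.44
met	biological_process	response to cadmium ion	24410	393	6216	138	1.38
met	biological_process	response to osmotic stress	24410	678	6216	220	1.27
met	biological_process	response to stress	24410	3386	6216	956	1.11
met	biological_process	response to salt stress	24410	638	6216	206	1.27
met	biological_process	organ morphogenesis	24410	295	6216	104	1.38
met	biological_process	carbohydrate metabolic process	24410	1680	6216	492	1.15
met	biological_process	metal ion transport	24410	507	6216	165	1.28
met	biological_process	regulation of anion channel activity	24410	27	6216	16	2.33
met	biological_process	auxin polar transport	24410	80	6216	35	1.72
met	biological_process	response to red or far red light	24410	336	6216	114	1.33
met	biological_process	monocarboxylic acid metabolic process	24410	1074	6216	321	1.17
met	biological_process	chloroplast organization	24410	186	6216	68	1.44
met	biological_process	protein targeting to membrane	24410	354	6216	118	1.31
met	biological_process	cellular nitrogen compound catabolic process	24410	226	6216	80	1.39
met	biological_process	response to auxin stimulus	24410	355	6216	118	1.31
met	biological_process	cellular protein modification process	24410	2090	6216	595	1.12
met	biological_process	auxin homeostasis	24410	17	6216	11	2.54
met	biological_process	root hair cell differentiation	24410	124	6216	48	1.52
met	biological_process	xylem development	24410	69	6216	30	1.71
met	biological_process	negative regulation of transcription, DNA-dependent	24410	321	6216	107	1.31
met	biological_process	regulation of plant-type hypersensitive response	24410	335	6216	111	1.30
met	molecular_function	acid phosphatase activity	24410	29	6216	21	2.84
met	molecular_function	transmembrane transporter activity	24410	873	6216	286	1.29
met	molecular_function	secondary active transmembrane transporter activity	24410	262	6216	101	1.51
met	molecular_function	flavin adenine dinucleotide binding	24410	144	6216	61	1.66
met	molecular_function	ATP binding	24410	1818	6216	533	1.15
met	molecular_function	secondary active sulfate transmembrane transporter activity	24410	7	6216	7	3.93
met	molecular_function	heme binding	24410	348	6216	118	1.33
met	molecular_function	antiporter activity	24410	136	6216	53	1.53
met	molecular_function	ATPase activity, coupled to transmembrane movement of substances	24410	153	6216	58	1.49
met	molecular_function	inorganic cation transmembrane transporter activity	24410	243	6216	85	1.37
met	molecular_function	UDP-N-acetylmuramate dehydrogenase activity	24410	45	6216	22	1.92
met	molecular_function	water transmembrane transporter activity	24410	22	6216	13	2.32
met	molecular_function	water channel activity	24410	22	6216	13	2.32
unmet	biological_process	response to stimulus	24113	5653	760	234	1.31
unmet	biological_process	raffinose family oligosaccharide biosynthetic process	24113	7	760	5	22.66
unmet	biological_process	respiratory burst involved in defense response	24113	107	760	13	3.85
unmet	biological_process	regulation of meristem structural organization	24113	14	760	5	11.33
unmet	biological_process	negative regulation of gibberellic acid mediated signaling pathway	24113	8	760	4	15.86
unmet	biological_process	monocarboxylic acid metabolic process	24113	1044	760	56	1.70
unmet	biological_process	hyperosmotic salinity response	24113	123	760	13	3.35
unmet	biological_process	carboxylic acid biosynthetic process	24113	945	760	51	1.71
unmet	biological_process	sesquiterpenoid biosynthetic process	24113	32	760	6	5.95
unmet	biological_process	jasmonic acid mediated signaling pathway	24113	237	760	18	2.41
unmet	biological_process	response to water deprivation	24113	324	760	22	2.15
unmet	biological_process	response to auxin stimulus	24113	346	760	23	2.11
unmet	biological_process	response to chitin	24113	368	760	24	2.07
unmet	biological_process	anatomical structure development	24113	1268	760	61	1.53
unmet	biological_process	regulation of defense response	24113	463	760	28	1.92
unmet	biological_process	regulation of cellular biosynthetic process	24113	2249	760	97	1.37
unmet	biological_process	attachment of spindle microtubules to kinetochore	24113	2	760	2	31.73
unmet	molecular_function	binding	24113	9528	760	348	1.16
unmet	molecular_function	nucleic acid binding transcription factor activity	24113	1459	760	70	1.52
unmet	molecular_function	sequence-specific DNA binding transcription factor activity	24113	1459	760	70	1.52
unmet	molecular_function	catalytic activity	24113	7647	760	284	1.18
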