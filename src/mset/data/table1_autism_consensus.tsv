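# Consensus autism genes found among significant postpartum lateral-septum
# expression changes, with the number of independent autism association
# databases (of nine) that list each gene. Only genes appearing in three or
# more databases are included.
symbol	n_databases	gene_name
Foxp2	7	Forkhead box P2
Sez6l2	7	Seizure related 6 homolog like 2
Lamb1	7	Laminin B1
Slc1a1	7	Solute carrier family 1, member 1
Adora2a	6	Adenosine A2a receptor
Gabra4	5	GABA A receptor, subunit alpha 4
Hras1	5	Harvey rat sarcoma virus oncogene 1
Arnt2	5	Aryl hydrocarbon receptor nuclear translocator 2
Lrfn5	4	Leucine rich repeat and fibronectin type III domain containing 5
Scn1a	4	Sodium channel, voltage-gated, type I, alpha
Drd2	4	Dopamine receptor D2
Nostrin	4	Nitric oxide synthase trafficker
Npy	4	Neuropeptide Y
Snrpn	4	Small nuclear ribonucleoprotein N
Fabp5	4	Fatty acid binding protein 5, epidermal
Pcdh10	4	Protocadherin 10
Kcnd2	3	Potassium voltage-gated channel, Shal-related family, member 2
Upp2	3	Uridine phosphorylase 2
Rbfox1	3	RNA binding protein, fox-1 homolog 1
Adra2a	3	Adrenergic receptor, alpha 2a
Cadps2	3	Ca2+-dependent activator protein for secretion 2
Camk2b	3	Calcium/calmodulin-dependent protein kinase II, beta
Csmd3	3	CUB and Sushi multiple domains 3
Drd1a	3	Dopamine receptor D1A
Fabp7	3	Fatty acid binding protein 7, brain
Foxo1	3	Forkhead box O1
Hcrtr1	3	Hypocretin (orexin) receptor 1
Htr5a	3	5-hydroxytryptamine (serotonin) receptor 5A
Mchr1	3	Melanin-concentrating hormone receptor 1
Nr2e1	3	Nuclear receptor subfamily 2, group E, member 1
Oprk1	3	Opioid receptor, kappa 1
Pde4b	3	Phosphodiesterase 4B, cAMP specific
Ppp1r1b	3	Protein phosphatase 1, regulatory subunit 1B
Rarb	3	Retinoic acid receptor, beta
Robo2	3	Roundabout homolog 2
Tac1	3	Tachykinin 1
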