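pathway_id	name	gene_id
glycolysis	Glycolysis (Embden-Meyerhof)	K00844
glycolysis	Glycolysis (Embden-Meyerhof)	K01810
glycolysis	Glycolysis (Embden-Meyerhof)	K00850
glycolysis	Glycolysis (Embden-Meyerhof)	K01623
glycolysis	Glycolysis (Embden-Meyerhof)	K01803
glycolysis	Glycolysis (Embden-Meyerhof)	K00134
glycolysis	Glycolysis (Embden-Meyerhof)	K00927
glycolysis	Glycolysis (Embden-Meyerhof)	K01834
glycolysis	Glycolysis (Embden-Meyerhof)	K01689
glycolysis	Glycolysis (Embden-Meyerhof)	K00873
tca_cycle	Citrate (TCA) cycle	K01647
tca_cycle	Citrate (TCA) cycle	K01681
tca_cycle	Citrate (TCA) cycle	K00031
tca_cycle	Citrate (TCA) cycle	K00164
tca_cycle	Citrate (TCA) cycle	K01902
tca_cycle	Citrate (TCA) cycle	K00234
tca_cycle	Citrate (TCA) cycle	K01679
tca_cycle	Citrate (TCA) cycle	K00024
nitrate_respiration	Dissimilatory nitrate reduction (narGHI)	K00370
nitrate_respiration	Dissimilatory nitrate reduction (narGHI)	K00371
nitrate_respiration	Dissimilatory nitrate reduction (narGHI)	K00374
nitrite_reduction	Nitrite reduction to ammonium (nirBD)	K00362
nitrite_reduction	Nitrite reduction to ammonium (nirBD)	K00363
nitrous_oxide_respiration	Nitrous-oxide reduction (nosZ)	K00376
thiamine_biosynthesis	Thiamine biosynthesis	K03148
thiamine_biosynthesis	Thiamine biosynthesis	K03149
thiamine_biosynthesis	Thiamine biosynthesis	K00941
thiamine_biosynthesis	Thiamine biosynthesis	K00788
thiamine_biosynthesis	Thiamine biosynthesis	K00878
riboflavin_biosynthesis	Riboflavin biosynthesis	K01497
riboflavin_biosynthesis	Riboflavin biosynthesis	K11752
riboflavin_biosynthesis	Riboflavin biosynthesis	K00794
riboflavin_biosynthesis	Riboflavin biosynthesis	K00793
niacin_biosynthesis	NAD (niacin) biosynthesis	K03517
niacin_biosynthesis	NAD (niacin) biosynthesis	K00278
niacin_biosynthesis	NAD (niacin) biosynthesis	K00767
pantothenate_biosynthesis	Pantothenate biosynthesis	K00606
pantothenate_biosynthesis	Pantothenate biosynthesis	K01918
pantothenate_biosynthesis	Pantothenate biosynthesis	K00077
folate_biosynthesis	Folate biosynthesis	K01495
folate_biosynthesis	Folate biosynthesis	K01633
folate_biosynthesis	Folate biosynthesis	K00796
folate_biosynthesis	Folate biosynthesis	K00287
nife_hydrogenase	NiFe hydrogenase (group 1)	K06281
nife_hydrogenase	NiFe hydrogenase (group 1)	K06282
assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00958
assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00860
assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00390
assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00380
assimilatory_sulfate_reduction	Assimilatory sulfate reduction	K00381
trehalose_biosynthesis	Trehalose biosynthesis (otsAB)	K00697
trehalose_biosynthesis	Trehalose biosynthesis (otsAB)	K01087
co_dehydrogenase	Aerobic CO dehydrogenase (coxLMS)	K03520
co_dehydrogenase	Aerobic CO dehydrogenase (coxLMS)	K03519
co_dehydrogenase	Aerobic CO dehydrogenase (coxLMS)	K03518
urease	Urease (ureABC)	K01428
urease	Urease (ureABC)	K01429
urease	Urease (ureABC)	K01430
metal_resistance	Metal resistance (copA/czcA efflux)	K17686
metal_resistance	Metal resistance (copA/czcA efflux)	K15726
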