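code	name	aliases
ADP1	Citrus maxima	Madhukarkati
ADP2	Morus alba	Tuda|Tooda
ADP3	Abelmoschus moschatus	Latakasturikam
ADP4	Allium sativum	Lasuna
ADP5	Cyamopsis tetragonoloba	Bakuchi
ADP6	Hydnocarpus wightiana	Tuvaraka
ADP7	Salacia reticulata	Vairi
ADP8	Tinospora malabarica	Gulvel sattva
ADP9	Zanthoxylum armatum	Tejasvini
ADP10	Achyranthes aspera	Apamarga
ADP11	Cajanus cajan	Adhaki
ADP12	Nelumbo nucifera	Padma
ADP13	Withania somnifera	Ashwagandha
ADP14	Perilla frutescens	Ajeka
ADP15	Phaseolus vulgaris	Mudga
ADP16	Phyllanthus niruri var. amarus	Bhumyamalaki
ADP17	Cullen corylifolium	Bakuchi
ADP18	Salacia oblonga	Saptarangi
ADP19	Sesamum orientale	Snehaphala
ADP20	Swertia chirayita	Anaryatikta
ADP21	Syzygium cumini	Jambu
ADP22	Vigna mungo var. silvestris	Mashaparni
ADP23	Zingiber officinale	Ardraka
ADP24	Trigonella foenum-graecum	Medhika
ADP25	Eclipta prostrata	Bhringaraj
ADP26	Aegle marmelos	Bilva
ADP27	Syzygium cumini var. cumini	Jambu
ADP28	Casearia esculenta	Saptchakra
ADP29	Avena sativa	Jai|Yavika
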