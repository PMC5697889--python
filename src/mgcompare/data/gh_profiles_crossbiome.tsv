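# Published relative weighted GH-family profiles (percent of lignocellulolytic
# GH coverage) for lignocellulose-degrading microbiomes: koala feces, wombat
# feces, wallaby foregut, cow rumen, termite hindgut and switchgrass-adapted
# compost.  Values are printed at 1-decimal precision; the literature columns
# are shipped as constants for cross-biome comparison tables.
family	koala	wombat	wallaby_foregut	cow_rumen	termite_hindgut	compost
GH5	6.9	7.5	3.7	1.0	13.9	3.2
GH6	0.0	0.0	0.0	0.0	0.0	2.1
GH7	0.0	0.0	0.0	0.0	0.0	0.1
GH9	1.5	4.3	0.0	0.9	4.3	4.3
GH44	0.5	0.2	0.0	0.0	0.8	0.4
GH45	0.0	0.0	0.0	0.0	0.6	0.0
GH48	0.0	0.3	0.0	0.0	0.0	0.5
GH8	0.5	1.1	0.4	0.5	2.7	0.5
GH10	1.4	3.6	4.1	1.0	9.9	8.9
GH11	0.0	2.9	0.0	0.1	1.9	1.4
GH12	0.0	0.0	0.0	0.0	0.0	0.6
GH26	3.0	2.7	1.9	0.8	2.0	1.5
GH28	4.6	4.4	0.7	0.6	1.4	0.9
GH53	2.2	0.9	3.3	2.7	2.2	0.2
GH16	2.5	4.5	1.5	0.1	0.6	2.0
GH17	0.0	0.1	0.0	0.0	0.0	0.1
GH51	4.5	2.7	4.5	9.9	2.0	7.8
GH54	0.0	0.1	0.0	0.2	0.0	0.0
GH62	0.0	0.0	0.0	0.0	0.0	1.7
GH67	0.2	0.5	1.9	0.0	3.3	3.6
GH74	1.0	2.6	0.4	0.0	0.7	1.6
GH78	5.4	4.3	9.3	5.1	0.8	8.1
GH81	0.0	0.0	0.0	0.0	0.0	0.3
GH1	1.8	0.8	22.7	1.8	2.5	9.2
GH2	19.7	16.8	8.9	28.5	13.6	8.6
GH3	18.7	13.1	26.8	26.6	15.5	12.2
GH29	3.3	6.3	0.7	4.2	1.2	2.1
GH35	1.2	1.3	1.1	1.9	0.6	0.6
GH38	0.9	1.9	1.1	2.6	4.2	2.6
GH39	0.9	1.1	0.4	0.3	1.5	1.0
GH42	0.8	1.1	3.0	1.9	6.9	2.5
GH43	18.5	14.8	3.7	9.3	6.6	11.3
GH52	0.0	0.0	0.0	0.0	0.3	0.0
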