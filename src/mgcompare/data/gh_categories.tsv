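# Glycoside hydrolase families implicated in lignocellulose degradation,
# grouped by their role in the process: cellulases cleave beta-1,4 linkages in
# cellulose; endohemicellulases attack the hemicellulose backbone; accessory
# hemicellulases remove side chains; oligosaccharide-degrading enzymes act on
# the soluble products of both.
family	category	known_activity
GH5	cellulase	cellulose
GH6	cellulase	endoglucanase
GH7	cellulase	endoglucanase
GH9	cellulase	endoglucanase
GH44	cellulase	endoglucanase
GH45	cellulase	endoglucanase
GH48	cellulase	endo-processive cellulases
GH8	endohemicellulase	endo-xylanases
GH10	endohemicellulase	endo-1,4-beta-xylanase
GH11	endohemicellulase	xylanase
GH12	endohemicellulase	endoglucanase & xyloglucan hydrolysis
GH26	endohemicellulase	beta-mannanase & xylanase
GH28	endohemicellulase	galacturonases
GH53	endohemicellulase	endo-1,4-beta-galactanase
GH16	accessory_hemicellulase	xyloglucanases & xyloglycosyltransferases
GH17	accessory_hemicellulase	1,3-beta-glucosidases
GH51	accessory_hemicellulase	alpha-L-arabinofuranosidase
GH54	accessory_hemicellulase	alpha-L-arabinofuranosidase
GH62	accessory_hemicellulase	alpha-L-arabinofuranosidase
GH67	accessory_hemicellulase	alpha-glucuronidase
GH74	accessory_hemicellulase	endoglucanases & xyloglucanases
GH78	accessory_hemicellulase	alpha-L-rhamnosidase
GH81	accessory_hemicellulase	1,3-beta-glucanase
GH1	oligosaccharide_degrading	beta-glucosidase & other beta-linked dimers
GH2	oligosaccharide_degrading	beta-galactosidases & other beta-linked dimers
GH3	oligosaccharide_degrading	mainly beta-glucosidases
GH29	oligosaccharide_degrading	alpha-L-fucosidase
GH35	oligosaccharide_degrading	beta-galactosidase
GH38	oligosaccharide_degrading	alpha-mannosidase
GH39	oligosaccharide_degrading	beta-xylosidase
GH42	oligosaccharide_degrading	beta-galactosidase
GH43	oligosaccharide_degrading	arabinases & xylosidases
GH52	oligosaccharide_degrading	beta-xylosidase
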