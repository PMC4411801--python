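# Default include list of glycoside hydrolase (GH) families with direct
# polysaccharide-degradation activity (cellulases, hemicellulases,
# chitinases, amylases, fucosidases ...). Editable; real-data analyses
# should supply a list matched to their annotation source.
# family	typical activities
GH1	beta-glucosidase / beta-galactosidase
GH2	beta-galactosidase / beta-mannosidase
GH3	beta-glucosidase / xylosidase
GH4	alpha-glucosidase / alpha-galactosidase
GH5	cellulase / endoglucanase
GH8	endoglucanase / chitosanase
GH9	endoglucanase
GH10	endo-xylanase
GH11	endo-xylanase
GH13	alpha-amylase
GH16	beta-glucanase / laminarinase
GH18	chitinase
GH26	beta-mannanase
GH29	alpha-L-fucosidase
GH30	glucuronoxylanase
GH31	alpha-glucosidase
GH32	invertase / levanase
GH35	beta-galactosidase
GH36	alpha-galactosidase
GH38	alpha-mannosidase
GH39	beta-xylosidase
GH42	beta-galactosidase
GH43	arabinanase / xylosidase
GH51	alpha-L-arabinofuranosidase
GH53	endo-galactanase
GH57	alpha-amylase
GH74	xyloglucanase
GH77	amylomaltase
GH78	alpha-L-rhamnosidase
GH92	alpha-mannosidase
GH95	alpha-L-fucosidase
GH106	alpha-L-rhamnosidase
GH113	beta-mannanase
GH115	xylan alpha-glucuronidase
GH130	beta-1,4-mannooligosaccharide phosphorylase
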