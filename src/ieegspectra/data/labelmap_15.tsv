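fine_label	coarse_label
rostralanteriorcingulate	a & p cingul
caudalanteriorcingulate	a & p cingul
posteriorcingulate	a & p cingul
superiorfrontal	sup frontal
rostralmiddlefrontal	mid frontal
caudalmiddlefrontal	mid frontal
lateralorbitofrontal	orb frontal
medialorbitofrontal	orb frontal
parsopercularis	inf frontal
parsorbitalis	inf frontal
parstriangularis	inf frontal
precentral	precentral
paracentral	precentral
postcentral	postcentral
isthmuscingulate	isth cingul
inferiorparietal	pari, prec & sup
superiorparietal	pari, prec & sup
precuneus	pari, prec & sup
supramarginal	pari, prec & sup
superiortemporal	temp & fusi
middletemporal	temp & fusi
inferiortemporal	temp & fusi
transversetemporal	temp & fusi
fusiform	temp & fusi
entorhinal	temp & fusi
parahippocampal	temp & fusi
lingual	ling & perical
pericalcarine	ling & perical
lateraloccipital	occipital
cuneus	occipital
hippocampus	hipp & amy
amygdala	hipp & amy
caudate	striatum
putamen	striatum
insula	insula
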