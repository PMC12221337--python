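ko	family	module
K00370	narG/H	denitrification
K00371	narG/H	denitrification
K02567	napA/B	denitrification
K02568	napA/B	denitrification
K15864	nirS/K	denitrification
K00368	nirS/K	denitrification
K04561	norB/C	denitrification
K02305	norB/C	denitrification
K00376	nosZ	denitrification
K00362	nirB/D	dissimilatory_nitrate_reduction
K00363	nirB/D	dissimilatory_nitrate_reduction
K03385	nrfA	dissimilatory_nitrate_reduction
K15876	nrfH	dissimilatory_nitrate_reduction
K02586	nifD/H/K	nitrogen_fixation
K02588	nifD/H/K	nitrogen_fixation
K02591	nifD/H/K	nitrogen_fixation
K10535	hao	nitrification
K10944	amoA/B/C-pmoA/B/C	nitrification
K10945	amoA/B/C-pmoA/B/C	nitrification
K10946	amoA/B/C-pmoA/B/C	nitrification
K20935	hdh	anammox
K00372	nasA/B	assimilatory_nitrate_reduction
K00360	nasA/B	assimilatory_nitrate_reduction
K00367	narB	assimilatory_nitrate_reduction
K00366	nirA	assimilatory_nitrate_reduction
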