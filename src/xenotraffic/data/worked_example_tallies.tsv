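# Printed region/direction tallies of the published analysis (worked example)
n_candidates	17379
n_HA_exclusive	14810
n_HA_containing	2569
n_HA_CD_not_HC	166
n_CD_to_HC	7496
n_HC_to_CD	2370
n_ambiguous	2931
n_unassigned	4582
n_in_HI_CD_origin	7437
n_in_HI_HA_origin	1917
n_unigenes_HC_dest	77615
n_unigenes_CD_source	54721
n_unigenes_HC_source	70119
n_unigenes_CD_dest	57091
orthogroup_missing_total	1720
orthogroup_shared_missing	926
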