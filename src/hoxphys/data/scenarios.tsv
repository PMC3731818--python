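# packaged manipulation scenarios for the mouse HoxD cluster
# each anterior deletion names the elasticity profile that realizes its case
scenario_id	kind	region	probe	profile_ref	removes_fixed_end	includes_evx2_boundary	expected_verdict	expected_secondary
del_8_10	deletion	8-10	11	uniform	0	0	UNCHANGED
del_i_8_10	deletion	i-8-10	11	stiff_deleted_block	0	0	ANTERIORIZED_WITH_GAIN
del_10_12	deletion	10-12	13	uniform	0	0	UNCHANGED
del_9_12	deletion	9-12	13	posterior_stiff_belt	0	0	SILENCED
posterior_deletion	deletion	12-13	11		0	0	POSTERIORIZED_DELAYED
posterior_duplication	duplication	11-13	10		0	0	ANTERIORIZED	DOWNREGULATED
fixed_end_split	split_inversion		9		1	0	ANTERIORIZED
del_i	deletion	i	11	stiff_region_i	0	0	ANTERIORIZED
anchor_sparing_inversion	split_inversion		13		0	0	UNCHANGED
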