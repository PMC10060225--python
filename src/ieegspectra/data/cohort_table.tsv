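subject	n_depth_electrodes	n_bipolar_channels	baseline_duration_s	ketamine_duration_s	propofol_duration_s
1	10	55	366	840
2	11	57	370	739	164
3	12	68	341	705	235
4	10	60	307	850
5	14	77	201	840	57
6	9	65	300	840	402
7	10	104	300	840	50
8	9	102	300	840
9	11	121	300	840	235
10	10	115	300	840	445
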