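sample	sampling_locality	q1	q2	localities	assignment_probs	f0	smp	fc
B1	China	0.564	0.436	Russia	0.831	0.995	0.09	MS
B2	China	0.436	0.564	China	0.981	0.452	0.041	-
B3	China	0.461	0.539	China/Russia	0.936/0.849	0.453	0.048	-
B4	China	0.488	0.512	China/Russia	0.541/0.485	0.451	0.047	-
B5	China	0.429	0.571	China/Russia	0.971/0.942	0.451	0.042	-
B6	China	0.423	0.577	China/Russia	0.922/0.993	0.962	0.053	MU/MS
B7	China	0.585	0.415	China	0.022	0.453	0.117	-
B8	China	0.435	0.565	China	0.992	0.453	0.04	-
B9	China	0.442	0.558	China/Russia	0.956/0.932	0.455	0.047	-
B10	China	0.558	0.442	China/Russia	0.455/0.417	0.453	0.052	-
B11	China	0.424	0.576	China	0.957	0.452	0.036	-
B12	China	0.435	0.565	China	0.990	0.432	0.038	-
B13	China	0.461	0.539	China	0.982	0.452	0.04	-
B14	China	0.467	0.533	China	0.964	0.452	0.044	-
B15	China	0.566	0.434	China	0.232	0.452	0.067	-
B16	Russia	0.431	0.569	Russia	0.772	0.924	0.055	-
B17	Russia	0.431	0.569	China/Russia	0.863/0.940	0.951	0.077	MS/MU
B18	Russia	0.438	0.562	Russia	0.996	0.361	0.055	-
B19	Russia	0.571	0.429	Russia	0.927	0.347	0.041	-
B20	Russia	0.577	0.423	Russia	0.928	0.341	0.041	-
B21	Russia	0.544	0.456	Russia	0.713	0.343	0.037	-
B22	Russia	0.576	0.424	Russia	0.405	0.379	0.041	-
B23	Russia	0.547	0.453	Russia	0.862	0.375	0.054	-
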