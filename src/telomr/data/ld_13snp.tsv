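rsid	rs10936599	rs2293607	rs2736100	rs7675998	rs9420907	rs4387287	rs2487999	rs8105767	rs755017	rs11125529	rs6772228	rs3027234	rs412658
rs10936599	1.0	0.45	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs2293607	0.45	1.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs2736100	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs7675998	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs9420907	0.0	0.0	0.0	0.0	1.0	0.25	0.16	0.0	0.0	0.0	0.0	0.0	0.0
rs4387287	0.0	0.0	0.0	0.0	0.25	1.0	0.09	0.0	0.0	0.0	0.0	0.0	0.0
rs2487999	0.0	0.0	0.0	0.0	0.16	0.09	1.0	0.0	0.0	0.0	0.0	0.0	0.0
rs8105767	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.2
rs755017	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0
rs11125529	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0
rs6772228	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0
rs3027234	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0
rs412658	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.2	0.0	0.0	0.0	0.0	1.0
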