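species	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10	p11	p12	p13	p14	p15	unknown_peaks_rt
Cortinarius cinnamomeus	trace	0	0	trace	0	main	0	trace	0	main	main	main	0	main	main
Cortinarius cistoadelphus	0	0	0	trace	0	main	main	main	0	0	0	0	main	0	0
Cortinarius fervidus	main	0	0	trace	0	main	main	main	0	0	main	main	0	0	main
Cortinarius hadrocroceus	0	0	0	trace	trace	0	0	trace	0	0	main	0	0	0	trace
Cortinarius holoxanthus	0	0	0	trace	main	0	0	trace	main	trace	main	0	0	trace	main
Cortinarius huronensis	0	trace	main	trace	trace	0	0	trace	trace	0	main	0	0	0	main
Cortinarius malicorius	main	0	0	trace	0	main	0	main	trace	trace	main	main	0	0	main
Cortinarius ominosus	0	0	0	main	0	main	main	main	main	0	0	0	trace	0	0	5.5
Cortinarius pellstonianus	0	0	0	0	0	main	trace	main	main	0	main	main	0	main	trace
Cortinarius purpureus	0	0	0	0	0	main	main	main	main	0	0	0	trace	0	0
Cortinarius rubrophyllus	main	0	0	trace	0	main	0	trace	0	trace	main	trace	main	0	main
Cortinarius salignus	0	0	0	trace	trace	0	trace	main	trace	0	main	0	trace	0	main
Cortinarius sanguineus	main	0	0	0	0	main	main	trace	trace	0	0	main	trace	0	0
Cortinarius sphagnogenus	0	0	trace	main	trace	main	main	main	0	main	0	0	main	0	0
Cortinarius vitiosus	0	0	0	trace	0	main	main	main	trace	0	0	0	trace	trace	trace
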