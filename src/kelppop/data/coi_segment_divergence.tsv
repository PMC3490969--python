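comparison	group	dxy_5prime	se_5prime	dxy_3prime	se_3prime	dxy_full	se_full
S. latissima - S. coriacea	saccharina	0.0141	0.0049	0.1488	0.0135	0.0774	0.0081
S. latissima - SHA	saccharina	0.0106	0.0042	0.1508	0.0136	0.0765	0.0080
S. latissima - TYP	saccharina	0.0528	0.0091	0.1647	0.0138	0.1054	0.0093
S. latissima - S. japonica	saccharina	0.0528	0.0091	0.1647	0.0138	0.1054	0.0093
S. latissima - S. angustata	saccharina	0.0599	0.0100	0.1607	0.0138	0.1073	0.0094
S. latissima - Laminaria digitata	laminariales	0.0915	0.0115	0.1488	0.0143	0.1185	0.0101
S. latissima - Agarum clathratum	laminariales	0.0951	0.0115	0.1607	0.0146	0.1259	0.0101
S. latissima - Ecklonia radiata	laminariales	0.1039	0.0120	0.1548	0.0140	0.1278	0.0103
S. latissima - Alaria esculenta	laminariales	0.0951	0.0118	0.1508	0.0137	0.1213	0.0097
S. latissima - Undaria pinnatifida	laminariales	0.1197	0.0130	0.1429	0.0142	0.1306	0.0103
S. latissima - Leathesia difformis	ectocarpales_similar	0.1655	0.0144	0.1290	0.0134	0.1483	0.0110
S. latissima - Asperococcus bullosus	ectocarpales_similar	0.1532	0.0143	0.1349	0.0138	0.1446	0.0104
S. latissima - Punctaria latifolia	ectocarpales_similar	0.1602	0.0143	0.1349	0.0138	0.1483	0.0110
S. latissima - Elachista fucicola	ectocarpales_similar	0.1989	0.0166	0.1627	0.0142	0.1819	0.0115
S. latissima - Hincksia granulosa	ectocarpales_similar	0.1549	0.0144	0.1290	0.0131	0.1427	0.0109
S. latissima - Scytosiphon lomentaria	ectocarpales_similar	0.1637	0.0148	0.1349	0.0136	0.1502	0.0110
S. latissima - Petalonia fascia	ectocarpales_similar	0.1532	0.0145	0.1468	0.0137	0.1502	0.0109
S. latissima - Colpomenia peregrina	ectocarpales_other	0.1495	0.0138	0.1468	0.0144	0.1483	0.0107
S. latissima - Ectocarpus siliculosus	ectocarpales_other	0.1373	0.0139	0.1627	0.0143	0.1493	0.0109
S. latissima - Pylaiella littoralis	ectocarpales_other	0.1585	0.0143	0.1607	0.0144	0.1595	0.0113
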