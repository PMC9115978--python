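breed	group	1-5	5-10	10-20	20-40	>40
YZ	AHIP	218	145	58	19	3
WNHZ	AHIP	512	425	164	43	2
HZ	AHIP	506	370	181	32	1
WNHUAZ	AHIP	727	391	160	40	1
LB	AHIP	296	157	71	31	2
LAN	WECP	1177	691	218	33	0
DUR	WECP	743	349	96	12	1
PIE	WECP	1153	591	133	21	0
LWY	WECP	1085	439	113	14	0
BER	WECP	1167	701	188	49	1
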