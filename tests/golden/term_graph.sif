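TERM0008	tg	G000008
TERM0008	tg	G000014
TERM0008	tg	G000017
TERM0008	tg	G000021
TERM0008	tg	G000036
TERM0008	tg	G000037
TERM0008	tg	G000049
TERM0008	tg	G000061
TERM0008	tg	G000062
TERM0019	tg	G000001
TERM0019	tg	G000005
TERM0019	tg	G000008
TERM0019	tg	G000023
TERM0019	tg	G000027
TERM0019	tg	G000032
TERM0019	tg	G000037
TERM0019	tg	G000051
TERM0019	tg	G000053
TERM0019	tg	G000059
TERM0019	tg	G000062
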