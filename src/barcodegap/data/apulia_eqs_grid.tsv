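site_id	season	database	eqs_class
1a	fall	morphological	Moderate
1a	fall	reduced	Poor
1a	spring	morphological	Poor
1a	spring	reduced	Poor
1b	fall	morphological	Poor
1b	fall	reduced	Bad
1b	spring	morphological	Moderate
1b	spring	reduced	Moderate
1c	fall	morphological	Moderate
1c	fall	reduced	Moderate
1c	spring	morphological	Poor
1c	spring	reduced	Poor
2a	fall	morphological	Poor
2a	fall	reduced	Poor
2a	spring	morphological	Good
2a	spring	reduced	Good
2b	fall	morphological	Moderate
2b	fall	reduced	Poor
2b	spring	morphological	Poor
2b	spring	reduced	Poor
2c	fall	morphological	Bad
2c	fall	reduced	Bad
2c	spring	morphological	Good
2c	spring	reduced	Moderate
3	fall	morphological	Bad
3	fall	reduced	Bad
3	spring	morphological	Bad
3	spring	reduced	Bad
4	fall	morphological	Poor
4	fall	reduced	Poor
4	spring	morphological	Bad
4	spring	reduced	Bad
5	fall	morphological	Bad
5	fall	reduced	Bad
5	spring	morphological	Bad
5	spring	reduced	Bad
6	fall	morphological	Bad
6	fall	reduced	Bad
6	spring	morphological	Bad
6	spring	reduced	Bad
7a	fall	morphological	Bad
7a	fall	reduced	Bad
7a	spring	morphological	Bad
7a	spring	reduced	Bad
7b	fall	morphological	Poor
7b	fall	reduced	Poor
7b	spring	morphological	Moderate
7b	spring	reduced	Moderate
8	fall	morphological	Moderate
8	fall	reduced	Bad
8	spring	morphological	Moderate
8	spring	reduced	Moderate
9	fall	morphological	Poor
9	fall	reduced	Moderate
9	spring	morphological	Moderate
9	spring	reduced	Poor
10	fall	morphological	High
10	fall	reduced	High
10	spring	morphological	Good
10	spring	reduced	Moderate
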