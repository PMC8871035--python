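# Coating weights (mg/m2) by chemical procedure, top center side (TCS).
# ALAF industry (Tanzania) galvanized iron sheets; 72 observations.
36.8
47.2
35.6
36.7
55.8
58.7
42.3
37.8
55.4
45.2
31.8
48.3
45.3
48.5
52.8
45.4
49.8
48.2
54.5
50.1
48.4
44.2
41.2
47.2
39.1
40.7
40.3
41.2
30.4
42.8
38.9
34.0
33.2
56.8
52.6
40.5
40.6
45.8
58.9
28.7
37.3
36.8
40.2
58.2
59.2
42.8
46.3
61.2
58.4
38.5
34.2
41.3
42.6
43.1
42.3
54.2
44.9
42.8
47.1
38.9
42.8
29.4
32.7
40.1
33.2
31.6
36.2
33.6
32.9
34.5
33.7
39.9
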