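# Coating weights (mg/m2) by chemical procedure, bottom center side (BCS).
# ALAF industry (Tanzania) galvanized iron sheets; 72 observations.
45.5
37.5
44.3
43.6
47.1
52.9
53.6
42.9
40.6
34.1
42.6
38.9
35.2
40.8
41.8
49.3
38.2
48.2
44.0
30.4
62.3
39.5
39.6
32.8
48.1
56.0
47.9
39.6
44.0
30.9
36.6
40.2
50.3
34.3
54.6
52.7
44.2
38.9
31.5
39.6
43.9
41.8
42.8
33.8
40.2
41.8
39.6
24.8
28.9
54.1
44.1
52.7
51.5
54.2
53.1
43.9
40.8
55.9
57.2
58.9
40.8
44.7
52.4
43.8
44.2
40.7
44.0
46.3
41.9
43.6
44.9
53.6
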