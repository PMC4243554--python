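wga,ltv_p3_ms,ltv_p10_ms,ltv_expected_ms,ltv_sd_ms
21,57.836,58.228,35.956,1.976
22,57.861,58.256,36.332,2.233
23,58.498,59.303,36.996,2.122
24,58.925,60.217,38.091,2.454
25,60.034,61.333,39.61,2.833
26,61.406,62.774,41.159,2.132
27,62.496,64.367,42.408,2.145
28,65.91,66.833,43.211,1.873
29,67.487,68.584,44.963,2.4
30,68.424,70.954,46.636,2.851
31,74.501,74.786,48.875,2.768
32,74.517,75.451,49.856,2.764
33,75.794,78.193,51.089,2.727
34,75.897,79.025,52.665,3.412
35,81.242,84.719,55.071,3.256
36,87.117,88.57,56.772,2.61
37,88.217,90.655,57.348,2.437
38,90.613,90.763,57.875,2.411
39,90.732,91.028,58.789,2.654
40,91.079,92.474,59.544,2.476
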