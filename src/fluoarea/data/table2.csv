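distance_cm,area_mm2
48.5,923.48
49.5,989.25
50.5,1055.03
51.5,1120.80
52.5,1186.57
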