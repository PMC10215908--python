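distance_cm,area_mm2,pixels
50,50,2127
50,100,3846
50,200,"10,547"
50,400,"14,263"
50,450,"15,480"
50,800,"28,019"
50,900,"31,204"
50,1600,"57,437"
75,50,736
75,100,1334
75,200,2672
75,400,5220
75,450,5579
75,800,"10,309"
75,900,"11,978"
75,1600,"22,185"
100,50,356
100,100,793
100,200,1979
100,400,2944
100,450,3807
100,800,5721
100,900,6499
100,1600,"12,013"
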