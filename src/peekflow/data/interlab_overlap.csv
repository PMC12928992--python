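color,overlap_min,overlap_max,intersect_n
yellow,0.0265,0.0307,18
blue,0.0944,0.1077,24
orange,1.3104,1.3476,5
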