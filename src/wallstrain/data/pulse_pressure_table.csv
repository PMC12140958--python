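condition,packing_pct,minute,lumen_pp,sac_pp
sequential,100,5,82.2,78.1
sequential,100,10,82.0,77.6
sequential,100,15,83.3,78.3
sequential,200,5,83.1,79.1
sequential,200,10,82.7,78.7
sequential,200,15,83.0,78.8
sequential,300,5,82.8,79.0
sequential,300,10,83.4,79.0
sequential,300,15,83.0,78.8
sequential,400,5,85.3,79.4
sequential,400,10,83.7,79.0
sequential,400,15,84.9,80.0
immediate,100,5,82.2,78.1
immediate,100,10,82.0,77.6
immediate,100,15,83.3,78.3
immediate,200,5,78.5,71.8
immediate,200,10,78.1,71.7
immediate,200,15,78.7,71.8
immediate,300,5,92.3,85.1
immediate,300,10,86.7,84.3
immediate,300,15,92.4,85.2
immediate,400,5,83.4,76.7
immediate,400,10,82.0,76.3
immediate,400,15,82.7,77.1
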