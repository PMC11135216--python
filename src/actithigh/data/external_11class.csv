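truth\pred,sitting,transitioning,walking,standing,lying,ascending_stairs,cycling,descending_stairs,running,driving,wheelchair
sitting,746,28,15,0,236,2,10,5,0,163,151
transitioning,1,131,64,0,10,4,66,14,7,35,30
walking,5,253,1178,72,0,60,108,191,89,50,69
standing,1,190,118,589,1,31,47,23,16,8,3
lying,208,58,4,0,746,0,0,0,0,54,136
ascending_stairs,0,8,143,29,0,184,40,38,42,0,0
cycling,0,57,57,6,0,19,1673,13,12,5,18
descending_stairs,0,17,520,26,0,30,7,162,12,0,0
running,0,13,28,7,0,4,5,18,1014,0,0
driving,23,50,31,0,34,0,4,15,4,3124,542
wheelchair,1,140,52,0,0,4,23,16,2,830,453
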