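truth\pred,sitting,transitioning,walking,standing,lying,ascending_stairs,cycling,descending_stairs,running,driving,wheelchair
sitting,2236,59,0,0,68,0,2,0,0,64,106
transitioning,27,1683,286,46,32,5,104,5,0,92,163
walking,0,220,3103,21,0,13,15,15,0,0,0
standing,0,48,4,1688,5,0,3,0,0,0,0
lying,17,48,0,0,1935,0,0,0,0,64,51
ascending_stairs,0,7,63,0,0,1060,31,24,6,0,0
cycling,0,36,20,1,0,19,44280,7,0,1,53
descending_stairs,0,0,105,0,0,30,12,979,7,0,0
running,0,0,7,0,0,1,1,8,34985,0,0
driving,4,44,0,0,20,0,3,0,0,42148,109
wheelchair,5,52,0,0,19,0,28,0,0,80,30134
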