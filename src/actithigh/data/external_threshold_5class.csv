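truth\pred,sedentary,walking,standing,cycling,running
sedentary,2124,4,72,0,0
walking,219,1999,443,12,30
standing,28,156,776,12,11
cycling,0,122,205,1491,7
running,0,203,43,0,834
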