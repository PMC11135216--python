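truth\pred,sedentary,walking,standing,cycling,running
sedentary,2046,143,0,11,0
walking,10,2381,95,122,95
standing,0,359,568,40,16
cycling,0,191,6,1631,8
running,0,66,7,6,1010
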