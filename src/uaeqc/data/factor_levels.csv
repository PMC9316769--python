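name,unit,low,center,high
methanol,%,50,70,90
ratio,mL/g,30,50,70
time,min,20,35,50
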