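trigger,kind,mode,accepts_normal_abnormal
22J,prefix,death,0
9491,prefix,death,0
62,prefix,pregnancy,0
pregnant,text,pregnancy,0
42,prefix,labtest,1
44,prefix,labtest,1
535,prefix,normal,1
9155,prefix,date,0
9D,prefix,sicknote,0
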