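prefix,reason
55,procedure
32,procedure
33B,procedure
42,test
44,test
535,procedure
5853,procedure
9D,administration
22J,administration
14A,history-of class
9155,administration
T503,injury cause description
62,administration
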