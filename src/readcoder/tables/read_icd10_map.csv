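read_code,icd10_code
G30..00,I21.9
G340.11,I25.1
G3...00,I25.9
G573000,I48
G575.00,I46.9
G580.00,I50.0
G581.00,I50.1
G581000,I50.1
G6...00,I67.9
G66..00,I64
G674.00,I63.9
G801.00,I80.2
G20..00,I10
B46..00,C61
B22z.00,C34.9
B723z00,D14.3
B902.00,C80.9
B576.00,C78.7
A38..00,A41.9
H262.00,J69.0
H260.00,J18.1
H3z..00,J44.9
Eu02z00,F03
P769000,Q27.1
K510000,N81.1
T4002,R96.0
486B,J18.0
486,J18.9
7969U,R99
4120AT,I25.1
199C,C80.9
401,I10
213100,R98
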