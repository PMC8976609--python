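label	population	population_unit	years_till_now	estimated_age
684 B.C.	11840	thousand	2704	2145
2 A.D.	59590	thousand	2018	2090
609 A.D.	46020	thousand	1411	1534
1110 A.D.	46730	thousand	910	1585
1403 A.D.	66600	thousand	617	992
1741 A.D.	143410	thousand	279	602
1949 A.D.	541.67	million	71	1006
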