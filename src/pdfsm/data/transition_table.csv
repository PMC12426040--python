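cases,state,S,DM,FM,AI,P,T,SD,F1,F2,F3,F4,L,PR,TU,DV,F,next,comment
8192,00000,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"S = 1, DV = 1, F = 1 go to alarm"
32768,00000,0,X,X,X,X,X,X,X,X,X,X,X,X,X,X,X,00000,"S = 0 stay in stand by"
2048,00000,1,1,0,X,X,X,X,X,X,X,X,X,X,X,0,0,00001,"S = 1, DM = 1, FM = 0, DV = 0, F = 0 go to w.ins"
2048,00000,1,0,1,X,X,X,X,X,X,X,X,X,X,X,0,0,01101,"S = 1, DM = 0, FM = 1, DV = 0, F = 0 go to flush stage"
8192,00001,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
512,00001,1,1,0,0,0,X,X,X,X,X,X,X,X,X,0,0,00001,"S = 1, F = 0, DM = 1, FM = 0, DV = 0 stay in w.ins"
512,00001,1,1,0,1,0,X,X,X,X,X,X,X,X,X,0,0,00010,"S = 1, DV = 0, F = 0, AI = 1 go to a.ins"
1024,00001,1,1,0,X,1,X,X,X,X,X,X,X,X,X,0,0,00011,"DV = 0, F = 0, S = 1, P = 1 go to heater on"
8192,00010,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"S = 1, DV = 1, F = 1 go to alarm"
512,00010,1,1,0,1,0,X,X,X,X,X,X,X,X,X,0,0,00010,"F = 0, AI = 1 stay in a.ins"
1024,00010,1,1,0,X,1,X,X,X,X,X,X,X,X,X,0,0,00011,"F = 0, P = 1 go to heater on"
8192,00011,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
1024,00011,1,1,0,X,X,0,X,X,X,X,X,X,X,X,0,0,00011,"F = 0, T = 0 stay in heater on"
1024,00011,1,1,0,X,X,1,X,X,X,X,X,X,X,X,0,0,00100,"F = 0, T = 1 go to heater off"
8192,00100,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
1024,00100,1,1,0,X,X,1,X,X,X,X,X,X,X,X,0,0,00100,"F = 0, T = 1 stay in heater off"
1024,00100,1,1,0,X,X,0,X,X,X,X,X,X,X,X,0,0,00011,"F = 0, T = 0 go to heater on"
512,00100,1,1,0,X,X,1,1,X,X,X,X,X,X,X,0,0,00101,"F = 0, T = 1, SD = 1 go to filling"
8192,00101,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
128,00101,1,1,0,X,X,1,X,X,1,X,X,1,1,X,0,0,00101,"F = 0, F2 = 1, L = 1, PR = 1 stay in filling"
1024,00101,1,1,0,X,X,X,X,X,X,X,X,0,X,X,0,0,00110,"F = 0, L = 0 go to filling end"
8192,00110,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
2048,00110,1,1,0,X,X,X,X,X,X,X,X,X,X,X,0,0,00111,"F = 0 after filling end go to dwm with delay"
8192,00111,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
2048,00111,1,1,0,X,X,X,X,X,X,X,X,X,X,X,0,0,01000,"F = 0 after dwm go to ds with delay"
8192,01000,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
1024,01000,1,1,0,X,X,X,X,X,X,X,1,X,X,X,0,0,01001,"F = 0, F4 = 1 go to V4F"
1024,01000,1,1,0,X,X,X,X,X,X,X,0,X,X,X,0,0,01010,"F = 0, F4 = 0 go to de"
8192,01001,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
2048,01001,1,1,0,X,X,X,X,X,X,X,X,X,X,X,0,0,01011,"F = 0 after V4F go to ls with delay"
8192,01010,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
8192,01011,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
256,01011,1,1,0,X,X,X,X,0,X,0,X,1,X,X,0,0,01100,"F = 0, F1 = 0, F3 = 0, L = 1 go to V31F"
8192,01100,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
2048,01100,1,0,1,X,X,X,X,X,X,X,X,X,X,X,0,0,01101,"F = 0 after V31F go to flush with delay"
8192,01101,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
2048,01101,1,0,1,X,X,X,X,X,X,X,X,X,X,X,0,0,01101,"F = 0, FM = 1 stay in flush"
1024,01101,1,0,1,X,X,X,X,X,X,X,0,X,X,X,0,0,01110,"F = 0, F4 = 0 go to V456F"
8192,01110,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
8192,01110,1,X,X,X,X,X,X,X,X,X,X,X,X,X,0,0,01111,"F = 0 after V456F go to V31N with delay"
8192,01111,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
4096,01111,1,X,X,X,X,X,X,X,X,X,X,1,X,X,0,0,10000,"F = 0, L = 1 go to V1F"
8192,10000,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
1024,10000,1,1,0,X,X,X,X,X,X,X,X,X,X,1,0,0,00011,"F = 0, TU = 1 go to heater on"
1024,10000,1,1,0,X,X,X,X,X,X,X,X,X,X,0,0,0,00000,"F = 0, TU = 0 go to stand by"
65536,10001,X,X,X,X,X,X,X,X,X,X,X,X,X,X,X,X,11111,"Unused"
65536,11110,X,X,X,X,X,X,X,X,X,X,X,X,X,X,X,X,11111,"Unused"
8192,11111,1,X,X,X,X,X,X,X,X,X,X,X,X,X,1,1,11111,"F = 1 go to alarm"
8192,11111,1,X,X,X,X,X,X,X,X,X,X,X,X,X,0,0,00000,"F = 0 go to stand by"
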