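index,input,input_description,transition,output,output_description,state_label,state_code
1,S,Start button,T_S,SB,Stand by,S_0,00000
2,DM,Dialysis mode button,T_DM,W.INS,Written instructions,S_1,00001
3,FM,Flush mode button,T_FM,A.INS,Audible instructions,S_2,00010
4,AI,Audible instructions button,T_AI,HN,Heater on,S_3,00011
5,P,Pass button,T_P,HF,Heater off,S_4,00100
6,T,Temperature sensor,T_T,FS,Filling start,S_5,00101
7,SD,Start dialysis button,T_SD,FE,Filling end,S_6,00110
8,F1,Flow sensor 1,T_F1,DWM,Downward movement,S_7,00111
9,F2,Flow sensor 2,T_F2,DS,Draining start,S_8,01000
10,F3,Flow sensor 3,T_F3,V4F,Valve 4 off,S_9,01001
11,F4,Flow sensor 4,T_F4,DE,Draining end,S_10,01010
12,L,Level sensor,T_L,LS,Loop stage,S_11,01011
13,PR,Pressure sensor,T_PR,V31F,Valves 3 and 1 off,S_12,01100
14,TU,Turbidity sensor,T_TU,FSH,Flush stage,S_13,01101
15,DV,Danger value,T_DV,V456F,"Valves 4, 5, and 6 off",S_14,01110
16,F,Fault in the system,T_F,V31N,Valves 3 and 1 on + downward movement,S_15,01111
17,,,,V1F,Valve 1 off,S_16,10000
18,,,,A,Error alarm,S_17,11111
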