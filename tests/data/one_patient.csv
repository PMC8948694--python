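ID,TIME,AMT,RATE,EVID,MDV,DV,OCC,BW,LAG
1,0.0,18.36,9.18,1,1,.,1,15.3,0.6666666666666666
1,2.5,0.0,0.0,0,0,1.95,1,15.3,0.6666666666666666
1,3.0,0.0,0.0,0,0,1.61,1,15.3,0.6666666666666666
1,4.0,0.0,0.0,0,0,1.02,1,15.3,0.6666666666666666
1,6.0,0.0,0.0,0,0,0.55,1,15.3,0.6666666666666666
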