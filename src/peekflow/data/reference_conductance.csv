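color,lab,n,mean,min,max,cv_pct
yellow,DRF,13,0.0284,0.0265,0.0316,4.8
yellow,UQAM,13,0.0267,0.0240,0.0307,7.3
blue,DRF,14,0.0986,0.0894,0.1077,5.6
blue,UQAM,15,0.1038,0.0944,0.1213,6.1
orange,DRF,22,1.2552,1.1731,1.3476,3.7
orange,UQAM,13,1.4070,1.3104,1.5235,4.5
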