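t,mean,sd
1,2.2000000000000002,0.84852813742385713
2,4.3799999999999999,0.86925255248402911
3,6.5999999999999996,0.7745966692414834
4,9,0
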