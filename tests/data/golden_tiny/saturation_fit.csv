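form,a,b,target_n,prediction,degenerate
shifted,7806114.0811697841,2.8507577483944155e-07,152,338.24344281857759,False
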