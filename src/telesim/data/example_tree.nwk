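(((2:1.0,4:1.0):1.0,(3:1.5,5:1.5):0.5):0.5,1:3.0);
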