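id,temperature,pressure,ethanol_flow,co2_flow
SC1,40,150,0.6,5.0
SC2,40,150,0.9,5.0
SC3,50,150,0.6,5.0
SC4,50,150,0.9,5.0
SC5,60,150,0.6,5.0
SC6,60,150,0.9,5.0
SC7,40,250,0.6,5.0
SC8,40,250,0.9,5.0
SC9,50,250,0.6,5.0
SC10,50,250,0.9,5.0
SC11,60,250,0.6,5.0
SC12,60,250,0.9,5.0
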