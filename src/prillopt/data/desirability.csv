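property,weight,shape,min,mid1,mid2,max
prilling_score,10,UP,0,1.5,1.6,2
feret_mm,5,TENT,1.107,2,2.5,3.022
circularity,1,UP,0.642,0.7985,0.7985,0.955
core_score,9,UP,0,4,4.1,5
coating_mm,8,UP,0.074,0.2345,0.2345,0.395
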