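signal,source,cell,area
demo_diffusible,V1,u,10.0
demo_diffusible,V1,v,6.0
demo_diffusible,V2,w,6.0
demo_diffusible,V2,x,2.0
demo_tethered,u,u,5.0
demo_tethered,v,u,3.0
demo_tethered,u,v,4.0
demo_tethered,v,v,6.0
demo_tethered,u,w,1.0
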