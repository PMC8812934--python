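group,Per,But,Fuc,Hex,Pra,Vio,All,Zea,Chlb,MVChla,DVChla
diatoms,0,0,75,0,0,0,0,0,0,100,0
haptophytes3,0,2,12,125,0,0,0,0,0,100,0
haptophytes4,0,52,13,65,0,0,0,0,0,100,0
dinoflagellates,106,0,0,0,0,0,0,0,0,100,0
cryptophytes,0,0,0,0,0,0,23,0,0,100,0
prasinophytes,0,0,0,0,15,11,0,0,2,100,0
chlorophytes,0,0,0,0,0,5,0,1,3,100,0
cyanophytes,0,0,0,0,0,0,0,34,0,100,0
prochlorophytes,0,0,0,0,0,0,0,69,114,0,100
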