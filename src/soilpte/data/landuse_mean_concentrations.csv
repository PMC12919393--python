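land_use,Hg,As,Zn,Pb,Co,Cd,Ni,Cr,Cu
CM,1.0,15.6,266.4,59.0,172.4,3.2,395.5,333.4,236.2
RD,0.7,2.9,174.7,27.4,79.6,3.1,234.1,152.0,86.0
AG,1.5,8.9,260.6,16.7,160.9,10.7,325.6,181.7,179.1
FT,0.2,9.1,146.0,40.2,118.1,2.6,248.9,117.9,96.2
RS,0.8,4.9,165.5,56.7,141.4,5.8,255.6,99.7,119.3
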