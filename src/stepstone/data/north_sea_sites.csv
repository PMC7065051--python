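site_id,full_name,lat,lon,depth_m,dist_shore_km,is_outgroup
BG1x,BG 1,53.8833,3.4983,0,116,False
BKUM,Borkum Riffgat,53.6900,6.4800,4,14,False
BLYT,Blythe,55.1258,-1.4983,0,0,False
BRES,Breskens,51.4068,3.5121,0,0,False
BVW,BV W,52.6007,3.5170,0,74,False
CALA,Calais,50.9661,1.8433,0,0,False
D15A,D15-A,54.3247,2.9346,7,181,False
EUR7,EURO 7,51.9900,3.5031,0,32,False
EURW,Euro W,51.9095,2.7232,0,70,False
F31A,F3-1A,54.8520,4.6949,5,166,False
FINO,FINO 3,55.1950,7.1583,4,71,False
G14A,G14-A,54.2241,5.4986,13,85,False
HARW,Harwich,51.9348,1.2813,0,0,False
HELG,Helgoland,54.1760,7.8945,0,47,False
HORN,Horns Rev,55.4789,7.8110,0,19,False
K10B,K10-B,53.3626,3.2539,27,104,False
K9A,K9-A,53.5202,3.9925,0,66,False
L10G,L10-G,53.4904,4.1952,10,53,False
L15A,L15-A,53.3295,4.8302,6,11,False
LIMF,Limfjorden,56.7830,8.9110,2,0,True
LISB,Lisbon,38.7635,-9.0926,0,0,True
PAAL,Texel,53.0118,4.7083,0,0,False
Q13A,Q13-A,52.1911,4.1361,0,13,False
SCHV,Scheveningen,52.0987,4.2582,0,0,False
SYLT,Sylt,55.0216,8.4403,0,0,False
WZA,Wadden Sea A,53.4521,6.3042,0,0,False
WZB,Wadden Sea B,53.4600,6.3583,2,0,False
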