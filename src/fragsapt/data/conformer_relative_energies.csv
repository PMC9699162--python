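guest,al_cx_elec,pc_cx_elec,wc_cx_elec,al_cx_total,pc_cx_total,wc_cx_total,al_bcx_elec,pc_bcx_elec,wc_bcx_elec,al_bcx_total,pc_bcx_total,wc_bcx_total
empty,13.2,0.0,15.8,12.0,0.0,14.9,10.7,0.0,1.7,9.7,0.0,2.4
Ala,2.7,2.4,0.0,2.0,1.5,0.0,3.5,3.6,0.0,1.6,1.5,0.0
Asn,0.0,16.1,15.7,0.0,16.3,17.5,1.8,14.4,0.0,0.0,12.0,0.0
AspH,0.0,4.1,8.7,0.0,4.2,9.4,3.9,11.1,0.0,3.5,11.0,0.0
Cys,0.0,4.7,6.0,0.0,4.3,6.3,0.0,11.2,0.2,0.0,10.0,1.8
Gln,0.0,1.6,1.8,0.0,0.1,1.9,4.2,6.9,0.0,2.9,6.4,0.0
GluH,0.0,1.1,1.1,0.0,1.5,1.7,9.9,10.2,0.0,9.1,9.2,0.0
Gly,0.0,8.7,7.0,0.0,8.3,8.0,7.6,17.0,0.0,6.0,14.7,0.0
HisD,2.0,2.4,0.0,0.9,1.6,0.0,5.1,11.9,0.0,4.5,9.9,0.0
HisE,0.0,3.5,4.8,0.0,4.1,5.6,5.2,4.8,0.0,2.5,2.9,0.0
Ile,2.9,0.0,1.7,3.6,0.0,2.5,8.8,7.9,0.0,7.2,6.5,0.0
Leu,0.8,0.0,13.7,0.3,0.0,13.5,9.8,6.6,0.0,7.9,6.1,0.0
Lys,0.0,1.0,1.6,0.0,2.5,2.2,1.6,12.6,0.0,0.0,13.3,0.0
Met,0.0,5.9,4.8,0.0,5.1,4.6,2.4,1.1,0.0,0.4,0.0,0.2
Phe,1.9,0.0,8.6,2.5,0.0,8.8,1.6,0.1,0.0,1.1,0.0,0.3
Pro,2.1,0.0,9.5,0.7,0.0,9.4,4.5,0.0,3.8,4.2,0.0,4.8
Ser,0.0,11.8,9.4,0.0,9.8,9.8,2.1,13.5,0.0,0.0,10.4,0.0
Thr,0.0,7.6,11.2,0.0,5.9,11.2,4.4,11.0,0.0,3.1,8.1,0.0
Trp,0.1,0.0,3.7,0.8,0.0,4.5,13.7,8.2,0.0,10.8,6.7,0.0
Tyr,2.7,2.2,0.0,1.9,1.2,0.0,8.6,0.0,5.7,6.9,0.0,5.3
Val,7.9,0.0,8.4,7.3,0.0,8.8,7.4,5.4,0.0,5.6,3.9,0.0
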