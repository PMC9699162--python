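conformer,host,guest,group_a,group_b,elst,exch,ind_eff,disp_eff,total,r_elst_printed,r_exch_printed,r_ind_printed,r_disp_printed,label
al,CX,Asn,OH-2,NH2-1,-53.9,60.7,-29.0,-7.5,-29.7,1.8,2.0,1.0,0.3,typical H-bond
al,BCX,Lys,OH-2,NH2-1,-48.3,47.9,-23.1,-6.5,-29.9,1.6,1.6,0.8,0.2,typical H-bond
al,CX,Pro,OH-2,Ring,-44.7,54.0,-26.2,-8.7,-25.5,1.7,2.1,1.0,0.3,typical H-bond+disp
wc,CX,Pro,OH-3,Ring,-26.8,29.1,-11.2,-5.8,-14.6,1.8,2.0,0.8,0.4,typical H-bond+disp
wc,BCX,Pro,OH-6,Ring,-25.7,28.4,-11.0,-5.6,-13.9,1.8,2.0,0.8,0.4,typical H-bond+disp
wc,CX,Leu,Ph-6,COOH,-19.7,7.5,-4.7,-4.8,-21.7,0.9,0.3,0.2,0.2,H⋯π
wc,CX,Pro,Ph-6,COOH,-16.6,6.2,-3.8,-4.5,-18.6,0.9,0.3,0.2,0.2,H⋯π
al,BCX,Ser,Ph-5,COOH,-19.4,10.2,-5.8,-5.8,-20.8,0.9,0.5,0.3,0.3,H⋯π
pc,BCX,Tyr,Ph-4,OH,-10.2,5.5,-2.5,-2.8,-9.9,1.0,0.6,0.3,0.3,H⋯π
pc,CX,HisE,Ph-6,Ring,-11.9,10.1,-2.7,-8.5,-13.0,0.9,0.8,0.2,0.7,disp
wc,CX,HisE,Ph-2,Ring,-11.8,7.5,-1.7,-7.2,-13.2,0.9,0.6,0.1,0.5,disp
pc,BCX,HisE,Ph-5,Ring,-13.4,10.6,-3.5,-8.8,-15.1,0.9,0.7,0.2,0.6,disp
wc,BCX,HisE,Ph-5,Ring,-13.9,10.0,-2.3,-9.0,-15.1,0.9,0.7,0.2,0.6,disp
wc,BCX,Trp,Ph-5,Ring,-12.1,10.7,-2.6,-10.8,-14.8,0.8,0.7,0.2,0.7,disp
pc,CX,Tyr,Ph-3,COOH,-15.7,1.2,-1.4,-2.2,-18.1,0.9,0.1,0.1,0.1,elst
al,CX,HisD,Ph-4,COOH,-11.7,0.3,-2.3,-1.5,-15.1,0.8,0.0,0.2,0.1,elst
al,BCX,Gly,Ph-5,COOH,-7.7,0.8,-1.4,-2.1,-10.5,0.7,0.1,0.1,0.2,elst
pc,BCX,GluH,Ph-3,COOH-1,-15.4,2.3,-2.2,-3.2,-18.5,0.8,0.1,0.1,0.2,elst
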