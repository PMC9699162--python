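conformer,guest,elst,exch,ind,exch_ind,disp,exch_disp,e_int_hf,e_tot_sapt0,mp2_corr,scs_mp2_corr,elst_pct_err,exch_pct_err,ind_pct_err,exch_ind_pct_err,disp_pct_err,exch_disp_pct_err,e_int_hf_pct_err,e_tot_sapt0_pct_err,mp2_corr_pct_err,scs_mp2_corr_pct_err
al,Ala,-66.5,97.9,-46.2,29.4,-56.6,8.3,-0.1,-48.4,-40.7,-29.6,-0.3,0.6,1.4,0.7,-1.4,-2.9,-423.9,-1.9,-1.0,-1.1
al,Asn,-86.9,110.4,-58.9,35.0,-57.0,8.5,-20.3,-68.8,-37.9,-26.8,0.4,0.1,-1.1,-1.4,-0.9,-1.3,-3.8,-1.7,-1.4,-1.7
al,AspH,-67.5,94.5,-46.7,29.9,-55.3,7.6,-3.7,-51.3,-40.1,-29.2,-0.3,0.3,-1.0,-1.9,-1.1,-1.4,-24.7,-2.8,-1.4,-1.5
al,Cys,-84.5,104.7,-51.6,31.4,-58.8,8.6,-15.8,-66.0,-38.4,-26.9,0.4,0.1,-0.4,-1.1,-1.5,-2.7,-0.8,-1.1,-1.8,-2.2
al,Gln,-102.6,128.1,-59.0,36.0,-68.9,10.1,-16.5,-75.3,-44.4,-30.8,0.0,0.6,-0.3,-0.5,-0.9,-1.4,-4.8,-1.7,-1.3,-1.6
al,GluH,-59.4,66.9,-30.4,18.7,-54.0,6.5,-11.8,-59.2,-34.9,-24.3,1.2,0.1,0.5,0.0,-1.8,-3.5,7.1,0.2,-2.0,-2.7
al,Gly,-74.7,91.3,-46.8,28.2,-50.6,7.5,-16.6,-59.7,-32.6,-22.7,0.5,0.2,-0.4,-1.2,-1.6,-2.7,-1.2,-1.3,-1.4,-1.6
al,HisD,-57.1,67.4,-30.6,18.3,-54.6,6.4,-10.2,-58.4,-38.4,-27.4,1.7,0.2,2.7,0.3,-1.4,-3.2,18.7,2.3,-1.1,-1.4
al,HisE,-67.6,96.5,-49.0,30.6,-63.7,8.7,-5.2,-60.1,-45.9,-33.8,-0.1,0.4,-1.4,-0.8,-0.8,-0.8,-26.7,-3.1,-1.3,-1.4
al,Ile,-56.1,76.0,-32.6,21.5,-61.6,7.6,0.4,-53.6,-43.6,-31.4,-0.3,0.1,0.9,-0.6,-1.5,-3.3,-73.8,-0.7,-1.5,-1.9
al,Leu,-58.3,83.7,-39.0,25.0,-57.6,7.5,-0.3,-50.4,-43.1,-31.9,-0.1,0.3,-1.1,-1.7,-1.2,-2.1,-267.8,-2.7,-1.5,-1.6
al,Lys,-75.7,102.7,-48.3,29.8,-63.0,8.7,-7.9,-62.2,-44.7,-32.5,0.2,0.4,-0.6,-1.5,-0.9,-2.0,-11.3,-2.1,-1.1,-1.3
al,Met,-58.3,74.6,-33.7,21.2,-62.2,7.6,-4.9,-59.5,-43.7,-31.5,1.9,0.1,1.5,-0.4,-1.7,-3.5,38.4,1.8,-1.1,-1.4
al,Phe,-52.8,68.5,-29.5,18.2,-53.5,6.4,-4.5,-51.6,-36.4,-26.0,-0.2,-0.1,-0.4,-0.4,-1.0,-2.0,-11.2,-1.8,-1.5,-1.7
al,Pro,-85.3,115.5,-59.8,36.2,-58.3,8.8,-13.8,-63.3,-39.5,-28.2,-0.1,0.3,-1.5,-1.1,-1.1,-1.7,-11.9,-3.4,-1.2,-1.4
al,Ser,-61.7,74.4,-31.1,19.8,-53.1,6.8,-6.2,-52.5,-37.6,-27.0,-0.4,0.4,1.6,0.8,-1.8,-4.3,3.1,-0.9,-1.4,-1.7
al,Thr,-62.4,72.3,-29.8,18.9,-57.1,7.1,-8.3,-58.3,-41.0,-29.5,-0.2,0.2,1.2,0.2,-1.7,-3.6,3.8,-0.7,-1.4,-1.7
al,Trp,-53.4,79.1,-34.7,24.3,-67.7,8.3,5.7,-53.6,-53.0,-39.6,-0.3,0.3,-0.4,-0.7,-0.7,-1.4,5.4,-1.2,-0.9,-1.0
al,Tyr,-60.8,73.3,-31.7,20.1,-60.1,7.4,-6.9,-59.6,-43.4,-31.7,-0.1,0.4,1.9,0.8,-1.6,-3.5,7.7,-0.3,-1.5,-1.8
al,Val,-60.1,78.8,-36.6,22.9,-57.7,7.3,-5.4,-55.9,-42.3,-31.0,-0.8,0.2,-0.2,-1.7,-1.2,-2.9,-11.2,-2.0,-1.7,-2.0
pc,Ala,-55.1,62.7,-29.5,18.2,-30.1,4.6,-12.0,-37.6,-18.0,-12.3,-0.2,0.1,2.9,0.0,-1.4,-1.9,2.8,0.0,-1.4,-1.8
pc,Asn,-34.1,37.7,-14.4,10.1,-31.2,3.4,-3.3,-31.1,-20.3,-14.4,1.2,0.0,13.3,2.1,-2.0,-2.6,65.5,5.3,-2.0,-2.6
pc,AspH,-26.6,32.8,-13.5,8.7,-26.9,2.8,-1.4,-25.6,-18.3,-13.2,2.1,0.4,13.9,2.7,-1.4,-1.8,147.3,7.0,-1.6,-2.1
pc,Cys,-14.6,19.6,-7.0,5.0,-19.7,1.8,1.4,-16.6,-14.4,-10.5,2.7,0.3,14.8,1.9,-1.1,-1.0,-95.5,6.7,-1.1,-1.3
pc,Gln,-50.1,57.3,-26.1,16.2,-35.4,4.5,-9.7,-40.6,-21.1,-14.4,0.2,0.3,6.5,1.3,-1.5,-1.8,15.8,2.7,-1.2,-1.7
pc,GluH,-41.8,45.6,-20.7,13.3,-29.8,3.6,-8.5,-34.7,-17.8,-12.3,0.6,0.2,9.7,2.0,-1.6,-2.1,25.2,5.0,-2.0,-2.6
pc,Gly,-33.4,36.0,-15.9,9.7,-20.1,2.6,-8.0,-25.5,-11.4,-7.7,0.8,0.0,6.8,0.9,-1.4,-1.9,15.3,3.9,-1.3,-1.9
pc,HisD,-39.8,52.5,-22.6,16.3,-47.0,5.4,2.0,-39.6,-34.1,-25.1,0.6,0.1,7.0,1.2,-1.1,-1.1,-84.7,3.2,-0.9,-1.1
pc,HisE,-24.9,36.2,-15.2,11.8,-39.4,4.3,5.0,-30.1,-30.3,-22.6,0.2,0.3,7.0,1.6,-0.6,-0.1,-18.9,2.3,-0.7,-0.7
pc,Ile,-22.2,39.8,-14.7,11.4,-41.2,4.4,11.1,-25.7,-32.1,-24.1,2.4,0.8,4.1,1.2,-1.3,-1.8,-6.8,1.1,-1.6,-1.8
pc,Leu,-31.0,43.8,-16.1,11.8,-38.5,4.1,4.9,-29.5,-28.1,-20.7,1.3,0.3,10.4,1.7,-1.0,-1.4,-40.4,5.5,-0.8,-1.0
pc,Lys,-19.3,38.9,-12.4,9.4,-43.2,4.5,13.4,-25.2,-35.4,-26.7,0.3,0.2,3.2,0.5,-1.0,-1.4,-3.5,0.4,-0.9,-1.0
pc,Met,-17.4,25.6,-8.6,6.0,-26.9,2.3,3.5,-21.0,-20.1,-14.8,2.1,0.5,17.7,2.2,-0.9,-0.2,-49.2,7.1,-1.6,-1.9
pc,Phe,-39.9,56.2,-24.9,18.4,-49.1,6.0,4.6,-38.5,-36.4,-27.1,0.9,0.0,5.8,0.9,-1.0,-1.7,-36.2,3.3,-0.8,-1.0
pc,Pro,-20.1,34.2,-12.8,9.6,-39.0,4.1,7.7,-27.2,-30.8,-22.9,0.0,0.2,3.4,0.7,-0.9,-0.9,-4.9,0.3,-1.1,-1.2
pc,Ser,-30.0,34.7,-14.4,9.6,-24.8,2.8,-3.5,-25.6,-16.2,-11.5,1.4,0.3,11.5,2.0,-1.5,-1.8,57.0,6.6,-1.3,-1.7
pc,Thr,-37.9,39.6,-17.7,10.5,-22.5,2.8,-10.4,-30.1,-12.1,-8.0,0.7,-0.3,4.3,0.2,-1.3,-1.7,11.0,3.0,-1.4,-2.0
pc,Trp,-35.8,54.5,-22.2,16.9,-55.7,6.2,8.9,-40.6,-42.7,-32.1,1.0,0.0,7.7,1.1,-0.9,-1.1,-22.9,3.9,-0.7,-0.8
pc,Tyr,-17.3,27.4,-10.8,7.0,-31.4,3.1,4.0,-24.3,-24.3,-17.9,1.8,0.1,4.6,1.2,-0.8,-0.7,-18.4,2.1,-0.5,-0.5
pc,Val,-23.1,37.5,-13.0,9.6,-39.5,4.2,8.0,-27.3,-30.4,-22.6,0.7,0.5,4.1,1.4,-1.1,-1.3,-5.8,0.3,-1.1,-1.3
wc,Ala,-72.9,80.5,-39.3,23.0,-36.4,5.7,-20.9,-51.7,-21.3,-14.2,-0.1,0.1,-1.3,-1.9,-1.2,-3.0,-0.4,-0.7,-1.3,-1.6
wc,Asn,-92.1,109.0,-55.3,31.5,-45.4,7.1,-23.8,-62.1,-25.6,-16.9,-0.1,0.2,-0.6,-1.4,-1.0,-2.5,-1.0,-0.8,-1.3,-1.8
wc,AspH,-49.7,48.1,-22.4,12.5,-30.0,3.6,-17.6,-44.1,-16.7,-10.8,0.6,-0.3,-0.8,-1.2,-1.2,-2.3,1.6,0.0,-2.0,-2.8
wc,Cys,-54.9,58.0,-27.8,16.0,-30.9,4.1,-17.7,-44.4,-16.7,-10.8,-0.3,-0.3,-0.2,-0.7,-1.3,-3.2,-1.4,-1.2,-2.0,-2.6
wc,Gln,-83.6,85.2,-41.1,22.2,-39.3,5.7,-31.4,-65.0,-18.1,-10.8,-0.2,-0.4,0.1,-1.0,-1.3,-2.9,0.7,-0.2,-2.0,-2.9
wc,GluH,-71.5,73.2,-37.1,19.9,-34.0,4.8,-28.0,-57.2,-16.0,-9.6,0.2,-0.4,-0.9,-0.9,-1.3,-3.1,-0.7,-0.9,-2.6,-3.7
wc,Gly,-74.2,80.0,-39.5,23.0,-34.7,5.6,-22.9,-52.0,-19.8,-13.0,0.0,0.2,-1.2,-1.8,-1.3,-3.3,-0.4,-0.7,-1.5,-1.9
wc,HisD,-89.0,104.4,-52.6,31.5,-52.9,7.9,-22.0,-67.1,-34.9,-24.6,0.2,0.1,-0.5,-1.2,-1.0,-2.4,0.0,-0.5,-1.1,-1.3
wc,HisE,-71.0,83.3,-40.8,25.9,-51.2,7.1,-13.7,-57.7,-36.3,-26.4,0.1,0.1,-0.6,-1.2,-1.0,-2.0,1.4,-0.3,-0.7,-0.8
wc,Ile,-68.1,75.6,-35.0,20.5,-39.4,5.5,-17.7,-51.6,-24.6,-16.8,0.0,0.0,-1.0,-1.8,-1.1,-2.7,0.7,-0.3,-1.2,-1.5
wc,Leu,-73.8,86.4,-42.5,25.2,-43.6,6.4,-17.0,-54.2,-26.3,-17.7,0.1,-0.1,-0.2,-1.1,-1.2,-2.2,2.1,0.0,-1.4,-1.7
wc,Lys,-92.1,105.1,-55.9,32.2,-44.8,7.1,-29.3,-66.9,-24.7,-16.1,0.2,-0.3,-0.6,-0.9,-1.4,-2.9,0.1,-0.5,-2.1,-2.8
wc,Met,-77.5,90.1,-43.9,25.6,-42.4,6.3,-19.7,-55.8,-25.7,-17.4,-0.1,0.1,-0.8,-1.9,-1.1,-2.8,-0.1,-0.6,-1.1,-1.4
wc,Phe,-78.8,88.2,-43.6,25.3,-41.3,6.2,-22.4,-57.4,-24.4,-16.4,0.1,0.1,-1.2,-2.1,-1.2,-3.1,0.5,-0.4,-1.3,-1.7
wc,Pro,-70.7,81.1,-39.8,24.7,-46.7,6.6,-15.4,-55.5,-29.0,-20.0,0.9,-0.1,-0.1,-0.6,-1.6,-3.1,6.1,0.7,-1.6,-2.0
wc,Ser,-81.1,84.1,-41.5,23.3,-39.4,5.9,-27.3,-60.8,-22.0,-14.2,0.0,-0.1,-0.4,-1.9,-1.0,-2.8,1.4,0.3,-1.3,-1.7
wc,Thr,-77.1,85.9,-40.0,23.7,-43.5,6.3,-19.3,-56.5,-25.8,-17.1,0.3,0.0,-0.2,-1.9,-1.3,-3.0,3.8,0.6,-1.7,-2.2
wc,Trp,-79.9,93.8,-43.3,27.4,-60.4,8.0,-13.9,-66.3,-40.8,-28.9,0.2,-0.1,0.1,-1.6,-1.1,-2.6,5.8,0.5,-1.3,-1.6
wc,Tyr,-72.2,83.8,-40.2,26.7,-53.7,7.5,-12.7,-58.9,-37.1,-26.6,0.1,-0.1,-0.7,-1.3,-0.7,-1.7,1.5,-0.1,-0.7,-0.8
wc,Val,-71.5,78.8,-37.3,21.8,-40.3,5.7,-19.4,-54.0,-24.6,-16.7,0.2,-0.1,-1.1,-2.0,-1.1,-2.8,1.2,-0.1,-1.3,-1.6
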