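plaque,circle,angle_deg,mean_pct,sd_pct
CIA,1,0,104.3,3.5
CIA,1,45,104.3,2.9
CIA,1,90,101.1,1.5
CIA,1,135,72.4,4.6
CIA,1,180,44.3,4.4
CIA,2,0,99.6,7.2
CIA,2,45,102.1,4.9
CIA,2,90,99.1,3.8
CIA,2,135,41.3,4.0
CIA,2,180,12.1,1.6
CIA,3,0,59.3,8.9
CIA,3,45,64.1,6.5
CIA,3,90,62.2,6.9
CIA,3,135,17.5,1.8
CIA,3,180,4.1,0.5
CIA,4,0,10.9,1.3
CIA,4,45,14.7,1.8
CIA,4,90,11.7,1.1
CIA,4,135,4.8,0.6
CIA,4,180,1.7,0.5
CIB,1,0,99.7,4.1
CIB,1,45,99.7,2.8
CIB,1,90,100.3,2.5
CIB,1,135,91.9,4.2
CIB,1,180,62.8,6.8
CIB,2,0,98.0,6.4
CIB,2,45,99.2,3.7
CIB,2,90,99.0,5.5
CIB,2,135,63.3,7.1
CIB,2,180,10.5,1.6
CIB,3,0,48.9,6.2
CIB,3,45,56.5,6.6
CIB,3,90,61.3,6.6
CIB,3,135,29.6,5.1
CIB,3,180,3.3,1.5
CIB,4,0,5.2,0.7
CIB,4,45,5.7,0.8
CIB,4,90,6.5,0.7
CIB,4,135,3.5,0.6
CIB,4,180,0.9,0.3
COB,1,0,97.8,4.0
COB,1,45,98.0,3.0
COB,1,90,99.4,3.2
COB,1,135,98.0,4.7
COB,1,180,82.5,7.4
COB,2,0,97.3,6.2
COB,2,45,96.4,5.2
COB,2,90,97.0,4.7
COB,2,135,94.1,6.7
COB,2,180,19.4,2.2
COB,3,0,44.3,9.2
COB,3,45,51.7,6.8
COB,3,90,58.8,6.9
COB,3,135,55.0,9.8
COB,3,180,5.6,0.8
COB,4,0,5.5,1.2
COB,4,45,6.4,0.7
COB,4,90,6.8,0.5
COB,4,135,5.7,0.9
COB,4,180,1.7,0.5
COC,1,0,94.2,6.3
COC,1,45,96.8,5.1
COC,1,90,98.7,2.7
COC,1,135,91.0,7.0
COC,1,180,32.3,4.9
COC,2,0,93.3,8.8
COC,2,45,94.4,5.7
COC,2,90,97.2,4.2
COC,2,135,97.8,5.9
COC,2,180,10.3,1.4
COC,3,0,34.1,8.2
COC,3,45,43.7,11.7
COC,3,90,48.8,6.9
COC,3,135,52.5,6.3
COC,3,180,3.4,0.7
COC,4,0,2.0,0.4
COC,4,45,2.4,0.6
COC,4,90,2.9,0.4
COC,4,135,2.8,0.4
COC,4,180,0.9,0.3
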