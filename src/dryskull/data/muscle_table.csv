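taxon,muscle,volume_mm3,length_mm,fmus_N,contribution_fmus_pct,alpha_deg,beta_deg,fres_N,contribution_fres_pct
Incisivosaurus,mAMEM,1492.1,43.4,30.9,12.3,27.6,4.4,27.3,12.2
Incisivosaurus,mAMEP,1393.8,44.4,28.2,11.2,30.0,4.2,24.4,10.9
Incisivosaurus,mAMES,2242.3,41.7,48.4,19.2,24.2,1.5,44.1,19.6
Incisivosaurus,mAMP,671.5,21.9,27.7,11.0,27.4,2.1,24.6,10.9
Incisivosaurus,mPSTp,379.0,31.1,11.0,4.4,26.6,5.3,9.8,4.4
Incisivosaurus,mPSTs,698.1,45.7,13.7,5.5,19.4,1.5,13.0,5.8
Incisivosaurus,mPTd,589.3,29.8,17.8,7.1,44.4,11.8,12.5,5.5
Incisivosaurus,mPTv,1695.8,20.7,73.7,29.3,13.3,15.6,69.1,30.8
Citipati,mAMEM,16130.0,69.2,209.9,15.6,23.8,4.0,191.6,16.6
Citipati,mAMEP,10122.5,59.9,152.1,11.3,32.4,8.4,127.1,11.0
Citipati,mAMES,19580.5,58.7,300.2,22.2,16.3,6.8,286.2,24.8
Citipati,mAMP,7221.5,43.8,148.4,11.0,44.7,14.7,102.1,8.8
Citipati,mPSTp,4876.0,50.9,86.2,6.4,33.6,27.2,63.8,5.5
Citipati,mPSTs,6962.5,64.9,96.6,7.2,25.9,5.9,86.5,7.5
Citipati,mPTd,3638.5,42.2,77.6,5.7,37.5,13.3,59.9,5.2
Citipati,mPTv,10858.0,35.1,278.8,20.7,19.0,25.1,238.8,20.7
Khaan,mAMEM,4032.0,48.5,74.9,12.1,28.9,1.2,65.6,12.4
Khaan,mAMEP,4398.0,45.8,86.5,13.9,35.5,7.1,69.9,13.2
Khaan,mAMES,6371.5,46.3,123.9,20.0,17.7,9.3,116.4,22.0
Khaan,mAMP,1782.5,27.5,58.3,9.4,40.4,7.7,44.0,8.3
Khaan,mPSTp,1440.0,34.8,37.2,6.0,39.5,22.5,26.6,5.0
Khaan,mPSTs,2260.5,49.3,41.3,6.7,27.0,2.7,36.8,7.0
Khaan,mPTd,1679.5,30.4,49.7,8.0,47.2,12.7,33.0,6.2
Khaan,mPTv,3900.0,23.6,148.9,24.0,14.9,19.2,135.8,25.7
Conchoraptor,mAMEM,2141.5,46.9,41.1,9.4,26.9,2.0,36.6,9.3
Conchoraptor,mAMEP,2950.5,44.5,59.7,13.7,33.4,7.0,49.5,12.7
Conchoraptor,mAMES,4071.0,46.1,79.6,18.3,18.8,6.6,74.8,19.1
Conchoraptor,mAMP,1573.0,27.9,50.8,11.7,24.9,1.6,46.0,11.8
Conchoraptor,mPSTp,786.0,31.1,22.7,5.2,17.1,9.8,21.4,5.5
Conchoraptor,mPSTs,1678.5,47.5,31.8,7.3,22.6,4.1,29.3,7.5
Conchoraptor,mPTd,1096.5,34.2,28.8,6.6,38.6,8.0,22.3,5.7
Conchoraptor,mPTv,3528.0,26.4,120.3,27.7,14.0,17.9,111.1,28.4
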