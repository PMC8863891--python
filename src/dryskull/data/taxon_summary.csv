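taxon,outlever_anterior_mm,outlever_mid_palate_mm,outlever_posterior_mm,sum_volume_mm3,sum_fmus_N,sum_fres_N,bite_sum_anterior_N,bite_sum_mid_palate_N,bite_sum_posterior_N,scaled_pct_anterior,scaled_pct_mid_palate,scaled_pct_posterior,ma_anterior,ma_mid_palate,ma_posterior,fres_fmus_ratio,relative_csa,gape_optimal_deg,gape_maximum_deg,constraining_cylinder,mdm_factor_optimal,mdm_factor_rest
Incisivosaurus,90.4,71.6,58.1,9161.7,251.5,224.7,53.0,67.0,82.5,,,,0.236,0.298,0.367,0.894,0.0121,25.0,49.5,mPTv1,1.08,1.20
Citipati,142.0,122.0,99.4,79389.5,1349.9,1155.9,349.3,406.5,499.0,84,69,69,0.302,0.352,0.432,0.856,0.0180,21.0,41.0,mAMES1,1.11,1.33
Khaan,103.6,88.7,72.0,25864.0,620.7,528.0,137.3,160.4,197.6,54,42,42,0.260,0.304,0.374,0.851,0.0177,20.5,40.0,mPTv1,1.16,1.48
Conchoraptor,85.8,76.9,58.3,17825.0,434.9,391.1,106.7,119.0,157.0,32,17,25,0.273,0.304,0.401,0.899,0.0137,23.0,46.0,mPTv1,1.19,1.67
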