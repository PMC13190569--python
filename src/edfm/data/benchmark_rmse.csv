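model_type,model,height_rmse_mm,lai_rmse_pct,leaf_length_r2,leaf_width_r2,weight_peak
Traditional,WOFOST,12.6,22.5,0.752,0.698,
Multimodal,GAMF,5.1,12.5,0.876,0.832,0.42
Multimodal,YOLO-DBM,6.3,15.8,0.812,0.785,0.55
This study,EDFM,3.2,8.2,0.985,0.944,0.68
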