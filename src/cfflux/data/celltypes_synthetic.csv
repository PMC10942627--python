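name,turnover_median,turnover_factor,ploidy,shed_externally,fraction_median,fraction_factor
erythrocyte_progenitors,2e11,1.3,2,false,0.09,1.6
neutrophils,9e10,1.4,2,false,0.32,1.5
lymphocytes,1e10,2.0,2,false,0.12,1.8
gut_epithelium,1e10,2.0,2,true,,
monocytes_macrophages,7e9,2.0,2,false,0.105,1.6
lung_epithelium,2e9,2.0,2,true,,
kidney_epithelium,1.5e9,2.0,2,true,,
skin_keratinocytes,1e9,2.0,2,true,,
breast_epithelium,1e9,2.5,2,false,,
hepatocytes,3e8,1.8,2.7,false,0.011,2.0
skeletal_myocytes,2.5e8,2.0,2,false,,
endothelial_cells,2e8,2.0,2,false,0.088,1.8
bladder_epithelium,2e8,2.0,2,true,,
megakaryocytes,7.4e7,1.8,16,false,0.26,1.5
adipocytes,5e7,2.0,2,false,,
cardiomyocytes,5e4,2.5,2,false,,
pancreatic_beta_cells,3e4,3.0,2,false,,
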