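subject_id,COOC_second_angular_moment,COOC_contrast,COOC_entropy,COOC_homogeneity,COOC_dissimilarity,COOC_inverse_difference_moment,VA_short_run_emphasis,VA_long_run_emphasis,VA_intensity_variability,VA_run_length_variability,VA_run_percentage,VA_low_intensity_run_emphasis,VA_high_intensity_run_emphasis,VA_low_intensity_short_run_emphasis,VA_high_intensity_short_run_emphasis,VA_low_intensity_long_run_emphasis,VA_high_intensity_long_run_emphasis,NID_coarseness,NID_contrast,NID_busyness,NID_complexity,NID_strength,ISZ_short_zone_emphasis,ISZ_large_zone_emphasis,ISZ_intensity_variability,ISZ_size_zone_variability,ISZ_zone_percentage,ISZ_low_intensity_zone_emphasis,ISZ_high_intensity_zone_emphasis,ISZ_low_intensity_short_zone_emphasis,ISZ_high_intensity_short_zone_emphasis,ISZ_low_intensity_large_zone_emphasis,ISZ_high_intensity_large_zone_emphasis,NCOOC_second_angular_moment,NCOOC_contrast,NCOOC_entropy,NCOOC_homogeneity,NCOOC_inverse_difference_moment,NCOOC_dissimilarity,NCOOC_correlation,STAT_suv_min,STAT_suv_max,STAT_suv_mean,STAT_suv_variance,STAT_suv_sd,STAT_suv_skewness,STAT_suv_kurtosis,STAT_suv_skewness_bias_corrected,STAT_suv_kurtosis_bias_corrected,STAT_tlg,STAT_tumor_volume,STAT_entropy,STAT_sul_peak,TS_max_spectrum,TS_black_white_symmetry,TFC_coarseness,TFC_homogeneity,TFC_mean_convergence,TFCC_second_angular_moment,TFCC_contrast,TFCC_entropy,TFCC_homogeneity,TFCC_intensity,TFCC_inverse_difference_moment,TFCC_correlation,TFCC_variance,TFCC_code_similarity,NGLD_small_number_emphasis,NGLD_large_number_emphasis,NGLD_number_nonuniformity,NGLD_second_moment,NGLD_entropy
golden_phantom,0.00755738896531,264.98215348,8.06196835259,0.403132968858,9.24211778703,0.362246529582,0.886070231433,1.5574501574,171.853620147,2830.36411333,0.854900201839,0.0103310159377,1748.14559286,0.0100685999268,1543.80852236,0.0114664782687,2745.06505771,0.00983995193334,2.61344307736,0.0637885551584,7345.38428831,16.3996313631,0.457290971558,84.203125,2.1875,13.5,0.186588921283,0.0323299593843,1560.84375,0.0274327114123,569.698576512,0.16173713906,156878.03125,0.00755738896531,1.16999324177,8.06196835259,0.754189424178,0.769226653101,0.614122293372,0.415003379117,2.83982617527,6.43424004887,5.00460117036,0.724446742799,0.851144372477,-0.234655464614,2.42414851676,-0.235687422257,2.4333640219,125.13340115,25.003671,4.6800554055,6.03809711259,0.0393700787402,0.141732283465,0,0.0217620435241,0.863294580344,0.000927689568565,7653.41969407,10.3533415785,0.0621809708471,30027.5745698,0.034396299815,0.0105558046101,3867.53478859,0.019120458891,0.147153191217,30.0903790087,40.4810495627,0.00997033548946,6.85693361096
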