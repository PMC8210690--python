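dataset_id,workflow,mean_sngfr_nl_min,sd_nl_min,relative_sd_percent
Dataset 1,previous,1.783,1.057,59.254
Dataset 2,previous,2.476,0.581,23.451
Dataset 3,previous,2.296,1.123,48.900
Dataset 4,previous,0.606,0.211,34.862
Dataset 5,previous,1.441,0.207,14.355
Dataset 6,previous,1.871,1.367,73.039
Dataset 7,previous,0.995,0.204,20.535
Dataset 8,previous,1.039,0.433,41.661
Dataset 9,previous,2.732,1.456,53.306
Dataset 10,previous,1.200,0.356,29.644
Dataset 11,previous,2.393,0.347,14.505
Dataset 12,previous,1.359,0.666,48.997
Dataset 13,previous,1.628,0.460,28.242
Dataset 14,previous,3.746,1.603,42.805
Dataset 15,previous,0.176,0.084,47.642
Dataset 1,extended,1.724,0.132,7.675
Dataset 2,extended,1.611,0.075,4.676
Dataset 3,extended,2.587,0.125,4.842
Dataset 4,extended,1.128,0.147,13.012
Dataset 5,extended,1.012,0.151,14.968
Dataset 6,extended,0.987,0.127,12.873
Dataset 7,extended,0.851,0.077,9.078
Dataset 8,extended,2.600,0.304,11.708
Dataset 9,extended,2.648,0.593,22.375
Dataset 10,extended,1.600,0.116,7.254
Dataset 11,extended,1.811,0.113,6.265
Dataset 12,extended,2.987,0.124,4.139
Dataset 13,extended,2.477,0.091,3.665
Dataset 14,extended,0.717,0.176,24.566
Dataset 15,extended,0.814,0.067,8.225
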