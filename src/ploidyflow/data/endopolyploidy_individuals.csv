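taxon,accession,individual,pct_2c,pct_4c,pct_8c,pct_16c,pct_32c,pct_64c,n_endocycles,cycle_value
E. catorce,5469,1,17.99,23.72,13.82,29.15,15.31,,3,2.001
E. catorce,5469,2,13.22,21.31,9.25,21.00,30.99,4.23,4,2.479
E. olivacea,6402,1,22.34,13.91,14.54,40.13,9.08,,3,1.997
E. olivacea,6402,2,17.54,19.40,10.71,14.71,31.55,6.10,4,2.416
E. juarezensis,7538,1,27.15,35.07,19.16,12.37,6.26,,3,1.355
E. juarezensis,7538,2,15.66,16.68,12.86,16.48,27.96,10.36,4,2.555
E. perezcalixii,6322,1,25.67,24.13,14.29,16.62,19.28,,3,1.797
E. perezcalixii,6322,2,40.96,19.81,11.73,11.15,11.35,5.00,4,1.471
E. longiflora,6923,1,42.54,19.67,21.98,15.80,,,2,1.110
E. longiflora,6013,2,50.84,15.29,9.49,21.91,2.46,,3,1.099
E. roseiflora,6744,1,37.57,48.36,14.07,,,,1,0.765
E. roseiflora,6744,2,37.50,33.51,23.96,5.03,,,2,0.965
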