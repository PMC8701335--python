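taxon,accession,pct_2c,pct_4c,pct_8c,pct_16c,pct_32c,pct_64c,endocycles_label,cycle_value,two_level,aggregate_discordant,rounding_tie
E. schaffneri,54,8.80,25.71,10.55,18.23,28.84,7.87,4,2.562,0,0,0
E. catorce,3223,12.49,19.00,11.25,22.68,27.18,7.39,4,2.552,0,0,0
E. cuicatecana,584,20.23,11.89,10.83,22.83,28.38,5.84,4,2.448,0,0,0
E. olivacea,6402,22.34,13.91,14.54,40.13,9.08,,3 or 4,2.207,1,0,0
E. catorce,5469,17.99,23.72,13.82,29.15,15.31,,3 or 4,2.240,1,0,0
E. juarezensis,7538,27.15,35.07,19.16,12.37,6.26,,3 or 4,2.155,1,1,0
E. helmutiana,7075,12.34,21.65,13.61,31.97,20.44,,3,2.265,0,0,0
E. caamanoi,8311,22.61,25.59,10.96,12.79,23.68,4.37,4,2.024,0,0,1
E. uhlii,8553,16.77,13.81,30.48,31.62,7.33,,3,1.989,0,0,0
E. magnifica,6270,19.36,18.96,16.42,35.54,9.71,,3,1.973,0,0,0
E. guerrerensis,7526,19.50,27.19,18.70,13.42,16.90,4.30,4,1.939,0,0,0
E. carnicolor,8374,26.29,15.11,22.60,27.03,8.97,,3,1.773,0,0,0
E. zorzaniana,7237,26.34,16.28,17.49,34.34,5.56,,3,1.765,0,0,0
E. perezcalixii,6322,25.67,24.13,14.29,16.62,19.28,,3 or 4,1.688,1,1,0
E. novogaliciana,6823,16.31,28.60,36.25,18.85,,,2,1.576,0,0,0
E. gibbiflora,3427,35.77,27.16,16.38,14.20,6.48,,3,1.285,0,0,0
E. multicaulis,7501,26.42,32.98,36.26,4.34,,,2,1.185,0,0,0
E. dactylifera,2603,41.23,22.07,18.03,16.91,1.75,,3,1.159,0,0,0
E. pallida,6475,38.75,18.93,14.12,17.18,11.02,,3,1.428,0,0,0
E. guerrerensis,7521,40.24,21.71,16.74,13.97,7.33,,3,1.264,0,0,0
E. triquiana,6396,29.81,30.11,31.93,8.15,,,2,1.184,0,0,0
E. altamirae,7548,39.49,22.33,20.97,17.21,,,2,1.159,0,0,0
E. longiflora,6923,42.54,19.67,21.98,15.80,,,2 or 3,1.105,1,0,0
E. cupreata,6807,65.65,16.91,6.08,5.55,5.81,,3,0.690,0,0,0
E. roseiflora,6744,37.57,48.36,14.07,,,,1 or 2,0.815,1,1,0
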