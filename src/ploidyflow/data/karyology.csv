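species,accession,series,two_n,x,multiplier,aneuploid_extra,standard,two_c_pg,two_c_se,one_cx_mbp,mbp_off_by_one
E. roseiflora,6744,Gibbiflorae,270,27,10,0,pea,7.70,0.10,753,0
E. novogaliciana,6823,Gibbiflorae,176,27,6,14,pea,5.81,0.06,947,0
E. gibbiflora,3427,Gibbiflorae,172,27,6,10,maize,3.68,0.05,599,1
E. altamirae,7548,Gibbiflorae,108,27,4,0,maize,3.54,0.10,865,1
E. perezcalixii,6322,Gibbiflorae,54,27,2,0,tomato,2.96,0.05,1447,0
E. dactylifera,2603,Gibbiflorae,108,27,4,0,maize,2.90,0.10,709,0
E. guerrerensis,7521,Gibbiflorae,54,27,2,0,pea,2.88,0.10,1408,0
E. helmutiana,7075,Racemosae,42,21,2,0,pea,2.81,0.10,1374,0
E. pallida,6475,Gibbiflorae,54,27,2,0,tomato,2.79,0.07,1364,0
E. guerrerensis,7526,Gibbiflorae,54,27,2,0,pea,2.73,0.10,1335,0
E. longiflora,6923,Gibbiflorae,162,27,6,0,pea,2.54,0.06,414,0
E. cupreata,6807,Gibbiflorae,108,27,4,0,pea,2.50,0.07,611,0
E. cuicatecana,584,Pruinosae,60,12,5,0,maize,2.44,0.05,477,0
E. uhlii,8553,Racemosae,54,27,2,0,maize,2.36,0.04,1154,0
E. carnicolor,8374,Racemosae,36,18,2,0,maize,2.31,0.10,1130,0
E. triquiana,6396,Gibbiflorae,32,16,2,0,maize,2.07,0.10,1012,0
E. olivacea,6402,Racemosae,28,14,2,0,maize,1.96,0.02,958,0
E. caamanoi,8311,Urbinae,60,12,5,0,maize,1.95,0.06,381,0
E. schaffneri,54,Angulatae,24,12,2,0,maize,1.50,0.09,733,1
E. zorzaniana,7237,Echeveria,40,20,2,0,maize,1.49,0.00,729,0
E. multicaulis,7501,Nudae,32,16,2,0,tomato,1.40,0.07,685,0
E. magnifica,6270,Gibbiflorae,54,27,2,0,tomato,1.36,0.05,665,0
E. juarezensis,7538,Gibbiflorae,54,27,2,0,tomato,1.31,0.06,641,0
E. catorce,5469,Angulatae,24,12,2,0,tomato,1.29,0.02,631,0
E. catorce,3223,Angulatae,24,12,2,0,tomato,1.26,0.02,616,0
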