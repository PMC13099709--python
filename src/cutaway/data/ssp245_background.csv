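year,co2_ppm,ch4_ppb,n2o_ppb
2020,412,1880,333
2030,435,1940,340
2040,460,1970,347
2050,486,1960,354
2060,508,1920,360
2070,524,1860,365
2080,532,1800,368
2090,536,1740,370
2100,538,1700,372
2110,539,1680,373
2120,540,1670,374
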