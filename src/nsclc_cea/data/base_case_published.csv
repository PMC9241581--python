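# Published base-case totals (2019 GBP) of the original evaluation of the
# 12 first-line strategies; used for incremental-arithmetic and frontier
# cross-checks against this package's own frontier algorithm.
country,arm,cost,qaly,ly
UK,gefitinib,24529,1.130,2.571
UK,osimertinib,139483,1.762,3.485
UK,afatinib,51865,1.255,2.899
UK,dacomitinib,155510,1.475,3.080
UK,erlotinib,27237,1.177,2.554
UK,afatinib_cetuximab,92935,1.113,2.535
UK,erlotinib_bevacizumab,106486,1.541,2.950
UK,gefitinib_pemetrexed,33221,1.401,3.080
UK,gefitinib_pbct,44445,1.687,3.632
UK,pbct,31595,0.861,2.426
UK,pfct,24999,0.744,2.607
China,gefitinib,12961,1.312,2.572
China,osimertinib,25459,1.935,3.485
China,afatinib,21478,1.469,2.900
China,icotinib,18308,1.254,2.482
China,dacomitinib,22517,1.656,3.081
China,erlotinib,19270,1.340,2.554
China,afatinib_cetuximab,52380,1.297,2.536
China,erlotinib_bevacizumab,58504,1.673,2.951
China,gefitinib_pemetrexed,16873,1.606,3.081
China,gefitinib_pbct,21545,1.918,3.633
China,pbct,16066,1.101,2.427
China,pfct,14780,1.061,2.607
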