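# Published base-case results (cost USD / discounted life years / discounted
# QALYs per strategy and PD-L1 stratum) from the original US-payer analysis
# this package re-implements.  Used as *inputs* to the frontier machinery:
# feeding the printed triples through compute_frontier must reproduce the
# printed dominance labels and frontier ICERs.
# check_icer=0 marks the one printed ICER whose QALY increment (0.06) is too
# coarsely rounded for recomputation from printed precision.
stratum,strategy,cost,life_years,qalys,label,icer_ly,icer_qaly,check_icer
all,chemotherapy,139820,1.86,1.39,reference,,,1
all,nivo_ipi,278126,2.65,2.02,weakly_dominated,,,1
all,atezo_chemo,282282,2.48,1.89,strongly_dominated,,,1
all,nivo_ipi_chemo,322647,2.97,2.24,weakly_dominated,,,1
all,pembro_chemo,363468,3.44,2.61,on_frontier,141790,183299,1
all,atezo_beva_chemo,469555,3.07,2.39,strongly_dominated,,,1
lt1,chemotherapy,116112,1.54,1.15,reference,,,1
lt1,atezo_chemo,226251,2.00,1.51,weakly_dominated,,,1
lt1,atezo_beva_chemo,231254,2.09,1.57,weakly_dominated,,,1
lt1,pembro_chemo,248009,2.39,1.79,weakly_dominated,,,1
lt1,nivo_ipi,264556,2.75,2.07,on_frontier,122691,161277,1
lt1,nivo_ipi_chemo,312575,2.84,2.13,on_frontier,567261,881975,0
1to49,chemotherapy,142188,1.72,1.30,reference,,,1
1to49,pembrolizumab,183856,1.90,1.47,weakly_dominated,,,1
1to49,atezo_chemo,276079,1.97,1.51,weakly_dominated,,,1
1to49,nivo_ipi,290386,1.90,1.48,strongly_dominated,,,1
1to49,nivo_ipi_chemo,345346,2.77,2.10,weakly_dominated,,,1
1to49,pembro_chemo,360991,3.02,2.30,on_frontier,168878,218159,1
ge50,chemotherapy,151703,2.10,1.57,reference,,,1
ge50,pembrolizumab,228390,3.12,2.37,on_frontier,74908,96189,1
ge50,nivo_ipi,321222,3.19,2.47,weakly_dominated,,,1
ge50,nivo_ipi_chemo,343656,3.38,2.57,weakly_dominated,,,1
ge50,atezo_chemo,401628,3.68,2.83,weakly_dominated,,,1
ge50,pembro_chemo,558990,5.20,4.03,on_frontier,159541,198913,1
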