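# Published cost inputs for the two case-study drugs: unadjusted source-currency
# amounts and the corresponding launch-year-EUR values (2015 = daratumumab
# launch, 2014 = pembrolizumab launch). Transcribed table; validated by
# cbpricer.adjustment.check_factor_consistency.
source_label,input_label,unadjusted_usd,adjusted_2015_eur,adjusted_2014_eur
wouters2020,rd_base,4461200000,3795249282,3165890999
wouters2020,rd_ci_low,3114000000,2649154098,2209850393
wouters2020,rd_ci_high,6001300000,5105449097,4258823109
wouters2020,rd_uncapitalized,1032000000,877947023,732358897
wouters2020,new_indication_aim,446120000,379524928,316589100
nosengo2016,new_indication_base,300000000,267020244,222740834
ouyang2019,manufacturing_base,51,42.61,35.55
kelly2009_low,manufacturing_low,26,25.89,21.59
kelly2009_high,manufacturing_high,134,133.43,111.30
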