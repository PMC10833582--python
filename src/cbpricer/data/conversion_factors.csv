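# Conversion factors: source-currency/source-year amount -> launch-year EUR.
# Derived as adjusted/unadjusted ratios of the published cost-input table
# (one anchor row per source and target year); not recomputed from PPP/CPI
# series, which the source publication does not print.
source_label,source_currency,target_year,factor,note
wouters2020,USD,2015,0.8507238594996862,derived from capitalized R&D base-case row
wouters2020,USD,2014,0.7096500939209182,derived from capitalized R&D base-case row
nosengo2016,USD,2015,0.89006748,derived from per-new-indication R&D base-case row
nosengo2016,USD,2014,0.7424694466666667,derived from per-new-indication R&D base-case row
ouyang2019,USD,2015,0.8354901960784313,derived from manufacturing-cost base-case row
ouyang2019,USD,2014,0.6970588235294117,derived from manufacturing-cost base-case row
kelly2009_low,USD,2015,0.9957692307692307,derived from low manufacturing-cost row
kelly2009_low,USD,2014,0.8303846153846154,derived from low manufacturing-cost row
kelly2009_high,USD,2015,0.9957462686567164,derived from high manufacturing-cost row
kelly2009_high,USD,2014,0.8305970149253731,derived from high manufacturing-cost row
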