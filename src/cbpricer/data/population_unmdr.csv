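# SYNTHETIC reconstruction of the United Nations "more developed regions"
# (Europe, North America, Australia/New Zealand, Japan) population aggregate:
# a smooth series of plausible magnitude (~1.27 billion, near-stationary with
# a shallow peak in the early 2020s). It is NOT the UN World Population
# Prospects output; the packaged drug profiles are calibrated against this
# table, so all packaged results are self-consistent with it.
region,year,persons
UN-MDR,2014,1271570000
UN-MDR,2015,1272080000
UN-MDR,2016,1272530000
UN-MDR,2017,1272920000
UN-MDR,2018,1273250000
UN-MDR,2019,1273520000
UN-MDR,2020,1273730000
UN-MDR,2021,1273880000
UN-MDR,2022,1273970000
UN-MDR,2023,1274000000
UN-MDR,2024,1273970000
UN-MDR,2025,1273880000
UN-MDR,2026,1273730000
UN-MDR,2027,1273520000
UN-MDR,2028,1273250000
UN-MDR,2029,1272920000
UN-MDR,2030,1272530000
UN-MDR,2031,1272080000
UN-MDR,2032,1271570000
UN-MDR,2033,1271000000
UN-MDR,2034,1270370000
UN-MDR,2035,1269680000
UN-MDR,2036,1268930000
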