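# Synthetic ontogenetic density-ratio schedule (larva density / seawater
# density at the upper thermocline) versus developmental age fraction
# (age / pelagic larval duration).  This is a synthetic stand-in table,
# constructed, not measured: the age-0 ratio corresponds to an initial
# Stokes buoyancy of ~8.5 m/day (density deficit 4.51 kg/m3 at a seawater
# density of 1024.4 kg/m3) decaying smoothly to neutral buoyancy by
# mid-development, the qualitative pattern measured for pre-metamorphic
# anguillid leptocephali.  Any user table with the same columns may be
# substituted.
age_fraction,density_ratio
0.00,0.99560
0.05,0.99610
0.10,0.99665
0.15,0.99720
0.20,0.99775
0.25,0.99830
0.30,0.99880
0.35,0.99920
0.40,0.99950
0.45,0.99972
0.50,0.99987
0.55,0.99995
0.60,1.00000
0.70,1.00000
0.80,1.00000
0.90,1.00000
1.00,1.00000
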