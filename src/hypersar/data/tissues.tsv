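# Tissue dielectric properties at 915 MHz (IT'IS database values).
# name	density_kg_m3	rel_permittivity	conductivity_S_m
air	1	1.0	0.0
di_water	1000	78.2	0.18
fat	911	11.3	0.11
bone	1908	12.4	0.15
muscle	1090	55.0	0.95
white_matter	1041	38.8	0.60
brain_average	1043	45.8	0.77
gray_matter	1045	52.7	0.95
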