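# Three-ring phased-array brain applicator (915 MHz, 72 dipole antennas).
ring_radius_cm: 13.0
ring_gap_cm: 4.2
antennas_per_ring: 24
n_rings: 3
frequency_hz: 915.0e6
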