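"""Physical constants (SI units)."""

SPEED_OF_LIGHT = 2.9979e8
"""Speed of light in vacuum, m/s."""

VACUUM_PERMITTIVITY = 8.854e-12
"""Vacuum permittivity epsilon_0, F/m."""

DEFAULT_FREQUENCY_HZ = 915.0e6
"""Operating frequency of the brain applicator, Hz."""
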