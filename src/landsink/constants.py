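"""Physical constants and declared defaults for the carbon budget pipeline.

None of the transport or stoichiometric defaults below is a measured value
specific to one study; they are community-standard conventions, and every
routine that uses them accepts overrides and records the values actually
used in its run metadata.
"""

# Two-box atmospheric transport
TAU_DEFAULT = 1.3
"""Interhemispheric exchange time (years)."""

KAPPA_GLOBAL_DEFAULT = 2.124
"""Whole-atmosphere conversion factor, Pg C per ppm CO2."""

FF_NORTH_FRACTION_DEFAULT = 0.94
"""Fraction of fossil fuel emissions released in the Northern Hemisphere."""

OCEAN_NORTH_FRACTION_DEFAULT = 0.45
"""Fraction of the anthropogenic ocean sink in the Northern Hemisphere
(the SH ocean sink is somewhat larger than the NH one)."""

# O2 budget stoichiometry (molar O2 : C ratios)
ALPHA_F_DEFAULT = 1.38
"""Oxidative ratio of fossil fuel combustion, mol O2 consumed per mol C."""

ALPHA_B_DEFAULT = 1.10
"""Oxidative ratio of terrestrial biosphere carbon, mol O2 released per
mol C stored."""

O2_MOLE_FRACTION = 0.20946
"""Mole fraction of O2 in dry air."""

AIR_MOLES = 1.769e20
"""Total moles of dry air in the atmosphere."""

GRAMS_C_PER_MOL = 12.0

# Unit bridges
MG_PER_PG = 1.0e9
"""Megagrams per petagram (1 Pg = 1e9 Mg = 1e15 g)."""

EARTH_RADIUS_M = 6.371e6

# Forest-inventory scale-factor presets (documented config options only;
# the pipeline default derives S from an ensemble instead).
S_PRESET_TROPICAL = 1.25
S_PRESET_TEMPERATE = 1.45
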