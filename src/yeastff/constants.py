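"""Physical constants and unit conversions shared across the package.

All intracellular balances are expressed in mM on a cytosolic-volume basis;
reaction rates in mM s^-1 (cytosolic volume).  Conversion to a biomass basis
uses the biomass specific volume below.
"""

#: Cell volume per gram biomass dry weight (L gDW^-1).
BIOMASS_SPECIFIC_VOLUME_L_PER_GDW = 0.002

#: Molar mass of glucose (g mol^-1); used for g/L <-> mM conversions.
MW_GLUCOSE = 180.156

#: Seconds per hour (dilution rates are configured in h^-1).
SECONDS_PER_HOUR = 3600.0


def glc_g_per_l_to_mm(value_g_per_l: float) -> float:
    """Convert a glucose concentration from g L^-1 to mM."""
    return value_g_per_l / MW_GLUCOSE * 1000.0


def glc_mm_to_g_per_l(value_mm: float) -> float:
    """Convert a glucose concentration from mM to g L^-1."""
    return value_mm * MW_GLUCOSE / 1000.0
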