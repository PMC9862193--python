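"""Kinetic rate-law families.

Every function accepts plain floats or numpy arrays (broadcasting) and
returns rates in mM s^-1 on a cytosolic-volume basis.  Concentration
arguments must be non-negative; constants strictly positive unless noted.

The forms used here:

* facilitated diffusion (glucose transport, equilibrium constant 1) with an
  optional extracellular-glucose threshold that shuts uptake off below a
  minimum concentration (the glucose-sensing proxy),
* reversible/irreversible uni-uni Michaelis-Menten with an optional
  multiplicative ``1/(1 + I/Ki)`` inhibition factor,
* a two-state (tense/relaxed) allosteric law for PFK,
* Hill laws for PYK (with fructose-1,6-bisphosphate activation) and PDC,
* an ordered bi-bi rational law for UDP-glucose pyrophosphorylase,
* phenomenological, table-interpolated glycogen synthesis/degradation with a
  substrate saturation factor.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "rate_hxt",
    "rate_mm_rev",
    "rate_mm_irrev",
    "rate_mm_irrev_bi",
    "rate_rev_bibi",
    "rate_pfk",
    "rate_hill",
    "rate_pyk",
    "rate_ugp",
    "rate_glycogen",
    "rate_adk",
    "inhibition_factor",
]


def inhibition_factor(inhibitor, ki):
    """Multiplicative inhibition ``1/(1 + I/Ki)``; ``ki=None`` disables it."""
    if ki is None:
        return 1.0
    return 1.0 / (1.0 + inhibitor / ki)


def rate_hxt(glc_ec, glc_i, vmax, km, ki, keq=1.0, glc_ec_min=0.0, sensing=True):
    """Facilitated-diffusion hexose transport with optional sensing threshold.

    With sensing on, the effective extracellular glucose is
    ``max(glc_ec - glc_ec_min, 0)`` (continuous piecewise-linear clamp);
    with sensing off it is ``glc_ec`` itself.  The net rate vanishes when the
    effective transmembrane gradient vanishes (``keq = 1``).
    """
    s2 = np.maximum(glc_ec - glc_ec_min, 0.0) if sensing else glc_ec
    num = (vmax / km) * (s2 - glc_i / keq)
    den = 1.0 + s2 / km + glc_i / km + (s2 * glc_i) / (ki * km * km)
    return num / den


def rate_mm_rev(s, p, vmax, km_s, km_p, keq, inhibitor=0.0, ki=None):
    """Reversible uni-uni Michaelis-Menten; sign follows the thermodynamic
    gradient.  Optional competitive-style multiplicative inhibition."""
    num = (vmax / km_s) * (s - p / keq)
    den = 1.0 + s / km_s + p / km_p
    return num / den * inhibition_factor(inhibitor, ki)


def rate_mm_irrev(s, vmax, km, inhibitor=0.0, ki=None):
    """Irreversible Michaelis-Menten, always >= 0 for s >= 0."""
    return vmax * s / (km + s) * inhibition_factor(inhibitor, ki)


def rate_mm_irrev_bi(a, b, vmax, km_a, km_b, inhibitor=0.0, ki=None):
    """Irreversible two-substrate MM as a product of saturation terms."""
    return (
        vmax * (a / (km_a + a)) * (b / (km_b + b)) * inhibition_factor(inhibitor, ki)
    )


def rate_rev_bibi(a, b, p, q, vmax, km_a, km_b, km_p, km_q, keq):
    """Reversible bi-bi rational law (random-order convenience form)."""
    num = (vmax / (km_a * km_b)) * (a * b - p * q / keq)
    den = (1.0 + a / km_a) * (1.0 + b / km_b) + (1.0 + p / km_p) * (1.0 + q / km_q) - 1.0
    return num / den


def rate_pfk(f6p, atp, amp, vmax, km_f6p, km_atp, n, l0, ki_atp, ka_amp):
    """Two-state (T/R) allosteric PFK.

    Monod-Wyman-Changeux form: the allosteric constant ``L`` is raised by ATP
    (inhibitor, favouring the tense state) and lowered by AMP (activator),
    each through a saturation ratio raised to the number of sites ``n``.
    """
    lam = f6p / km_f6p
    big_l = l0 * ((1.0 + atp / ki_atp) / (1.0 + amp / ka_amp)) ** n
    occupancy = lam * (1.0 + lam) ** (n - 1.0) / ((1.0 + lam) ** n + big_l)
    return vmax * occupancy * atp / (km_atp + atp)


def rate_hill(s, vmax, k05, n):
    """Hill law ``vmax * s^n / (k05^n + s^n)``; ``n = 1`` reduces to MM."""
    sn = s**n
    return vmax * sn / (k05**n + sn)


def rate_pyk(pep, adp, fbp, vmax, k05, n, ka_fbp, km_adp):
    """Hill-type pyruvate kinase with FBP activation.

    FBP lowers the half-saturation constant (``k05 / (1 + FBP/Ka)``), so the
    rate is strictly increasing in FBP at fixed substrate concentrations.
    """
    k_eff = k05 / (1.0 + fbp / ka_fbp)
    return rate_hill(pep, vmax, k_eff, n) * adp / (km_adp + adp)


def rate_ugp(g1p, utp_proxy, udpg, pi, vmax, km_g1p, km_atp, km_udpg, ki_g1p, keq):
    """Ordered bi-bi law for UDP-glucose pyrophosphorylase.

    The nucleotide substrate is proxied by ATP.  The net rate changes sign
    when the product term ``UDPG * Pi / Keq`` dominates the substrate term.
    """
    num = vmax * (g1p * utp_proxy - udpg * pi / keq)
    den = (ki_g1p * km_atp + km_atp * g1p + km_g1p * utp_proxy + g1p * utp_proxy) * (
        1.0 + udpg / km_udpg
    )
    return num / den


def rate_glycogen(t, s, table_t, table_v, k_sat, period=None):
    """Phenomenological glycogen flux: table interpolation times saturation.

    ``v(t) = interp(t) * s / (s + k_sat)``.  ``table_t`` must be increasing
    and cover the cycle; with ``period`` set, ``t`` is wrapped periodically,
    otherwise values outside the table range raise ``ValueError``.
    """
    t = np.asarray(t, dtype=float)
    if period is not None:
        t = np.mod(t, period)
    else:
        if np.any(t < table_t[0]) or np.any(t > table_t[-1]):
            raise ValueError(
                f"time {t} outside interpolation table range "
                f"[{table_t[0]}, {table_t[-1]}] and no period given"
            )
    base = np.interp(t, table_t, table_v)
    out = base * s / (s + k_sat)
    return float(out) if out.ndim == 0 and np.isscalar(s) else out


def rate_adk(atp, adp, amp, k, keq):
    """Adenylate kinase mass action: ``k (ADP^2 - ATP*AMP/Keq)``."""
    return k * (adp * adp - atp * amp / keq)
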