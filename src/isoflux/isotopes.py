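"""Delta notation for natural-abundance nitrogen isotope ratios.

All isotopic abundances in this package are expressed in the conventional
delta notation, i.e. parts-per-thousand deviations of the sample
:sup:`15`\\ N/:sup:`14`\\ N ratio from that of atmospheric N2::

    delta15N = 1000 * (R_sample / R_standard - 1)

Discrimination factors (``Delta15N``) are diet-referenced deltas,
``Delta15N_pool = delta15N_pool - delta15N_diet``, so that the dietary
baseline cancels when comparing pools of one animal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 15N/14N isotope ratio of atmospheric N2 (the international standard).
R_STANDARD = 0.0036765


@dataclass(frozen=True)
class IsotopeConstants:
    """Reference constants for delta <-> ratio conversions.

    Parameters
    ----------
    r_standard:
        Isotope ratio of the standard (atmospheric N2 by default).
    delta_diet:
        delta15N of the diet (permil vs the standard); used to convert
        absolute deltas into diet-referenced discrimination factors.
    """

    r_standard: float = R_STANDARD
    delta_diet: float = 0.0

    def __post_init__(self) -> None:
        if self.r_standard <= 0:
            raise ValueError("r_standard must be positive")

    def discrimination(self, delta):
        """Delta15N of a pool: its delta15N minus the dietary delta15N."""
        return np.asarray(delta, dtype=float) - self.delta_diet


def delta_from_ratio(r_sample, r_standard: float = R_STANDARD):
    """Convert an isotope ratio to a delta value (permil).

    Raises
    ------
    ValueError
        If any ratio is non-positive (a ratio of heavy to light isotope
        amounts is strictly positive by construction).
    """
    r = np.asarray(r_sample, dtype=float)
    if np.any(r <= 0):
        raise ValueError("isotope ratio must be positive")
    out = 1000.0 * (r / r_standard - 1.0)
    return float(out) if np.isscalar(r_sample) else out


def ratio_from_delta(delta, r_standard: float = R_STANDARD):
    """Exact inverse of :func:`delta_from_ratio`."""
    d = np.asarray(delta, dtype=float)
    out = r_standard * (1.0 + d / 1000.0)
    return float(out) if np.isscalar(delta) else out


def atom_fraction_from_delta(delta, r_standard: float = R_STANDARD):
    """15N atom fraction of a pool with the given delta15N."""
    r = ratio_from_delta(delta, r_standard)
    return r / (1.0 + r)


def delta_from_atom_fraction(x, r_standard: float = R_STANDARD):
    """delta15N of a pool with 15N atom fraction ``x`` (0 < x < 1)."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("atom fraction must lie strictly between 0 and 1")
    out = delta_from_ratio(x / (1.0 - x), r_standard)
    return float(out) if np.ndim(out) == 0 else out
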