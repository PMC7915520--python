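"""Map-function arithmetic shared by the simulator and the map builder.

Genetic distances are handled on two scales:

* the *meiotic* recombination fraction ``r`` between two loci in a single
  meiosis, related to map distance through the Kosambi map function; and
* the *observed* recombination fraction ``R`` between the fully inbred
  genotypes of selfed recombinant inbred lines (RILs), which accumulates
  recombination over the selfing generations: ``R = 2r / (1 + 2r)``.

All public functions accept scalars or numpy arrays and are exact inverses
of each other (up to the clamping applied near the 0.5 singularity).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kosambi_cm_to_r",
    "kosambi_r_to_cm",
    "ril_r_from_meiotic",
    "meiotic_r_from_ril",
    "ril_r_from_cm",
    "cm_from_ril_r",
]

# meiotic r is clamped just below 0.5 so cm_from_ril_r stays finite for
# unlinked marker pairs (R -> 0.5 implies r -> 0.5, infinite Kosambi distance)
_R_MAX = 0.49


def kosambi_cm_to_r(cm):
    """Kosambi map function: distance in centimorgans -> meiotic r."""
    return 0.5 * np.tanh(np.asarray(cm, dtype=float) / 50.0)


def kosambi_r_to_cm(r):
    """Inverse Kosambi: meiotic r -> distance in centimorgans."""
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def ril_r_from_meiotic(r):
    """Observed recombination between selfed-RIL genotypes: R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def meiotic_r_from_ril(R):
    """Invert the selfed-RIL correction: r = R/(2-2R), clamped below 0.5."""
    R = np.asarray(R, dtype=float)
    return np.minimum(R / (2.0 - 2.0 * R), _R_MAX)


def ril_r_from_cm(cm):
    """Centimorgans -> observed RIL recombination fraction."""
    return ril_r_from_meiotic(kosambi_cm_to_r(cm))


def cm_from_ril_r(R):
    """Observed RIL recombination fraction -> centimorgans."""
    return kosambi_r_to_cm(meiotic_r_from_ril(R))
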