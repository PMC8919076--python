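"""Non-linear transmural pressure–area law shared by conduits and compartments.

    p_trans(A) = p0 · [ ((A + A_w/2)/(A0 + A_w/2))^(k/3 − 1)
                        − max(0, (A/A0)^(−0.7) · (A_w/A0)^(0.4) − 1)² ]

The first (elastic) factor equals 1 at the reference area A0, so
p_trans(A0) = p0: p0 is the transmural pressure at which lumen area and wall
area take their reference values A0 and A_w.  The exponent is (k/3 − 1);
k sets the wall stiffness (larger k = stiffer).  The second term is a
collapsible-tube correction active only well below the reference area
(for A_w ≤ A0 it is zero at A = A0); it diverges as A → 0 so transmural
pressure becomes progressively negative as the vessel approaches collapse.
Exponent signs in the collapse term are chosen so that the law is inactive
at the reference state and unbounded below at collapse.
"""

from __future__ import annotations

import numpy as np


def transmural_pressure_area(A, p0, A0, Aw, k):
    """Transmural pressure (units of p0) at lumen area(s) A."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0.0):
        raise ValueError("lumen area must be > 0")
    elastic = ((A + 0.5 * Aw) / (A0 + 0.5 * Aw)) ** (k / 3.0 - 1.0)
    g = (A / A0) ** (-0.7) * (Aw / A0) ** 0.4
    collapse = np.where(g > 1.0, (g - 1.0) ** 2, 0.0)
    return p0 * (elastic - collapse)


def dp_dA(A, p0, A0, Aw, k):
    """Analytic derivative of the pressure–area law (units of p0 per area)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0.0):
        raise ValueError("lumen area must be > 0")
    denom = A0 + 0.5 * Aw
    d_el = (k / 3.0 - 1.0) * ((A + 0.5 * Aw) / denom) ** (k / 3.0 - 2.0) / denom
    g = (A / A0) ** (-0.7) * (Aw / A0) ** 0.4
    dg = -0.7 * g / A
    d_col = np.where(g > 1.0, 2.0 * (g - 1.0) * dg, 0.0)
    return p0 * (d_el - d_col)
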