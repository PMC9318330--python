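"""Interpretation of corrected labeling data: fractional labeling and
flux split ratios at the glucose-6-phosphate branch point.

Fractional labeling
-------------------
The mean fraction of labelable positions actually carrying label,

    FL = sum_i i * [M+i] / n,

where n is the number of tracer positions of the metabolite.  FL = 0 for
an unlabeled pool, 1 for a uniformly labeled one.

Split ratios from [1-13C]glucose
--------------------------------
Feeding [1-13C]glucose distinguishes the pathways that consume
glucose-6-phosphate by where the C1 label ends up in three-carbon
intermediates (3-phosphoglycerate, phosphoenolpyruvate, pyruvate):

* glycolysis (Embden-Meyerhof-Parnas, fraction X): the hexose splits
  into two triose units, one carrying the label (at pyruvate C3) and one
  unlabeled — an M+0:M+1 ratio of 1:1;
* oxidative pentose phosphate pathway (fraction Y): C1 is lost as CO2
  and each glucose yields 5/3 unlabeled triose units;
* Entner-Doudoroff pathway (fraction Z, bacteria): two triose units, one
  labeled at pyruvate C1, one unlabeled.

With two pathways (X + Y = 1) a single fragment covering all three
backbone carbons suffices; resolving the ED pathway additionally needs a
fragment covering only carbons 2-3, which the C1 (ED) label does not
reach.  Per pathway fraction the triose pools are:

    ================  =========  ================  ==========
    contribution       unlabeled  labeled at C3     labeled at C1
    ================  =========  ================  ==========
    glycolysis X       X          X                 —
    PP pathway Y       5/3 Y      —                 —
    ED pathway Z       Z          —                 Z
    ================  =========  ================  ==========

so for the fragment containing carbons 1-3 [M+0]:[M+1] =
(X + 5/3 Y + Z) : (X + Z), and for the carbons 2-3 fragment
(X + 5/3 Y + 2Z) : X.  A variant with the fragment roles exchanged is
available via ``as_printed=True`` (see
:func:`split_ratio_glycolysis_pp_ed`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SplitRatioResult",
    "fractional_labeling",
    "split_ratio_glycolysis_pp",
    "split_ratio_glycolysis_pp_ed",
    "forward_mdv_emp_pp",
    "forward_mdv_emp_pp_ed",
]


def fractional_labeling(mdv_corr, n: int) -> float:
    """Mean enrichment sum_i i*[M+i] / n of a corrected MDV.

    ``n`` is the number of tracer-labelable positions; the MDV must have
    exactly n+1 entries (M+0..M+n) and be normalized.
    """
    values = getattr(mdv_corr, "values", mdv_corr)
    v = np.asarray(values, dtype=float)
    if n <= 0:
        raise ValueError("n must be a positive integer")
    if v.size != n + 1:
        raise ValueError(f"MDV has {v.size} entries, expected n+1 = {n + 1}")
    return float(np.arange(n + 1) @ v / n)


@dataclass(frozen=True)
class SplitRatioResult:
    """Split ratios at the glucose-6-phosphate branch point.

    ``x``: glycolysis (EMP); ``y``: pentose phosphate pathway; ``z``:
    Entner-Doudoroff pathway (None in the two-pathway model).  If the
    solved ratios fell outside [0, 1] they are clamped onto the simplex
    and ``clamped`` is set; ``unclamped`` keeps the original solution.
    ``residual`` is the 2-norm residual of the solved linear system.
    """

    x: float
    y: float
    z: float | None = None
    clamped: bool = False
    residual: float = 0.0
    unclamped: tuple[float, ...] = ()

    def as_tuple(self) -> tuple[float, ...]:
        return (self.x, self.y) if self.z is None else (self.x, self.y, self.z)


def _clamp_simplex(v: np.ndarray) -> tuple[np.ndarray, bool]:
    # overshoot below ~1e-9 is float noise from the solve, not model misfit
    if np.all(v >= -1e-9) and np.all(v <= 1 + 1e-9):
        return np.clip(v, 0.0, 1.0), False
    c = np.clip(v, 0.0, 1.0)
    total = c.sum()
    if total <= 0:
        raise ValueError(f"split-ratio solution {v.tolist()} cannot be clamped")
    return c / total, True


def _first_two(mdv) -> tuple[float, float]:
    values = getattr(mdv, "values", mdv)
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("MDV needs at least M+0 and M+1 entries")
    return float(v[0]), float(v[1])


def split_ratio_glycolysis_pp(mdv_corr) -> SplitRatioResult:
    """Two-pathway split ratio (glycolysis X vs PP pathway Y) from the
    corrected MDV of a three-carbon intermediate (3PG or PEP) under
    [1-13C]glucose.

    Solves X + Y = 1 with [M+0]:[M+1] = (X + 5/3 Y):X.  Closed form:
    X = (5/3) / ([M+0]/[M+1] + 2/3); [M+1] = 0 gives X = 0 (pure PP).
    Only the M+0 and M+1 entries are used; the ratio is scale-invariant,
    so no renormalization over the first two channels is applied.
    """
    m0, m1 = _first_two(mdv_corr)
    if m0 == 0.0 and m1 == 0.0:
        raise ValueError("M+0 and M+1 are both zero; split ratio undefined")
    if m1 == 0.0:
        x = 0.0
    else:
        x = (5.0 / 3.0) / (m0 / m1 + 2.0 / 3.0)
    raw = np.array([x, 1.0 - x])
    clamped_v, was_clamped = _clamp_simplex(raw)
    return SplitRatioResult(
        x=float(clamped_v[0]),
        y=float(clamped_v[1]),
        clamped=was_clamped,
        residual=0.0,
        unclamped=tuple(raw.tolist()),
    )


def split_ratio_glycolysis_pp_ed(
    mdv_123, mdv_23, as_printed: bool = False
) -> SplitRatioResult:
    """Three-pathway split ratio (glycolysis X, PP Y, Entner-Doudoroff Z)
    from two fragments of a three-carbon intermediate: one containing
    backbone carbons 1-3, one containing carbons 2-3.

    Solves the linear system

        X + Y + Z = 1
        (X + 5/3 Y + Z)  * [M+1]_123 = (X + Z) * [M+0]_123
        (X + 5/3 Y + 2Z) * [M+1]_23  = X       * [M+0]_23

    which follows from the atom mapping: the glycolytic label sits at
    pyruvate C3 (seen by both fragments) and the ED label at pyruvate C1
    (seen only by the 1-3 fragment).  ``as_printed=True`` exchanges the
    fragment roles (the 2Z balance applied to the 1-3 fragment), a
    convention found in the literature; note it violates subset
    consistency — a molecule labeled within carbons 2-3 is necessarily
    labeled within carbons 1-3.

    Out-of-simplex solutions are clamped and flagged; a singular system
    (e.g., both fragments entirely M+0) raises.
    """
    a0, a1 = _first_two(mdv_123)
    b0, b1 = _first_two(mdv_23)
    if as_printed:
        (a0, a1), (b0, b1) = (b0, b1), (a0, a1)
    if a1 == 0.0 and b1 == 0.0:
        raise ValueError(
            "both fragments show no M+1; the labeling carries no pathway "
            "information"
        )
    # rows: [coeff_X, coeff_Y, coeff_Z] @ [X, Y, Z] = rhs
    A = np.array(
        [
            [1.0, 1.0, 1.0],
            [a1 - a0, 5.0 / 3.0 * a1, a1 - a0],
            [b1 - b0, 5.0 / 3.0 * b1, 2.0 * b1],
        ]
    )
    rhs = np.array([1.0, 0.0, 0.0])
    if np.linalg.cond(A) > 1e12:
        raise ValueError(
            "singular split-ratio system; the two fragment MDVs do not "
            "discriminate the three pathways"
        )
    sol = np.linalg.solve(A, rhs)
    residual = float(np.linalg.norm(A @ sol - rhs))
    clamped_v, was_clamped = _clamp_simplex(sol)
    return SplitRatioResult(
        x=float(clamped_v[0]),
        y=float(clamped_v[1]),
        z=float(clamped_v[2]),
        clamped=was_clamped,
        residual=residual,
        unclamped=tuple(sol.tolist()),
    )


def forward_mdv_emp_pp(x: float) -> np.ndarray:
    """Forward model: [M+0, M+1] of a three-carbon intermediate under
    [1-13C]glucose given the glycolysis fraction ``x`` (PP fraction 1-x)."""
    if not (0.0 <= x <= 1.0):
        raise ValueError("x must be in [0, 1]")
    y = 1.0 - x
    pools = np.array([x + 5.0 / 3.0 * y, x])
    return pools / pools.sum()


def forward_mdv_emp_pp_ed(
    x: float, y: float, z: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward model for the three-pathway branch: the [M+0, M+1] vectors
    of the carbons-1-3 and carbons-2-3 fragments given split ratios
    (x, y, z) on the simplex."""
    if min(x, y, z) < -1e-12 or abs(x + y + z - 1.0) > 1e-9:
        raise ValueError("(x, y, z) must lie on the probability simplex")
    frag123 = np.array([x + 5.0 / 3.0 * y + z, x + z])
    frag23 = np.array([x + 5.0 / 3.0 * y + 2.0 * z, x])
    return frag123 / frag123.sum(), frag23 / frag23.sum()
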