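"""Isotopologue channel generation for SIM and MRM acquisition.

For a tracer with ``n`` labelable atom positions in a fragment ion, a
labeling measurement needs channels M+0..M+n, plus *extra* channels above
M+n that capture natural heavy isotopes riding on fully labeled species
-- without them the correction of natural isotopes is biased for highly
labeled samples.  For tandem (MRM) acquisition the set of precursor /
product shift combinations consistent with the tracer atom bookkeeping is
enumerated.

Channel tables are plain :class:`pandas.DataFrame` objects with the CSV
schema used by the command-line interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import (
    ElementIsotopeTable,
    Formula,
    TracerSpec,
    monoisotopic_mz,
    natural_shift_distribution,
)

__all__ = [
    "FragmentIon",
    "MRMPair",
    "generate_sim_channels",
    "generate_mrm_channels",
    "theoretical_natural_mdv",
    "SIM_COLUMNS",
    "MRM_COLUMNS",
]

SIM_COLUMNS = ["name", "label", "mz", "is_extra"]
MRM_COLUMNS = ["name", "prec_label", "prod_label", "prec_mz", "prod_mz", "is_extra"]


@dataclass(frozen=True)
class FragmentIon:
    """A charged fragment ion targeted for isotopologue monitoring.

    The formula is that of the ion *as detected*: derivatization groups
    and adduct atoms included.  ``n_tracer_positions`` counts only the
    atom positions that can carry tracer label (e.g., metabolite backbone
    carbons for a 13C tracer), never derivatization or adduct atoms.
    """

    name: str
    formula: Formula
    charge: int
    n_tracer_positions: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"{self.name}: charge must be nonzero")
        if self.n_tracer_positions < 0:
            raise ValueError(f"{self.name}: n_tracer_positions must be >= 0")

    def validate_tracer(self, tracer: TracerSpec) -> None:
        have = self.formula[tracer.element]
        if self.n_tracer_positions > have:
            raise ValueError(
                f"{self.name}: {self.n_tracer_positions} tracer positions "
                f"exceed the {have} {tracer.element} atoms in {self.formula}"
            )

    def mz(self, table: ElementIsotopeTable | None = None) -> float:
        return monoisotopic_mz(self.formula, self.charge, table)


@dataclass(frozen=True)
class MRMPair:
    """A precursor/product ion pair for tandem acquisition.

    The product must be a fragment of the precursor: its formula an
    elementwise sub-formula, and its tracer positions ``m`` a subset of
    the precursor's ``n`` (m <= n).
    """

    precursor: FragmentIon
    product: FragmentIon

    def __post_init__(self) -> None:
        if self.product.n_tracer_positions > self.precursor.n_tracer_positions:
            raise ValueError(
                f"{self.precursor.name}: product carries more tracer positions "
                f"({self.product.n_tracer_positions}) than the precursor "
                f"({self.precursor.n_tracer_positions})"
            )
        if not self.precursor.formula.contains(self.product.formula):
            raise ValueError(
                f"{self.precursor.name}: product formula {self.product.formula} "
                f"is not a sub-formula of precursor {self.precursor.formula}"
            )


def _shifted_mz(base: float, i: int, tracer: TracerSpec, charge: int,
                nominal: bool) -> float:
    mz = base + i * tracer.mass_diff / abs(charge)
    return round(mz) if nominal else mz


def generate_sim_channels(
    ion: FragmentIon,
    tracer: TracerSpec,
    extra: int = 3,
    table: ElementIsotopeTable | None = None,
    nominal: bool = False,
) -> pd.DataFrame:
    """SIM channel list M+0..M+(n+extra) for one fragment ion.

    Channel i sits at ``monoisotopic m/z + i * tracer mass difference /
    |charge|``; channels above M+n are flagged ``is_extra`` (they exist
    to observe natural heavy isotopes of the fully labeled species).
    Returns a DataFrame with columns ``name,label,mz,is_extra``.
    """
    if extra < 0:
        raise ValueError("extra must be non-negative")
    ion.validate_tracer(tracer)
    base = ion.mz(table)
    n = ion.n_tracer_positions
    rows = [
        {
            "name": ion.name,
            "label": f"M+{i}",
            "mz": _shifted_mz(base, i, tracer, ion.charge, nominal),
            "is_extra": i > n,
        }
        for i in range(n + extra + 1)
    ]
    return pd.DataFrame(rows, columns=SIM_COLUMNS)


def tracer_consistent_pairs(n: int, m: int) -> list[tuple[int, int]]:
    """All (precursor shift i, product shift j) pairs realizable by
    placing labels on n precursor tracer positions of which m survive in
    the product: 0 <= i <= n and max(0, i-(n-m)) <= j <= min(i, m)."""
    return [
        (i, j)
        for i in range(n + 1)
        for j in range(max(0, i - (n - m)), min(i, m) + 1)
    ]


def generate_mrm_channels(
    pair: MRMPair,
    tracer: TracerSpec,
    extra: int = 0,
    table: ElementIsotopeTable | None = None,
    nominal: bool = False,
) -> pd.DataFrame:
    """MRM transition list for a precursor/product pair.

    With ``extra == 0`` only tracer-consistent (i, j) combinations are
    emitted.  With ``extra > 0`` the bounds widen to ``i <= n+extra``,
    ``j <= m+extra`` and ``i-j <= (n-m)+extra`` to admit natural-isotope
    shifts on either side; combinations outside the tracer-consistent set
    are flagged ``is_extra`` so they can be filtered downstream.
    """
    if extra < 0:
        raise ValueError("extra must be non-negative")
    prec, prod = pair.precursor, pair.product
    prec.validate_tracer(tracer)
    prod.validate_tracer(tracer)
    n, m = prec.n_tracer_positions, prod.n_tracer_positions
    core = set(tracer_consistent_pairs(n, m))
    combos = [
        (i, j)
        for i in range(n + extra + 1)
        for j in range(min(i, m + extra) + 1)
        if i - j <= (n - m) + extra
    ]
    prec_base = prec.mz(table)
    prod_base = prod.mz(table)
    rows = [
        {
            "name": prec.name,
            "prec_label": f"M+{i}",
            "prod_label": f"M+{j}",
            "prec_mz": _shifted_mz(prec_base, i, tracer, prec.charge, nominal),
            "prod_mz": _shifted_mz(prod_base, j, tracer, prod.charge, nominal),
            "is_extra": (i, j) not in core,
        }
        for i, j in combos
    ]
    return pd.DataFrame(rows, columns=MRM_COLUMNS)


def theoretical_natural_mdv(
    ion: FragmentIon,
    n_channels: int,
    table: ElementIsotopeTable | None = None,
) -> np.ndarray:
    """Theoretical isotopologue distribution of the *unlabeled* ion.

    This is the natural mass-shift distribution of the ion formula
    truncated to ``n_channels`` entries -- the pattern an unlabeled
    standard should show in the generated channels.  Comparing it with a
    measured unlabeled sample validates a newly created acquisition
    method (fragment purity, co-elution artifacts).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    return natural_shift_distribution(ion.formula, n_channels - 1, table)
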