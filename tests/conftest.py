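"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's convolution and
enumeration code paths: natural isotope distributions are computed by
exhaustive enumeration over per-atom isotope assignments, and MRM
transition sets by exhaustive placement of labels on tracer positions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

from isocalc import ElementIsotopeTable, Formula, Isotope, TracerSpec

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table() -> ElementIsotopeTable:
    return ElementIsotopeTable.default()


@pytest.fixture(scope="session")
def tracer_13c() -> TracerSpec:
    return TracerSpec.from_string("13C")


@pytest.fixture(scope="session")
def pure_table() -> ElementIsotopeTable:
    """Abundance table where every lightest isotope has abundance 1:
    no natural isotope spread at all."""
    base = ElementIsotopeTable.default()
    return ElementIsotopeTable(
        {
            sym: (Isotope(0, isos[0].mass, 1.0),)
            for sym, isos in base.entries.items()
        }
    )


def brute_force_shift_distribution(
    formula: Formula, table: ElementIsotopeTable
) -> np.ndarray:
    """Exact natural mass-shift distribution by enumerating every
    combination of isotope assignments over all atoms."""
    atom_choices = []
    for sym, count in formula.counts.items():
        atom_choices.extend([table.isotopes(sym)] * count)
    max_shift = sum(isos[-1].mass_shift for isos in atom_choices)
    dist = np.zeros(max_shift + 1)
    for combo in itertools.product(*atom_choices):
        shift = sum(i.mass_shift for i in combo)
        dist[shift] += math.prod(i.abundance for i in combo)
    return dist


def brute_force_mrm_pairs(n: int, m: int) -> set[tuple[int, int]]:
    """All (precursor shift, product shift) pairs realizable by labeling
    any subset of n tracer positions when the product retains a fixed
    set of m of them."""
    retained = set(range(m))
    pairs = set()
    for labeled in itertools.chain.from_iterable(
        itertools.combinations(range(n), k) for k in range(n + 1)
    ):
        pairs.add((len(labeled), len(retained & set(labeled))))
    return pairs


def random_small_ion(rng: np.random.Generator):
    """A random plausible fragment ion for round-trip tests."""
    from isocalc import FragmentIon

    n = int(rng.integers(1, 6))
    counts = {
        "C": n + int(rng.integers(0, 8)),
        "H": int(rng.integers(1, 20)),
        "O": int(rng.integers(0, 6)),
        "N": int(rng.integers(0, 3)),
        "Si": int(rng.integers(0, 3)),
    }
    return FragmentIon(
        name=f"ion{rng.integers(1e6)}",
        formula=Formula({k: v for k, v in counts.items() if v}),
        charge=1,
        n_tracer_positions=n,
    )
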