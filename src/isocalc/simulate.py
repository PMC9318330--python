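"""Forward simulation of raw isotopologue area datasets with known
ground truth.

The generative model runs the correction pipeline in reverse: a true
(corrected) MDV is pushed through the correction matrix to channel
space, scaled to a total ion intensity, and perturbed by multiplicative
log-normal noise::

    areas = intensity * (CM @ MDV_true) * exp(sigma * eps),   eps ~ N(0, I)

Multiplicative noise reflects that peak areas are positive with roughly
constant relative (not absolute) error.  With ``sigma = 0`` the forward
projection is exact, so the full pipeline (simulate -> correct ->
interpret) must reproduce every ground-truth quantity to numerical
precision — the backbone of this package's validation.

:func:`simulate_dataset` arranges records in a factorial layout
(e.g. 2 cell lines x 4 tracer conditions x 3 replicates per metabolite)
mirroring a typical tracing study, and returns the ground truth
alongside for scoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import ElementIsotopeTable, TracerSpec
from .channels import FragmentIon
from .correction import CorrectionMatrix, build_correction_matrix
from .interpret import forward_mdv_emp_pp

__all__ = [
    "SimulationScenario",
    "simulate_raw_areas",
    "simulate_dataset",
    "binomial_mdv",
]


def binomial_mdv(n: int, enrichment: float) -> np.ndarray:
    """MDV of n positions labeled independently with probability
    ``enrichment`` — the stationary pattern of a well-mixed single
    uniformly labeled substrate."""
    if not (0.0 <= enrichment <= 1.0):
        raise ValueError("enrichment must be in [0, 1]")
    i = np.arange(n + 1)
    from scipy.stats import binom

    return binom.pmf(i, n, enrichment)


def _resolve_mdv(spec, n: int) -> np.ndarray:
    """Accept an explicit vector, {'binomial': f} or {'split_emp_pp': x}."""
    if isinstance(spec, dict):
        if "binomial" in spec:
            return binomial_mdv(n, float(spec["binomial"]))
        if "split_emp_pp" in spec:
            m01 = forward_mdv_emp_pp(float(spec["split_emp_pp"]))
            mdv = np.zeros(n + 1)
            mdv[:2] = m01
            return mdv
        raise ValueError(
            f"parametric MDV spec {spec!r} not understood; use 'binomial' "
            "or 'split_emp_pp'"
        )
    v = np.asarray(spec, dtype=float)
    if v.ndim != 1 or v.size != n + 1:
        raise ValueError(f"true MDV must have n+1 = {n + 1} entries, got {v.size}")
    if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
        raise ValueError("true MDV must be non-negative and sum to 1")
    return v / v.sum()


@dataclass
class SimulationScenario:
    """Specification of a synthetic labeling dataset.

    ``true_mdvs`` maps metabolite name -> explicit vector, or
    ``{"binomial": f}`` (independent labeling at enrichment f), or
    ``{"split_emp_pp": x}`` (two-pathway split-ratio pattern).
    ``layout`` maps factor name -> list of level names; one record is
    generated per factor combination x metabolite x replicate.
    """

    targets: list[FragmentIon]
    true_mdvs: dict
    tracer: TracerSpec = field(default_factory=lambda: TracerSpec.from_string("13C"))
    extra: int = 3
    intensity: float = 1e6
    sigma: float = 0.01
    layout: dict[str, list[str]] = field(
        default_factory=lambda: {"condition": ["c1"]}
    )
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.replicates < 1 or any(len(v) < 1 for v in self.layout.values()):
            raise ValueError("layout counts must be >= 1")
        missing = [t.name for t in self.targets if t.name not in self.true_mdvs]
        if missing:
            raise ValueError(f"no true MDV given for targets {missing}")


def simulate_raw_areas(
    true_mdv,
    ion: FragmentIon,
    tracer: TracerSpec,
    extra: int = 3,
    intensity: float = 1e6,
    sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    cm: CorrectionMatrix | None = None,
    table: ElementIsotopeTable | None = None,
) -> np.ndarray:
    """Raw channel areas for one record.

    ``seed`` may be an integer or an existing Generator (to share a
    stream across records); the same integer seed always yields the same
    vector.
    """
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    mdv = np.asarray(getattr(true_mdv, "values", true_mdv), dtype=float)
    if cm is None:
        cm = build_correction_matrix(ion, tracer, extra, table=table)
    if mdv.size != cm.n_states:
        raise ValueError(
            f"true MDV has {mdv.size} entries, correction matrix expects "
            f"{cm.n_states}"
        )
    expected = intensity * (cm.matrix @ mdv)
    if sigma == 0.0:
        return expected
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return expected * np.exp(sigma * rng.standard_normal(expected.size))


def simulate_dataset(
    scenario: SimulationScenario,
    table: ElementIsotopeTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full factorial dataset.

    Returns ``(areas, truth)``: a long-format area table with columns
    ``sample,metabolite,label,area`` plus one column per layout factor,
    and a ground-truth table ``metabolite,label,fraction`` with the true
    corrected MDVs.  Sample ids encode the factor levels and replicate
    (``lvl1-lvl2-r1``).
    """
    rng = np.random.default_rng(scenario.seed)
    cms = {
        t.name: build_correction_matrix(
            t, scenario.tracer, scenario.extra, table=table
        )
        for t in scenario.targets
    }
    resolved = {
        t.name: _resolve_mdv(scenario.true_mdvs[t.name], t.n_tracer_positions)
        for t in scenario.targets
    }

    factor_names = list(scenario.layout)
    rows = []
    for combo in itertools.product(*scenario.layout.values()):
        for rep in range(1, scenario.replicates + 1):
            sample = "-".join([*combo, f"r{rep}"])
            for t in scenario.targets:
                areas = simulate_raw_areas(
                    resolved[t.name],
                    t,
                    scenario.tracer,
                    scenario.extra,
                    scenario.intensity,
                    scenario.sigma,
                    seed=rng,
                    cm=cms[t.name],
                )
                for i, a in enumerate(areas):
                    rows.append(
                        {
                            "sample": sample,
                            "metabolite": t.name,
                            "label": f"M+{i}",
                            "area": a,
                            **dict(zip(factor_names, combo)),
                            "replicate": rep,
                        }
                    )
    areas_df = pd.DataFrame(rows)

    truth_rows = [
        {"metabolite": name, "label": f"M+{i}", "fraction": frac}
        for name, mdv in resolved.items()
        for i, frac in enumerate(mdv)
    ]
    truth_df = pd.DataFrame(truth_rows, columns=["metabolite", "label", "fraction"])
    return areas_df, truth_df
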