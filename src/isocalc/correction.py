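"""Natural-isotope and tracer-purity correction of mass isotopologue
distributions.

The observed (raw) mass isotopologue distribution vector MDVraw of a
fragment ion is the true labeling distribution MDVcorr spread over extra
channels by natural heavy isotopes::

    MDVraw = CM @ MDVcorr

where CM is the *correction matrix*: column j is the natural mass-shift
distribution of the ion with j tracer atoms removed (those j positions
carry tracer label and hence no natural variation), placed starting at
row j.  Correction solves this linear system — an exact inverse when the
matrix is square, linear least squares when extra observation channels
are present.

Sub-unity tracer purity alpha mixes a naturally labeled component into
the measurement; it is removed elementwise by::

    MDVlabeled = (MDVmeas - (1 - alpha) * MDVnatural) / alpha
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .chem import ElementIsotopeTable, Formula, TracerSpec, natural_shift_distribution
from .channels import FragmentIon

logger = logging.getLogger(__name__)

__all__ = [
    "MDV",
    "CorrectionMatrix",
    "LabelingRecord",
    "CorrectionDiagnostics",
    "BatchLog",
    "build_correction_matrix",
    "areas_to_mdv",
    "correct_natural",
    "correct_purity",
    "batch_correct",
]

#: default threshold separating numerical noise from model misfit when
#: clipping negative corrected fractions
DEFAULT_TOLERANCE = 1e-3


@dataclass(frozen=True)
class MDV:
    """A mass isotopologue distribution vector.

    ``values[i]`` is the abundance fraction of the M+i isotopologue; a
    normalized MDV is non-negative and sums to 1.  ``role`` records the
    processing stage (raw | corrected | natural | labeled | measured).
    """

    values: np.ndarray
    role: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("MDV must be a non-empty 1-D vector")

    def __len__(self) -> int:
        return self.values.size

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return bool(np.all(self.values >= 0) and abs(self.values.sum() - 1) <= tol)


@dataclass(frozen=True)
class LabelingRecord:
    """One measured isotopologue area vector for one sample x metabolite."""

    sample: str
    metabolite: str
    areas: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "areas", np.asarray(self.areas, dtype=float))


@dataclass(frozen=True)
class CorrectionMatrix:
    """Correction matrix mapping true labeling states to observed channels.

    Shape is (n+1+extra) x (n+1) for an ion with n tracer positions and
    ``extra`` natural-isotope channels.  Lower-band: entry (i, j) is zero
    for i < j; column sums approach 1 as ``extra`` grows.
    """

    matrix: np.ndarray
    ion: FragmentIon
    tracer: TracerSpec
    elements: frozenset[str]
    extra: int

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_states(self) -> int:
        return self.matrix.shape[1]


def _restrict_elements(formula: Formula, elements: frozenset[str]) -> Formula:
    """Keep only the chosen elements; the rest are treated as monoisotopic
    (they contribute no isotope spread, hence can be dropped entirely)."""
    return Formula({s: c for s, c in formula.counts.items() if s in elements})


def build_correction_matrix(
    ion: FragmentIon,
    tracer: TracerSpec,
    extra: int = 3,
    elements: set[str] | frozenset[str] | None = None,
    table: ElementIsotopeTable | None = None,
) -> CorrectionMatrix:
    """Build the natural-isotope correction matrix for one fragment ion.

    Column j is the natural mass-shift distribution of the ion formula
    with j tracer-element atoms removed, shifted down j rows: the j
    labeled positions are fixed heavy and carry no natural variation,
    while all remaining atoms — including tracer-element atoms outside
    the labelable backbone, e.g. derivatization carbons — keep their
    natural spread.

    ``elements`` restricts which elements contribute isotope spread
    (useful to reproduce tools that correct only selected elements);
    ``None`` uses every element of the formula.
    """
    if extra < 0:
        raise ValueError("extra must be non-negative")
    ion.validate_tracer(tracer)
    if table is None:
        table = ElementIsotopeTable.default()
    n = ion.n_tracer_positions
    if elements is None:
        elements = frozenset(ion.formula.counts)
    else:
        elements = frozenset(elements)
        unknown = elements - set(ion.formula.counts)
        if unknown:
            raise ValueError(
                f"{ion.name}: correction elements {sorted(unknown)} not in "
                f"formula {ion.formula}"
            )

    rows = n + 1 + extra
    cm = np.zeros((rows, n + 1))
    for j in range(n + 1):
        residual = _restrict_elements(ion.formula.remove(tracer.element, j), elements)
        depth = rows - j
        if residual:
            col = natural_shift_distribution(residual, depth - 1, table)
        else:  # all spread switched off -> point mass at shift 0
            col = np.zeros(depth)
            col[0] = 1.0
        cm[j:, j] = col
    return CorrectionMatrix(cm, ion, tracer, elements, extra)


def areas_to_mdv(areas, record_id: str = "") -> MDV:
    """Normalize a raw peak-area vector into a raw MDV.

    Negative areas are clipped to zero (with a warning); the vector is
    then divided by its sum.  All-nonpositive input is an error.
    """
    a = np.asarray(areas, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("area vector must be non-empty and 1-D")
    if np.any(a < 0):
        logger.warning(
            "negative peak area(s) clipped to 0%s",
            f" in record {record_id}" if record_id else "",
        )
        a = np.clip(a, 0.0, None)
    total = a.sum()
    if total <= 0:
        raise ValueError(
            f"all peak areas non-positive{f' in record {record_id}' if record_id else ''}"
        )
    return MDV(a / total, role="raw")


@dataclass(frozen=True)
class CorrectionDiagnostics:
    """What happened while solving one correction."""

    raw_solution: np.ndarray      # least-squares / inverse solution before clipping
    residual: float               # ||CM @ x - mdv_raw||_2 of the raw solution
    clipped: tuple[int, ...]      # indices in (-tolerance, 0) set to 0
    flagged: tuple[int, ...]      # indices <= -tolerance (model misfit suspected)

    @property
    def ok(self) -> bool:
        return not self.flagged


def _clip_renormalize(
    x: np.ndarray, tolerance: float
) -> tuple[np.ndarray, tuple[int, ...], tuple[int, ...]]:
    clipped = tuple(np.flatnonzero((x < 0) & (x > -tolerance)).tolist())
    flagged = tuple(np.flatnonzero(x <= -tolerance).tolist())
    out = np.clip(x, 0.0, None)
    total = out.sum()
    if total <= 0:
        raise ValueError("corrected MDV has no positive entries after clipping")
    return out / total, clipped, flagged


def correct_natural(
    mdv_raw,
    cm: CorrectionMatrix,
    tolerance: float = DEFAULT_TOLERANCE,
    nonnegative: bool = False,
) -> tuple[MDV, CorrectionDiagnostics]:
    """Remove natural-isotope effects from a raw MDV.

    Solves ``MDVraw = CM @ MDVcorr`` by exact inversion (square matrix)
    or unconstrained linear least squares (extra channels present).
    Small negative entries — magnitude below `tolerance` — are treated
    as numerical noise and clipped to 0; larger negatives indicate model
    misfit and are flagged in the diagnostics (the corrected record is
    kept).  The result is renormalized to sum 1.

    Set ``nonnegative=True`` to use a non-negativity-constrained solver
    (NNLS) instead of unconstrained least squares.
    """
    raw = mdv_raw.values if isinstance(mdv_raw, MDV) else np.asarray(mdv_raw, float)
    A = cm.matrix
    if raw.shape != (A.shape[0],):
        raise ValueError(
            f"raw MDV length {raw.size} does not match the {A.shape[0]} "
            f"channels of the correction matrix"
        )
    if nonnegative:
        x, _ = scipy.optimize.nnls(A, raw)
    elif A.shape[0] == A.shape[1]:
        # diagonal of the lower-band matrix = column residual mass at shift 0
        if np.min(np.abs(np.diag(A))) < 1e-12:
            raise np.linalg.LinAlgError("singular correction matrix")
        x = np.linalg.solve(A, raw)
    else:
        x, *_ = np.linalg.lstsq(A, raw, rcond=None)
    residual = float(np.linalg.norm(A @ x - raw))
    values, clipped, flagged = _clip_renormalize(x, tolerance)
    return (
        MDV(values, role="corrected"),
        CorrectionDiagnostics(x, residual, clipped, flagged),
    )


def correct_purity(
    mdv_meas,
    tracer: TracerSpec,
    mdv_natural=None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> MDV:
    """Remove the contribution of unlabeled (natural) substrate caused by
    sub-unity tracer purity alpha.

    ``MDVlabeled = (MDVmeas - (1 - alpha) * MDVnatural) / alpha``,
    followed by the same clip-and-renormalize policy as
    :func:`correct_natural`.  ``mdv_natural`` defaults to the unit vector
    at M+0, the natural labeling state *after* natural-isotope
    correction; pass the theoretical natural MDV to apply the formula to
    uncorrected data instead.
    """
    meas = mdv_meas.values if isinstance(mdv_meas, MDV) else np.asarray(mdv_meas, float)
    alpha = tracer.purity  # TracerSpec guarantees alpha in (0, 1]
    if mdv_natural is None:
        nat = np.zeros_like(meas)
        nat[0] = 1.0
    else:
        nat = (
            mdv_natural.values
            if isinstance(mdv_natural, MDV)
            else np.asarray(mdv_natural, float)
        )
    if nat.shape != meas.shape:
        raise ValueError("measured and natural MDVs must have the same length")
    if alpha == 1.0:
        return MDV(meas.copy(), role="labeled")
    x = (meas - (1.0 - alpha) * nat) / alpha
    values, _, _ = _clip_renormalize(x, tolerance)
    return MDV(values, role="labeled")


@dataclass
class BatchLog:
    """Processing log of a batch correction run."""

    processed: int = 0
    clipped_entries: int = 0
    flagged_records: list[str] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)  # (record id, message)

    def summary(self) -> str:
        lines = [
            f"records processed: {self.processed}",
            f"negative entries clipped: {self.clipped_entries}",
            f"records flagged (entry <= -tolerance): {len(self.flagged_records)}",
            f"records failed: {len(self.errors)}",
        ]
        lines += [f"  {rid}: {msg}" for rid, msg in self.errors]
        return "\n".join(lines)


def batch_correct(
    records: list[LabelingRecord],
    targets: dict[str, FragmentIon],
    tracer: TracerSpec,
    extra: int = 3,
    elements: set[str] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    table: ElementIsotopeTable | None = None,
    nonnegative: bool = False,
) -> tuple[list[tuple[LabelingRecord, MDV, CorrectionDiagnostics]], BatchLog]:
    """Correct a batch of labeling records.

    Per record: normalize areas to a raw MDV, correct natural isotopes
    and, when the tracer purity is below 1, correct purity.  A record
    whose metabolite lacks a target definition (or that fails any step)
    is logged and skipped; the run continues.

    Returns the per-record results and a :class:`BatchLog`.
    """
    cms: dict[str, CorrectionMatrix] = {}
    results: list[tuple[LabelingRecord, MDV, CorrectionDiagnostics]] = []
    log = BatchLog()
    for rec in records:
        rid = f"{rec.sample}/{rec.metabolite}"
        try:
            ion = targets.get(rec.metabolite)
            if ion is None:
                raise KeyError(
                    f"no target definition for metabolite {rec.metabolite!r}"
                )
            if rec.metabolite not in cms:
                cms[rec.metabolite] = build_correction_matrix(
                    ion, tracer, extra, elements, table
                )
            cm = cms[rec.metabolite]
            raw = areas_to_mdv(rec.areas, record_id=rid)
            corrected, diag = correct_natural(raw, cm, tolerance, nonnegative)
            if tracer.purity < 1.0:
                corrected = correct_purity(corrected, tracer, tolerance=tolerance)
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            log.errors.append((rid, str(exc)))
            continue
        log.processed += 1
        log.clipped_entries += len(diag.clipped)
        if diag.flagged:
            log.flagged_records.append(rid)
        results.append((rec, corrected, diag))
    return results, log
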