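"""CSV readers/writers and run configuration.

File schemas (comma-separated, UTF-8, "." decimal separator, header
required):

targets
    ``name,ion_formula,charge,n_tracer_positions`` — one fragment ion
    per row; with the optional columns ``product_formula,
    product_n_tracer_positions`` each row defines an MRM
    precursor/product pair instead.
areas
    long format ``sample,metabolite,label,area`` with labels ``M+0,
    M+1, ...`` contiguous from M+0 within each sample x metabolite.
corrected
    ``sample,metabolite,label,fraction,flag``.
mapping export
    tidy ``metabolite,sample,statistic,value`` sorted by (metabolite,
    sample, statistic).

Floats are written with 6 significant digits; m/z with 4 decimals in
exact mode and as integers in nominal mode.
"""

from __future__ import annotations

import re
import sys
import tomllib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import FormulaError, parse_formula
from .channels import FragmentIon, MRMPair
from .correction import DEFAULT_TOLERANCE, LabelingRecord

__all__ = [
    "RunConfig",
    "read_targets",
    "read_areas",
    "write_channels",
    "write_corrected",
    "write_mapping_export",
    "read_config",
]

TARGET_COLUMNS = ["name", "ion_formula", "charge", "n_tracer_positions"]
MRM_TARGET_COLUMNS = TARGET_COLUMNS + ["product_formula", "product_n_tracer_positions"]
AREA_COLUMNS = ["sample", "metabolite", "label", "area"]

_LABEL = re.compile(r"M\+(\d+)")


@dataclass
class RunConfig:
    """Options shared across the processing chain; a TOML config file may
    supply any of them, with command-line flags taking precedence."""

    tracer: str = "13C"
    extra: int = 3
    purity: float = 1.0
    elements: list[str] | None = None
    tolerance: float = DEFAULT_TOLERANCE
    seed: int = 0
    nominal_mz: bool = False
    as_printed: bool = False
    isotope_table: str | None = None

    def validate(self) -> None:
        if self.extra < 0:
            raise ValueError("extra must be non-negative")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


def read_config(path) -> RunConfig:
    """Load a RunConfig from a TOML file; unknown keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; known: {sorted(known)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def _read_csv(path, what: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, skipinitialspace=True)
    except (FileNotFoundError, pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValueError(f"cannot read {what} file {path}: {exc}") from exc


def read_targets(path) -> list[FragmentIon] | list[MRMPair]:
    """Read a target CSV into fragment ions (or MRM pairs when the
    product columns are present).  Duplicate names and malformed rows
    raise with the offending row number."""
    df = _read_csv(path, "targets")
    cols = list(df.columns)
    if cols[: len(TARGET_COLUMNS)] != TARGET_COLUMNS:
        raise ValueError(
            f"targets file {path} must start with columns {TARGET_COLUMNS}, "
            f"got {cols}"
        )
    is_mrm = "product_formula" in cols
    if is_mrm and "product_n_tracer_positions" not in cols:
        raise ValueError(
            f"targets file {path}: product_formula requires "
            "product_n_tracer_positions"
        )
    seen: set[str] = set()
    out: list = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, plus header
        try:
            name = str(row["name"])
            if name in seen:
                raise ValueError(f"duplicate target name {name!r}")
            seen.add(name)
            ion = FragmentIon(
                name=name,
                formula=parse_formula(row["ion_formula"]),
                charge=int(row["charge"]),
                n_tracer_positions=int(row["n_tracer_positions"]),
            )
            if is_mrm:
                product = FragmentIon(
                    name=f"{name} (product)",
                    formula=parse_formula(row["product_formula"]),
                    charge=ion.charge,
                    n_tracer_positions=int(row["product_n_tracer_positions"]),
                )
                out.append(MRMPair(ion, product))
            else:
                out.append(ion)
        except (ValueError, FormulaError, KeyError) as exc:
            raise ValueError(f"targets file {path}, row {rowno}: {exc}") from exc
    return out


def read_areas(path) -> list[LabelingRecord]:
    """Read a long-format area CSV into labeling records.

    Labels must be ``M+i`` and contiguous from M+0 within each
    sample x metabolite group; gaps, non-numeric areas or a wide-format
    file raise with the location.
    """
    df = _read_csv(path, "areas")
    if list(df.columns[: len(AREA_COLUMNS)]) != AREA_COLUMNS:
        raise ValueError(
            f"areas file {path} must have columns {AREA_COLUMNS} (long "
            f"format, one row per channel), got {list(df.columns)}"
        )
    extra_meta = [c for c in df.columns if c not in AREA_COLUMNS]
    records: list[LabelingRecord] = []
    for (sample, metabolite), grp in df.groupby(
        ["sample", "metabolite"], sort=False
    ):
        where = f"areas file {path}, sample {sample!r}, metabolite {metabolite!r}"
        shifts = []
        for label in grp["label"]:
            m = _LABEL.fullmatch(str(label).strip())
            if not m:
                raise ValueError(f"{where}: bad isotopologue label {label!r}")
            shifts.append(int(m.group(1)))
        order = np.argsort(shifts)
        sorted_shifts = [shifts[i] for i in order]
        if sorted_shifts != list(range(len(sorted_shifts))):
            raise ValueError(
                f"{where}: labels must be contiguous from M+0, got "
                f"{['M+%d' % s for s in sorted_shifts]}"
            )
        try:
            areas = grp["area"].astype(float).to_numpy()[order]
        except ValueError as exc:
            raise ValueError(f"{where}: non-numeric area ({exc})") from exc
        meta = {c: grp.iloc[0][c] for c in extra_meta}
        records.append(LabelingRecord(str(sample), str(metabolite), areas, meta))
    return records


def _format_float(x: float) -> str:
    return f"{x:.6g}"


def write_channels(table: pd.DataFrame, path, nominal: bool = False) -> None:
    """Write a SIM or MRM channel table (m/z with 4 decimals, or as
    integers in nominal mode)."""
    out = table.copy()
    for col in out.columns:
        if col.endswith("mz"):
            out[col] = (
                out[col].map(lambda v: f"{int(round(v))}")
                if nominal
                else out[col].map(lambda v: f"{v:.4f}")
            )
    out.to_csv(path, index=False)


def write_corrected(results, path) -> None:
    """Write batch-correction results as a long-format corrected CSV
    ``sample,metabolite,label,fraction,flag``."""
    rows = []
    for rec, mdv, diag in results:
        flag = "flagged" if diag.flagged else "ok"
        for i, frac in enumerate(mdv.values):
            rows.append(
                {
                    "sample": rec.sample,
                    "metabolite": rec.metabolite,
                    "label": f"M+{i}",
                    "fraction": _format_float(float(frac)),
                    "flag": flag,
                }
            )
    pd.DataFrame(rows, columns=["sample", "metabolite", "label", "fraction", "flag"]).to_csv(
        path, index=False
    )


def read_corrected(path) -> pd.DataFrame:
    """Read a corrected CSV back into a DataFrame with numeric fractions."""
    df = _read_csv(path, "corrected")
    need = ["sample", "metabolite", "label", "fraction"]
    if list(df.columns[: len(need)]) != need:
        raise ValueError(
            f"corrected file {path} must have columns {need}, got {list(df.columns)}"
        )
    df["fraction"] = df["fraction"].astype(float)
    return df


def write_mapping_export(results: pd.DataFrame, path) -> None:
    """Write a tidy ``metabolite,sample,statistic,value`` CSV for generic
    mapping/plotting tools, with deterministic lexicographic row order."""
    cols = ["metabolite", "sample", "statistic", "value"]
    if results.empty:
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return
    missing = set(cols) - set(results.columns)
    if missing:
        raise ValueError(f"mapping export needs columns {cols}; missing {sorted(missing)}")
    out = results[cols].copy()
    out = out.sort_values(["metabolite", "sample", "statistic"], kind="mergesort")
    out["value"] = out["value"].map(lambda v: _format_float(float(v)))
    out.to_csv(path, index=False)


def eprint(*args) -> None:
    print(*args, file=sys.stderr)
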