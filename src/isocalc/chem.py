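"""Elemental formula algebra, isotope abundance tables and natural
mass-shift distributions.

Everything downstream (channel generation, correction matrices,
theoretical labeling) is built on two primitives defined here:

* an :class:`ElementIsotopeTable` holding, per element, the naturally
  occurring isotopes with their integer mass shift relative to the
  lightest isotope, exact mass and natural abundance;
* :func:`natural_shift_distribution`, the probability distribution of a
  molecule's total integer mass shift obtained by convolving per-atom
  isotope distributions.

All isotopes are binned by *nominal* (integer) mass shift, the
unit-resolution convention: one :sup:`18`\\ O and two :sup:`13`\\ C both
land in the M+2 channel.  This is appropriate for low-resolution
quadrupole data where element-specific fine structure is not resolved.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "Isotope",
    "ElementIsotopeTable",
    "Formula",
    "TracerSpec",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mz",
    "natural_shift_distribution",
]

#: Electron rest mass in Da; charged-ion m/z accounts for gained/lost electrons.
ELECTRON_MASS = 0.000549


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formulas."""


@dataclass(frozen=True)
class Isotope:
    """One isotope of an element.

    Parameters
    ----------
    mass_shift : int
        Integer (nominal) mass difference to the element's lightest isotope.
    mass : float
        Exact isotopic mass in Da.
    abundance : float
        Natural abundance as a fraction in [0, 1].
    """

    mass_shift: int
    mass: float
    abundance: float


# Exact isotope masses: CODATA/IUPAC monoisotopic values (Da).
# Abundances: the values commonly quoted for natural terrestrial material,
# rounded to the precision used throughout this package's reference
# calculations (13C 1.07%, 2H 0.01%, 17O 0.04%, 18O 0.21%, 15N 0.36%,
# 29Si 4.69%, 30Si 3.09%, 33S 0.75%, 34S 4.25%); the lightest isotope
# takes the complement so every element sums to exactly 1.  Published
# tables differ in the third decimal -- use ``ElementIsotopeTable.from_csv``
# to substitute e.g. full-precision IUPAC values.
_DEFAULT_ISOTOPES: dict[str, list[Isotope]] = {
    "H": [Isotope(0, 1.00782503, 0.9999), Isotope(1, 2.01410178, 0.0001)],
    "C": [Isotope(0, 12.0, 0.9893), Isotope(1, 13.00335484, 0.0107)],
    "N": [Isotope(0, 14.00307401, 0.9964), Isotope(1, 15.00010890, 0.0036)],
    "O": [
        Isotope(0, 15.99491462, 0.9975),
        Isotope(1, 16.99913176, 0.0004),
        Isotope(2, 17.99915961, 0.0021),
    ],
    "P": [Isotope(0, 30.97376200, 1.0)],
    "S": [
        Isotope(0, 31.97207117, 0.9500),
        Isotope(1, 32.97145890, 0.0075),
        Isotope(2, 33.96786701, 0.0425),
    ],
    "Si": [
        Isotope(0, 27.97692653, 0.9222),
        Isotope(1, 28.97649466, 0.0469),
        Isotope(2, 29.97377014, 0.0309),
    ],
}


@dataclass(frozen=True)
class ElementIsotopeTable:
    """Per-element isotope data behind every convolution in the package.

    Invariants enforced at construction: per element, abundances sum to 1
    (within 1e-9), mass shifts start at 0 and increase strictly.
    """

    entries: dict[str, tuple[Isotope, ...]]

    def __post_init__(self) -> None:
        for sym, isos in self.entries.items():
            if not isos:
                raise ValueError(f"element {sym!r} has no isotopes")
            shifts = [i.mass_shift for i in isos]
            if shifts[0] != 0 or any(b <= a for a, b in zip(shifts, shifts[1:])):
                raise ValueError(
                    f"element {sym!r}: mass shifts must start at 0 and be "
                    f"strictly increasing, got {shifts}"
                )
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"element {sym!r}: abundances sum to {total!r}, expected 1"
                )
            if any(not (0.0 <= i.abundance <= 1.0) for i in isos):
                raise ValueError(f"element {sym!r}: abundance outside [0, 1]")

    @classmethod
    def default(cls) -> "ElementIsotopeTable":
        """The built-in table covering C, H, N, O, P, S and Si."""
        return cls({k: tuple(v) for k, v in _DEFAULT_ISOTOPES.items()})

    @classmethod
    def from_csv(cls, path) -> "ElementIsotopeTable":
        """Load a replacement table from a CSV with columns
        ``element,shift,exact_mass,abundance`` (one row per isotope)."""
        rows: dict[str, list[Isotope]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"element", "shift", "exact_mass", "abundance"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(
                    f"isotope table must have columns {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            for row in reader:
                rows.setdefault(row["element"], []).append(
                    Isotope(
                        int(row["shift"]),
                        float(row["exact_mass"]),
                        float(row["abundance"]),
                    )
                )
        for isos in rows.values():
            isos.sort(key=lambda i: i.mass_shift)
        return cls({k: tuple(v) for k, v in rows.items()})

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def isotopes(self, symbol: str) -> tuple[Isotope, ...]:
        try:
            return self.entries[symbol]
        except KeyError:
            raise KeyError(f"element {symbol!r} not in isotope table") from None

    def lightest_mass(self, symbol: str) -> float:
        return self.isotopes(symbol)[0].mass

    def shift_vector(self, symbol: str) -> np.ndarray:
        """Single-atom mass-shift distribution as a dense vector indexed
        by integer shift (gaps filled with 0)."""
        isos = self.isotopes(symbol)
        vec = np.zeros(isos[-1].mass_shift + 1)
        for iso in isos:
            vec[iso.mass_shift] = iso.abundance
        return vec

    def max_shift(self, symbol: str) -> int:
        return self.isotopes(symbol)[-1].mass_shift


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental formula: element symbol -> non-negative atom count."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {s: int(c) for s, c in self.counts.items() if c}
        if any(c < 0 for c in clean.values()):
            raise FormulaError(f"negative atom count in {self.counts}")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        return parse_formula(text)

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        out = dict(self.counts)
        for s, c in other.counts.items():
            out[s] = out.get(s, 0) + c
        return Formula(out)

    def __sub__(self, other: "Formula") -> "Formula":
        out = dict(self.counts)
        for s, c in other.counts.items():
            out[s] = out.get(s, 0) - c
            if out[s] < 0:
                raise FormulaError(
                    f"cannot remove {c} {s} from {self}: only {self[s]} present"
                )
        return Formula(out)

    def remove(self, symbol: str, count: int) -> "Formula":
        """Formula with `count` atoms of `symbol` taken out."""
        return self - Formula({symbol: count})

    def contains(self, other: "Formula") -> bool:
        """True if `other` is an elementwise sub-formula of self."""
        return all(self[s] >= c for s, c in other.counts.items())

    def atom_count(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        syms = sorted(
            self.counts,
            key=lambda s: (s != "C", s != "H" if "C" in self.counts else False, s),
        )
        return "".join(f"{s}{self.counts[s] if self.counts[s] != 1 else ''}" for s in syms)


def parse_formula(text: str, table: ElementIsotopeTable | None = None) -> Formula:
    """Parse a molecular formula string such as ``"C6H12O6"``.

    Symbols are one uppercase letter optionally followed by one lowercase
    letter, each with an optional positive integer count (default 1).
    Unknown element symbols (not present in `table`, default table if
    None) are rejected.
    """
    if table is None:
        table = ElementIsotopeTable.default()
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in table:
            raise FormulaError(f"unknown element symbol {sym!r} in formula {text!r}")
        if num == "0":
            raise FormulaError(f"zero count for {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    return Formula(counts)


@dataclass(frozen=True)
class TracerSpec:
    """A stable-isotope tracer: which element is labeled, by how much the
    mass shifts per label, and the isotopic purity of the fed substrate.

    Attributes
    ----------
    element : str
        Labeled element symbol (e.g., "C" for a 13C tracer).
    mass_shift : int
        Integer mass shift per label (1 for 13C or 15N, 2 for 18O...).
    mass_diff : float
        Exact mass difference per label in Da (13C - 12C = 1.003355).
    purity : float
        Isotopic enrichment alpha of the tracer substrate, in (0, 1].
    """

    element: str
    mass_shift: int = 1
    mass_diff: float = 13.00335484 - 12.0
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"tracer purity must be in (0, 1], got {self.purity}")
        if self.mass_shift < 1:
            raise ValueError("tracer mass shift must be a positive integer")

    @classmethod
    def from_string(
        cls,
        spec: str,
        purity: float = 1.0,
        table: ElementIsotopeTable | None = None,
    ) -> "TracerSpec":
        """Build from a nuclide string like ``"13C"``, ``"15N"`` or ``"2H"``.

        The mass shift and exact mass difference are looked up in the
        isotope table; the named heavy isotope must exist there.
        """
        if table is None:
            table = ElementIsotopeTable.default()
        m = re.fullmatch(r"(\d+)([A-Z][a-z]?)", spec.strip())
        if not m:
            raise ValueError(f"cannot parse tracer {spec!r}; expected e.g. '13C'")
        nominal, element = int(m.group(1)), m.group(2)
        isos = table.isotopes(element)
        light = isos[0]
        shift = nominal - round(light.mass)
        for iso in isos[1:]:
            if iso.mass_shift == shift:
                return cls(element, shift, iso.mass - light.mass, purity)
        raise ValueError(
            f"isotope {spec!r} not found in table for element {element!r}"
        )

    def with_purity(self, purity: float) -> "TracerSpec":
        return replace(self, purity=purity)


def monoisotopic_mz(
    formula: Formula,
    charge: int,
    table: ElementIsotopeTable | None = None,
) -> float:
    """m/z of the all-lightest-isotope species of a charged ion.

    Computed as (sum of lightest-isotope exact masses minus
    ``charge * ELECTRON_MASS``) divided by ``|charge|``: a -1 ion gains
    one electron mass, a +1 ion loses one.
    """
    if charge == 0:
        raise ValueError("charge must be nonzero")
    if not formula:
        raise FormulaError("empty formula")
    if table is None:
        table = ElementIsotopeTable.default()
    mass = sum(table.lightest_mass(s) * c for s, c in formula.counts.items())
    return (mass - charge * ELECTRON_MASS) / abs(charge)


def _vector_power(p: np.ndarray, n: int, length: int) -> np.ndarray:
    """`p` convolved with itself `n` times, truncated to `length` entries.

    Truncation is exact for the retained entries: convolution is
    lower-triangular in the shift index, so entries below `length` never
    depend on discarded ones.
    """
    out = np.zeros(length)
    out[0] = 1.0
    base = p[:length].copy()
    while n:
        if n & 1:
            out = np.convolve(out, base)[:length]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:length]
    return out


def natural_shift_distribution(
    formula: Formula,
    max_shift: int | None = None,
    table: ElementIsotopeTable | None = None,
) -> np.ndarray:
    """Probability distribution of a molecule's total integer mass shift.

    Entry ``i`` is the probability that the nominal mass shifts of all
    atoms (every element, heavy isotopes binned by integer shift) sum to
    ``i``.  Computed per element by repeated self-convolution of the
    single-atom shift vector, then convolved across elements.

    Parameters
    ----------
    formula : Formula
        Non-empty elemental formula.
    max_shift : int, optional
        Truncate the returned vector to shifts ``0..max_shift``.  ``None``
        returns the full (untruncated) distribution, which sums to 1.
    table : ElementIsotopeTable, optional
        Abundance table; the package default when omitted.
    """
    if not formula:
        raise FormulaError("empty formula")
    if table is None:
        table = ElementIsotopeTable.default()
    if max_shift is not None and max_shift < 0:
        raise ValueError("max_shift must be non-negative")

    full_extent = 1 + sum(
        table.max_shift(s) * c for s, c in formula.counts.items()
    )
    # Guard band of 2 beyond the request keeps the workspace cheap while the
    # truncation itself stays exact (see _vector_power).
    length = full_extent if max_shift is None else min(max_shift + 3, full_extent)

    dist = np.zeros(length)
    dist[0] = 1.0
    for sym, count in formula.counts.items():
        atom = table.shift_vector(sym)
        dist = np.convolve(dist, _vector_power(atom, count, length))[:length]
    if max_shift is not None:
        out = np.zeros(max_shift + 1)
        k = min(max_shift + 1, length)
        out[:k] = dist[:k]
        return out
    return dist
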