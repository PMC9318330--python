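"""Built-in target definitions for the worked examples.

Two target sets are provided:

* :func:`gcms_targets` — 15 methoxyaminated / TBDMS-derivatized amino
  acids and central-carbon intermediates measured by GC-MS (electron
  ionization [M-57]+ fragments, i.e. loss of a tert-butyl radical from
  the silylated molecule).  ``n_tracer_positions`` counts the metabolite
  backbone carbons; the many derivatization carbons and the abundant
  29Si/30Si isotopes make these ions a stringent test of natural-isotope
  correction.
* :func:`glycerolipid_targets` — yeast glycerolipids: 6 lipid classes x
  the 10 unordered combinations of two acyl chains from {16:0, 16:1,
  18:0, 18:1}, as the adduct ions observed in LC-MS.  Tracer positions
  under [U-13C]glucose are the two acyl chains + the glycerol backbone
  (3 C) + the headgroup carbons.

Formulas are assembled by plain formula arithmetic: e.g. a
diacylglycerol is glycerol + two fatty acids - 2 H2O, and each
phospholipid class adds HPO3 + its head alcohol - H2O.
"""

from __future__ import annotations

from importlib import resources

from .chem import Formula, parse_formula
from .channels import FragmentIon
from .io import read_targets

__all__ = [
    "gcms_targets",
    "glycerolipid_targets",
    "glycerolipid_species",
    "ACYL_CHAINS",
    "LIPID_CLASSES",
]


def gcms_targets() -> list[FragmentIon]:
    """The packaged 15-ion GC-MS target set (TBDMS [M-57]+ fragments)."""
    path = resources.files("isocalc.data") / "gcms_targets.csv"
    with resources.as_file(path) as p:
        return read_targets(p)  # type: ignore[return-value]


#: (carbons, double bonds) of the acyl chains dominant in S. cerevisiae
ACYL_CHAINS = ["16:0", "16:1", "18:0", "18:1"]

_GLYCEROL = parse_formula("C3H8O3")
_WATER = parse_formula("H2O")
_HPO3 = parse_formula("HO3P")

# head alcohol esterified onto the phosphate, headgroup tracer carbons,
# adduct formula delta, adduct charge
LIPID_CLASSES: dict[str, dict] = {
    "PC": {"head": "C5H13NO", "head_c": 5, "adduct": ("+C2H3O2", -1)},   # [M+CH3COO]-
    "PE": {"head": "C2H7NO", "head_c": 2, "adduct": ("-H", -1)},         # [M-H]-
    "PI": {"head": "C6H12O6", "head_c": 6, "adduct": ("-H", -1)},        # [M-H]-
    "PS": {"head": "C3H7NO3", "head_c": 3, "adduct": ("-H", -1)},        # [M-H]-
    "PG": {"head": "C3H8O3", "head_c": 3, "adduct": ("-H", -1)},         # [M-H]-
    "DAG": {"head": None, "head_c": 0, "adduct": ("+NH4", 1)},           # [M+NH4]+
}


def _acyl(chain: str) -> tuple[Formula, int]:
    """Free fatty acid formula CcH(2c-2d)O2 and its carbon count."""
    c, d = (int(v) for v in chain.split(":"))
    return Formula({"C": c, "H": 2 * c - 2 * d, "O": 2}), c


def _apply_adduct(neutral: Formula, adduct: str) -> Formula:
    sign, body = adduct[0], adduct[1:]
    delta = parse_formula(body)
    return neutral + delta if sign == "+" else neutral - delta


def glycerolipid_species(
    lipid_class: str, chain_a: str, chain_b: str
) -> FragmentIon:
    """Build the detected adduct ion of one glycerolipid molecular species.

    ``n_tracer_positions`` = acyl carbons + 3 glycerol carbons +
    headgroup carbons, i.e. every carbon of the neutral lipid — all are
    glucose-derived under [U-13C]glucose labeling.
    """
    try:
        cls = LIPID_CLASSES[lipid_class]
    except KeyError:
        raise ValueError(
            f"unknown lipid class {lipid_class!r}; expected one of "
            f"{sorted(LIPID_CLASSES)}"
        ) from None
    fa_a, ca = _acyl(chain_a)
    fa_b, cb = _acyl(chain_b)
    dag = _GLYCEROL + fa_a + fa_b - _WATER - _WATER
    neutral = dag
    if cls["head"] is not None:
        neutral = dag + _HPO3 + parse_formula(cls["head"]) - _WATER
    adduct, charge = cls["adduct"]
    ion = _apply_adduct(neutral, adduct)
    n = ca + cb + 3 + cls["head_c"]
    return FragmentIon(
        name=f"{lipid_class} {chain_a}_{chain_b}",
        formula=ion,
        charge=charge,
        n_tracer_positions=n,
    )


def glycerolipid_targets(
    classes: list[str] | None = None,
    chains: list[str] | None = None,
) -> list[FragmentIon]:
    """All lipid class x unordered acyl-chain-pair combinations.

    Defaults reproduce the yeast survey: 6 classes x 10 pairs from 4
    chains = 60 molecular species.
    """
    classes = list(LIPID_CLASSES) if classes is None else classes
    chains = ACYL_CHAINS if chains is None else chains
    out = []
    for cls in classes:
        for i, a in enumerate(chains):
            for b in chains[i:]:
                out.append(glycerolipid_species(cls, a, b))
    return out
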