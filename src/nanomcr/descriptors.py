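"""Physicochemical descriptors, druglikeness filters and the CNS MPO score.

Descriptors are computed with RDKit: molecular weight, Crippen cLogP,
topological polar surface area, H-bond donor/acceptor counts, rotatable
bonds, molar refractivity and simple atom/ring counts.  Donors and
acceptors follow the original rule-of-five conventions: a donor is any N or
O atom bearing at least one hydrogen (one *group* regardless of its H
count, so water contributes one donor), and an acceptor is any N or O
atom.  Two
quantities the toolkit cannot compute from structure alone — the
distribution coefficient cLogD and the strongest basic pKa — are read from
a user-supplied side table when available and otherwise replaced by
transparent stubs (cLogD := cLogP, pKa := 7.0) whose provenance is flagged
on every vector.

Filters implement the standard inclusive-bound rule sets:

* Lipinski: MW <= 500, cLogP <= 5, NHD <= 5, NHA <= 10
* Ghose: 160 <= MW <= 480, -0.4 <= cLogP <= 5.6, 40 <= MR <= 130,
  20 <= heavy atoms <= 70
* Muegge: 200 <= MW <= 600, -2 <= cLogP <= 5, TPSA <= 150, rings <= 7,
  carbons > 4, heteroatoms > 1, rotatable bonds <= 15, NHA <= 10, NHD <= 5

The CNS multi-parameter optimisation (MPO) score sums six piecewise-linear
desirability transforms (cLogP, cLogD, MW, TPSA, NHD, strongest basic pKa),
each in [0, 1], for a total in [0, 6]; scores > 5 are classed ``high`` and
<= 2 ``low``.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

_DONOR = Chem.MolFromSmarts("[#7,#8;!H0]")
_ACCEPTOR = Chem.MolFromSmarts("[#7,#8]")


@dataclass(frozen=True)
class DescriptorVector:
    mw: float
    clogp: float
    clogd: float
    tpsa: float
    nha: int
    nhd: int
    num_rot_bonds: int
    basic_pka: float
    molar_refractivity: float
    atom_count: int          # heavy atoms
    carbon_count: int
    heteroatom_count: int
    ring_count: int
    clogd_source: str = "stub"   # "stub" or "table"
    pka_source: str = "stub"

    def replace(self, **kwargs) -> "DescriptorVector":
        from dataclasses import replace

        return replace(self, **kwargs)


def compute_descriptors(
    structure: str,
    side_table: dict[str, dict[str, float]] | None = None,
    key: str | None = None,
) -> DescriptorVector:
    """Descriptor vector for a SMILES string.

    ``side_table`` maps a molecule key (usually its id) to optional
    ``{"clogd": ..., "basic_pka": ...}`` entries from external predictors.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"structure does not parse: {structure!r}")
    clogp = Crippen.MolLogP(mol)
    clogd, clogd_source = clogp, "stub"
    basic_pka, pka_source = 7.0, "stub"
    if side_table and key is not None and key in side_table:
        entry = side_table[key]
        if "clogd" in entry:
            clogd, clogd_source = float(entry["clogd"]), "table"
        if "basic_pka" in entry:
            basic_pka, pka_source = float(entry["basic_pka"]), "table"
    carbons = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        clogp=clogp,
        clogd=clogd,
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        nha=len(mol.GetSubstructMatches(_ACCEPTOR)),
        nhd=len(mol.GetSubstructMatches(_DONOR)),
        num_rot_bonds=Lipinski.NumRotatableBonds(mol),
        basic_pka=basic_pka,
        molar_refractivity=Crippen.MolMR(mol),
        atom_count=mol.GetNumHeavyAtoms(),
        carbon_count=carbons,
        heteroatom_count=mol.GetNumHeavyAtoms() - carbons,
        ring_count=rdMolDescriptors.CalcNumRings(mol),
        clogd_source=clogd_source,
        pka_source=pka_source,
    )


@dataclass(frozen=True)
class FilterResult:
    name: str
    violations: int
    passed: bool


def lipinski(v: DescriptorVector) -> FilterResult:
    rules = [v.mw <= 500, v.clogp <= 5, v.nhd <= 5, v.nha <= 10]
    violations = sum(not ok for ok in rules)
    return FilterResult("lipinski", violations, violations == 0)


def ghose(v: DescriptorVector) -> FilterResult:
    rules = [
        160 <= v.mw <= 480,
        -0.4 <= v.clogp <= 5.6,
        40 <= v.molar_refractivity <= 130,
        20 <= v.atom_count <= 70,
    ]
    violations = sum(not ok for ok in rules)
    return FilterResult("ghose", violations, violations == 0)


def muegge(v: DescriptorVector) -> FilterResult:
    rules = [
        200 <= v.mw <= 600,
        -2 <= v.clogp <= 5,
        v.tpsa <= 150,
        v.ring_count <= 7,
        v.carbon_count > 4,
        v.heteroatom_count > 1,
        v.num_rot_bonds <= 15,
        v.nha <= 10,
        v.nhd <= 5,
    ]
    violations = sum(not ok for ok in rules)
    return FilterResult("muegge", violations, violations == 0)


def pass_all3(v: DescriptorVector) -> bool:
    return lipinski(v).passed and ghose(v).passed and muegge(v).passed


# ---------------------------------------------------------------------------
# CNS MPO
# ---------------------------------------------------------------------------


def _desc_down(x: float, lo: float, hi: float) -> float:
    """Monotone-decreasing desirability: 1 below ``lo``, 0 above ``hi``."""
    if x <= lo:
        return 1.0
    if x >= hi:
        return 0.0
    return (hi - x) / (hi - lo)


def _desc_hump(x: float, zero_lo: float, one_lo: float, one_hi: float, zero_hi: float) -> float:
    """Trapezoidal desirability: 0 outside, 1 on the plateau, linear ramps."""
    if x <= zero_lo or x >= zero_hi:
        return 0.0
    if one_lo <= x <= one_hi:
        return 1.0
    if x < one_lo:
        return (x - zero_lo) / (one_lo - zero_lo)
    return (zero_hi - x) / (zero_hi - one_hi)


#: Default transform parameters; override to explore alternative weightings.
MPO_PARAMS: dict[str, tuple] = {
    "clogp": (3.0, 5.0),
    "clogd": (2.0, 4.0),
    "mw": (360.0, 500.0),
    "tpsa": (20.0, 40.0, 90.0, 120.0),
    "nhd": (0.5, 3.5),
    "basic_pka": (8.0, 10.0),
}


@dataclass(frozen=True)
class MPOResult:
    score: float
    components: dict[str, float]
    cns_class: str  # "high" (>5), "low" (<=2) or "mid"


def cns_mpo(v: DescriptorVector, params: dict[str, tuple] | None = None) -> MPOResult:
    p = MPO_PARAMS if params is None else params
    components = {
        "clogp": _desc_down(v.clogp, *p["clogp"]),
        "clogd": _desc_down(v.clogd, *p["clogd"]),
        "mw": _desc_down(v.mw, *p["mw"]),
        "tpsa": _desc_hump(v.tpsa, *p["tpsa"]),
        "nhd": _desc_down(v.nhd, *p["nhd"]),
        "basic_pka": _desc_down(v.basic_pka, *p["basic_pka"]),
    }
    score = sum(components.values())
    if score > 5:
        cns_class = "high"
    elif score <= 2:
        cns_class = "low"
    else:
        cns_class = "mid"
    return MPOResult(score=score, components=components, cns_class=cns_class)
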