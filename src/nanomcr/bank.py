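"""Classed building-block banks for multicomponent-reaction campaigns.

A campaign draws its reactants from a single 384-well source plate holding
classed building blocks (amidines, aldehydes, ketones, isocyanides,
carboxylic acids, primary and secondary amines) plus a handful of fixed
reagents (catalysts, azide source, special aldehydes).  Each stock is
prepared in a low-volatility "transporter solvent" (ethylene glycol by
default) at one of three concentration tiers (0.5, 0.25 or 0.16 M) so that
it can be moved by acoustic droplet ejection.

This module defines the in-memory bank, a deterministic synthetic-bank
generator (curated seed fragments decorated combinatorially), and plain-text
bank I/O (per-class SMILES files plus a CSV manifest).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

STOCK_TIERS = (0.5, 0.25, 0.16)
SOLVENTS = ("ethylene_glycol", "2-methoxyethanol", "dimethoxyethane")

#: Canonical class order (also the source-plate grouping order).
BB_CLASSES = (
    "amidine",
    "aldehyde",
    "ketone",
    "isocyanide",
    "carboxylic_acid",
    "primary_amine",
    "secondary_amine",
    "amino_acid",
    "dipeptide",
    "special",
)

_ID_PREFIX = {
    "amidine": "A",
    "aldehyde": "B",
    "ketone": "K",
    "isocyanide": "I",
    "carboxylic_acid": "C",
    "primary_amine": "P",
    "secondary_amine": "S",
    "amino_acid": "X",
    "dipeptide": "D",
    "special": "R",
}

#: Class-defining substructures.  ``special`` holds fixed reagents of mixed
#: chemistry and is deliberately unconstrained.
CLASS_PATTERNS: dict[str, str | None] = {
    "amidine": "[NX3;H2]-[c]:[n;X2;H0]",
    "aldehyde": "[CX3;H1](=O)[#6]",
    "ketone": "[#6][CX3](=O)[#6]",
    "isocyanide": "[N+]#[C-]",
    "carboxylic_acid": "[CX3](=O)[OX2;H1]",
    "primary_amine": "[NX3;H2][CX4]",
    "secondary_amine": "[NX3;H1]([CX4])[CX4]",
    "amino_acid": "[NX3;H2][CX4][CX3](=O)[OX2;H1]",
    "dipeptide": "[NX3;H2][CX4][CX3](=O)[NX3;H1][CX4][CX3](=O)[OX2;H1]",
    "special": None,
}

_COMPILED = {
    cls: Chem.MolFromSmarts(pat) if pat else None for cls, pat in CLASS_PATTERNS.items()
}


class CapacityError(ValueError):
    """Requested bank does not fit one 384-well source plate."""


class BankError(ValueError):
    """Invalid bank contents."""


@dataclass(frozen=True)
class BuildingBlock:
    """One classed reagent with structure and stock metadata."""

    id: str
    bb_class: str
    structure: str
    mw: float
    stock_conc: float = 0.5
    solvent: str = "ethylene_glycol"

    def validate(self) -> None:
        if self.bb_class not in BB_CLASSES:
            raise BankError(f"unknown building-block class {self.bb_class!r}")
        mol = Chem.MolFromSmiles(self.structure)
        if mol is None:
            raise BankError(f"{self.id}: structure {self.structure!r} does not parse")
        patt = _COMPILED[self.bb_class]
        if patt is not None and not mol.HasSubstructMatch(patt):
            raise BankError(
                f"{self.id}: structure lacks the {self.bb_class} defining group"
            )
        if self.stock_conc not in STOCK_TIERS:
            raise BankError(
                f"{self.id}: stock_conc {self.stock_conc} not in tiers {STOCK_TIERS}"
            )
        if self.solvent not in SOLVENTS:
            raise BankError(f"{self.id}: unknown solvent {self.solvent!r}")
        if not self.mw > 0:
            raise BankError(f"{self.id}: mw must be positive")


@dataclass
class Bank:
    """A collection of building blocks indexed by class."""

    blocks: list[BuildingBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [b.id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise BankError("duplicate building-block ids")
        self._by_id = {b.id: b for b in self.blocks}
        self.class_index: dict[str, list[str]] = {}
        for b in self.blocks:
            self.class_index.setdefault(b.bb_class, []).append(b.id)

    def __len__(self) -> int:
        return len(self.blocks)

    def get(self, block_id: str) -> BuildingBlock:
        return self._by_id[block_id]

    def members(self, bb_class: str) -> list[BuildingBlock]:
        return [self._by_id[i] for i in self.class_index.get(bb_class, [])]

    def class_sizes(self) -> dict[str, int]:
        return {cls: len(ids) for cls, ids in self.class_index.items()}

    def validate(self) -> None:
        for b in self.blocks:
            b.validate()


# ---------------------------------------------------------------------------
# Synthetic bank generation
# ---------------------------------------------------------------------------

# Ring/side-chain substituents used to decorate the seed cores.  The mix of
# halogens (incl. iodine), methyl/methoxy, nitro, trifluoromethyl and nitrile
# mirrors the electron-rich/poor spread a diversity-oriented bank aims for.
_SUBSTITUENTS = (
    "",
    "(F)",
    "(Cl)",
    "(Br)",
    "(I)",
    "(C)",
    "(OC)",
    "([N+](=O)[O-])",
    "(C(F)(F)F)",
    "(C#N)",
)

# Curated seed cores per class.  ``{}`` marks the decoration point.  Entries
# without a placeholder are fixed members appended to the decorated pool.
_CORES: dict[str, tuple[list[str], list[str]]] = {
    "amidine": (
        [
            "Nc1ccc{}cn1",       # 2-aminopyridines (GBB workhorses)
            "Nc1cc{}ccn1",
            "Nc1ncc{}cn1",       # 2-aminopyrimidines
            "Nc1ncc{}s1",        # 2-aminothiazoles
            "Nc1ncc{}o1",        # 2-aminooxazoles
            "Nc1cc{}n(C)n1",     # N-methyl 3-aminopyrazoles
        ],
        ["Nc1ncnn1C", "Nc1nc[nH]n1"],  # aminotriazoles (electron-poor cases)
    ),
    "aldehyde": (
        [
            "O=Cc1ccc{}cc1",
            "O=Cc1cccc{}c1",
            "O=Cc1ccc{}o1",
            "O=Cc1ccc{}s1",
            "O=Cc1ccc{}cn1",
            "O=CC1CCC{}CC1",
            "O=CCc1ccc{}cc1",
            "O=Cc1c[nH]c2ccc{}cc12",
        ],
        [],
    ),
    "ketone": (
        [
            "O=C(C)c1ccc{}cc1",
            "O=C1CCC{}CC1",
            "O=C(C)C1CCC{}CC1",
            "O=C(CC)c1ccc{}cc1",
        ],
        ["O=C1CCc2ccccc21", "O=C(C)C(C)C"],
    ),
    "isocyanide": (
        [
            "[C-]#[N+]Cc1ccc{}cc1",
            "[C-]#[N+]c1ccc{}cc1",
            "[C-]#[N+]C1CCC{}CC1",
            "[C-]#[N+]CCc1ccc{}cc1",
            "[C-]#[N+]CCOc1ccc{}cc1",
            "[C-]#[N+]CC(=O)OCc1ccc{}cc1",  # alpha-acidic (Orru-competent)
        ],
        [
            "[C-]#[N+]C(C)(C)C",
            "[C-]#[N+]C1CCCC1",
            "[C-]#[N+]CC(=O)OC",
            "[C-]#[N+]CC(=O)OCC",
            "[C-]#[N+]CCOC",
            "[C-]#[N+]C1CCCCC1",
            "[C-]#[N+]CC1CCCCC1",
            "[C-]#[N+]CCC(C)C",
        ],
    ),
    "carboxylic_acid": (
        [
            "OC(=O)c1ccc{}cc1",
            "OC(=O)c1cccc{}c1",
            "OC(=O)Cc1ccc{}cc1",
            "OC(=O)c1ccc{}o1",
            "OC(=O)c1ccc{}s1",
            "OC(=O)c1ccc{}cn1",
            "OC(=O)C1CCC{}CC1",
            "OC(=O)CCc1ccc{}cc1",
            "OC(=O)COc1ccc{}cc1",
        ],
        ["OC(=O)c1ccccc1N", "OC(=O)C(C)C", "OC(=O)CC(C)C"],  # incl. anthranilic
    ),
    "primary_amine": (
        [
            "NCc1ccc{}cc1",
            "NCCc1ccc{}cc1",     # 2-arylethylamines (Pictet-Spengler competent)
            "NCC1CCC{}CC1",
            "NCCOc1ccc{}cc1",
        ],
        [
            # alpha-amino acids with nucleophilic side chains and short
            # dipeptides live in this class too: chemically they are primary
            # amines, and the intramolecular Ugi variants select them through
            # their transformation templates.
            "NCCCCC(N)C(=O)O",        # lysine
            "NCCCC(N)C(=O)O",         # ornithine
            "OCCCCC(N)C(=O)O",        # extended homoserine
            "NCC(=O)NCC(=O)O",        # Gly-Gly
            "CC(N)C(=O)NCC(=O)O",     # Ala-Gly
            "NCC(=O)NC(C)C(=O)O",     # Gly-Ala
            "CC(C)C(N)C(=O)NCC(=O)O", # Val-Gly
            "NCCc1c[nH]c2ccccc12",    # tryptamine
        ],
    ),
    "secondary_amine": (
        [
            "N1CCC{}CC1",
            "N1CCC{}C1",
            "CNCc1ccc{}cc1",
            "CNCCc1ccc{}cc1",
        ],
        ["C1COCCN1", "CN1CCNCC1"],  # morpholine, N-methylpiperazine
    ),
    "amino_acid": (
        [],
        [
            "NCCCCC(N)C(=O)O",   # lysine
            "NCCCC(N)C(=O)O",    # ornithine
            "OCCCCC(N)C(=O)O",   # extended homoserine
            "OCCC(N)C(=O)O",     # homoserine
            "SCCC(N)C(=O)O",     # homocysteine
            "OCC(N)C(=O)O",      # serine
            "SCC(N)C(=O)O",      # cysteine
            "NCCC(N)C(=O)O",     # 2,4-diaminobutyric acid
        ],
    ),
    "dipeptide": (
        [],
        [
            "NCC(=O)NCC(=O)O",
            "CC(N)C(=O)NCC(=O)O",
            "NCC(=O)NC(C)C(=O)O",
            "CC(C)C(N)C(=O)NCC(=O)O",
            "CC(C)CC(N)C(=O)NCC(=O)O",
            "NCC(=O)NC(Cc1ccccc1)C(=O)O",
            "CC(N)C(=O)NC(C)C(=O)O",
            "OCC(N)C(=O)NCC(=O)O",
        ],
    ),
}

#: Fixed reagents referenced by reaction schemes (catalysts, azide source,
#: special bifunctional aldehydes).  Their ids are stable names so schemes can
#: reference them directly.
SPECIAL_REAGENTS: tuple[tuple[str, str], ...] = (
    ("TMSN3", "C[Si](C)(C)N=[N+]=[N-]"),
    ("ScOTf3", "O=S(=O)([O-])C(F)(F)F.O=S(=O)([O-])C(F)(F)F.O=S(=O)([O-])C(F)(F)F.[Sc+3]"),
    ("TosMIC", "[C-]#[N+]CS(=O)(=O)c1ccc(C)cc1"),
    ("KOCN", "[K+].[N-]=C=O"),
    ("MFB", "COC(=O)c1ccccc1C=O"),  # methyl 2-formylbenzoate
    ("FormicAcid", "OC=O"),
    ("AcOH", "CC(=O)O"),
    ("Et3N", "CCN(CC)CC"),
    ("PhPO2H2", "O=P(O)c1ccccc1"),
    ("TFA", "OC(=O)C(F)(F)F"),
    ("ZnCl2", "Cl[Zn]Cl"),
    ("MgSO4", "O=S(=O)([O-])[O-].[Mg+2]"),
    ("DIPEA", "CCN(C(C)C)C(C)C"),
    ("BF3OEt2", "CCO[B-](F)(F)F.[H+]"),
    ("Piperidine", "C1CCNCC1"),
    ("DBU", "C1CCC2=NCCCN2CC1"),
    ("pTsOH", "Cc1ccc(S(=O)(=O)O)cc1"),
    ("Glyoxal", "O=CC=O"),
    ("Paraformaldehyde", "C=O"),
    ("NH4Cl", "[NH4+].[Cl-]"),
)


def _class_pool(bb_class: str) -> list[str]:
    """Ordered, de-duplicated canonical SMILES pool for one class."""
    if bb_class == "special":
        return [smi for _, smi in SPECIAL_REAGENTS]
    cores, fixed = _CORES[bb_class]
    seen: dict[str, None] = {}
    for core in cores:
        for sub in _SUBSTITUENTS:
            smi = core.format(sub)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            seen.setdefault(Chem.MolToSmiles(mol), None)
    for smi in fixed:
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            seen.setdefault(Chem.MolToSmiles(mol), None)
    return list(seen)


def generate_bank(
    class_sizes: dict[str, int],
    seed: int = 0,
    *,
    tier_weights: tuple[float, float, float] = (0.7, 0.2, 0.1),
    solvent_weights: tuple[float, float, float] = (0.8, 0.15, 0.05),
    stock_overrides: dict[str, float] | None = None,
) -> Bank:
    """Generate a deterministic synthetic bank with the requested class sizes.

    Structures are drawn from curated per-class seed cores decorated with
    halogen/methyl/methoxy/nitro/CF3/CN substituents, so every member is
    chemically valid, distinct and carries its class-defining group.  Stock
    concentrations default to 0.5 M with a seeded minority diluted to 0.25 or
    0.16 M, emulating limited-solubility stocks; ``stock_overrides`` (id ->
    tier) pins individual blocks.

    Raises :class:`CapacityError` when the total exceeds one 384-well source
    plate, and ``KeyError`` for unknown classes.
    """
    import numpy as np

    for cls, n in class_sizes.items():
        if cls not in BB_CLASSES:
            raise KeyError(f"unknown building-block class {cls!r}")
        if n < 0:
            raise ValueError(f"negative count for class {cls!r}")
    total = sum(class_sizes.values())
    if total > 384:
        raise CapacityError(
            f"{total} blocks do not fit one 384-well source plate"
        )

    rng = np.random.default_rng(seed)
    blocks: list[BuildingBlock] = []
    for cls in BB_CLASSES:
        n = class_sizes.get(cls, 0)
        if n == 0:
            continue
        pool = _class_pool(cls)
        if n > len(pool):
            raise ValueError(
                f"class {cls!r}: requested {n} members but only "
                f"{len(pool)} distinct structures are available"
            )
        if cls == "special":
            chosen = pool[:n]  # fixed reagents keep their canonical order
            chosen_ids = [SPECIAL_REAGENTS[i][0] for i in range(n)]
        else:
            idx = rng.permutation(len(pool))[:n]
            chosen = [pool[i] for i in sorted(idx)]
            prefix = _ID_PREFIX[cls]
            chosen_ids = [f"{prefix}-{k + 1}" for k in range(n)]
        concs = rng.choice(STOCK_TIERS, size=n, p=tier_weights)
        solvs = rng.choice(SOLVENTS, size=n, p=solvent_weights)
        for bid, smi, conc, solv in zip(chosen_ids, chosen, concs, solvs):
            if stock_overrides and bid in stock_overrides:
                conc = stock_overrides[bid]
            mol = Chem.MolFromSmiles(smi)
            blocks.append(
                BuildingBlock(
                    id=bid,
                    bb_class=cls,
                    structure=smi,
                    mw=Descriptors.MolWt(mol),
                    stock_conc=float(conc),
                    solvent=str(solv),
                )
            )
    bank = Bank(blocks)
    bank.validate()
    return bank


#: Class sizes of the campaign's variable building blocks (316 in total).
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "amidine": 36,
    "aldehyde": 52,
    "ketone": 15,
    "isocyanide": 64,
    "carboxylic_acid": 71,
    "primary_amine": 46,
    "secondary_amine": 32,
}


def default_campaign_bank(seed: int = 0, n_special: int = 20) -> Bank:
    """The study-scale bank: 316 variable blocks plus fixed reagents.

    The 20 ``special`` entries bring the source plate to 336 occupied wells
    (building blocks *and* reagents).
    """
    sizes = dict(DEFAULT_CLASS_SIZES)
    sizes["special"] = n_special
    return generate_bank(sizes, seed=seed)


# ---------------------------------------------------------------------------
# Bank I/O: per-class two-column SMILES files plus a CSV manifest
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.csv"


def write_bank(bank: Bank, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / _MANIFEST, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "class", "stock_conc", "solvent"])
        for b in bank.blocks:
            writer.writerow([b.id, b.bb_class, b.stock_conc, b.solvent])
    for cls, ids in bank.class_index.items():
        with open(directory / f"{cls}.smi", "w") as fh:
            for bid in ids:
                fh.write(f"{bank.get(bid).structure}\t{bid}\n")


def read_bank(directory: str | Path) -> Bank:
    directory = Path(directory)
    meta: dict[str, tuple[str, float, str]] = {}
    with open(directory / _MANIFEST, newline="") as fh:
        for row in csv.DictReader(fh):
            meta[row["id"]] = (
                row["class"],
                float(row["stock_conc"]),
                row["solvent"],
            )
    blocks = []
    for cls in BB_CLASSES:
        path = directory / f"{cls}.smi"
        if not path.exists():
            continue
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            smi, bid = line.split("\t")
            if bid not in meta:
                raise BankError(f"{bid} present in {path.name} but not in manifest")
            mcls, conc, solv = meta[bid]
            if mcls != cls:
                raise BankError(f"{bid}: class mismatch between manifest and {path.name}")
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise BankError(f"{bid}: structure does not parse")
            blocks.append(
                BuildingBlock(
                    id=bid,
                    bb_class=cls,
                    structure=smi,
                    mw=Descriptors.MolWt(mol),
                    stock_conc=conc,
                    solvent=solv,
                )
            )
    bank = Bank(blocks)
    bank.validate()
    return bank
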