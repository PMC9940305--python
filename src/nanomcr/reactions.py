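"""Reaction schemes, virtual enumeration and combinatorial-space arithmetic.

Each of the campaign's multicomponent reactions is encoded as a
:class:`ReactionScheme`: an ordered list of variable building-block classes
(the *slots*), fixed reagents, a reaction-SMARTS transformation template and
per-well conditions.  Applying the template to one building block per slot
yields a :class:`VirtualProduct`; the full Cartesian product of slot classes
is the scheme's theoretical space.

Template application failures (a building block that lacks the required
reacting group, or a combination whose product cannot be sanitised) are
recorded as skipped combinations rather than raised — mirroring real
building-block incompatibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from .bank import BB_CLASSES, Bank

SCALE_TIERS = (300, 375, 500)


class SchemeError(ValueError):
    """Malformed or conflicting reaction-scheme definition."""


@dataclass
class ReactionScheme:
    """One multicomponent reaction: typed slots plus a transformation template."""

    scheme_id: int
    name: str
    slots: list[str]
    template: str
    reagents: list[dict] = field(default_factory=list)
    scale_nmol: int = 500
    conditions: dict = field(default_factory=dict)
    post_additions: list[str] = field(default_factory=list)
    post_step: str | None = None
    provenance: str = "inferred"

    def __post_init__(self) -> None:
        if not self.slots:
            raise SchemeError(f"scheme {self.scheme_id}: slots must be non-empty")
        for cls in self.slots:
            if cls not in BB_CLASSES:
                raise SchemeError(
                    f"scheme {self.scheme_id}: unknown slot class {cls!r}"
                )
        if self.scale_nmol not in SCALE_TIERS:
            raise SchemeError(
                f"scheme {self.scheme_id}: scale {self.scale_nmol} nmol is not "
                f"one of {SCALE_TIERS}"
            )
        try:
            self._rxn = AllChem.ReactionFromSmarts(self.template)
        except Exception as exc:  # pragma: no cover - RDKit raises varied types
            raise SchemeError(
                f"scheme {self.scheme_id}: template does not parse: {exc}"
            ) from exc
        if self._rxn.GetNumReactantTemplates() != len(self.slots):
            raise SchemeError(
                f"scheme {self.scheme_id}: template consumes "
                f"{self._rxn.GetNumReactantTemplates()} reactants but declares "
                f"{len(self.slots)} slots"
            )

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        return self._rxn

    @property
    def slot_labels(self) -> list[str]:
        """Unique per-slot labels (class name, suffixed when repeated)."""
        counts: dict[str, int] = {}
        labels = []
        for cls in self.slots:
            counts[cls] = counts.get(cls, 0) + 1
            labels.append(cls if self.slots.count(cls) == 1 else f"{cls}_{counts[cls]}")
        return labels


@dataclass(frozen=True)
class VirtualProduct:
    scheme_id: int
    slot_choice: tuple[str, ...]  # building-block ids, ordered as the slots
    product_structure: str


@dataclass(frozen=True)
class SkippedCombination:
    scheme_id: int
    slot_choice: tuple[str, ...]
    reason: str


@dataclass
class EnumerationResult:
    products: list[VirtualProduct]
    skipped: list[SkippedCombination]

    def __iter__(self):
        return iter(self.products)

    def __len__(self) -> int:
        return len(self.products)


class SchemeRegistry:
    """Ordered collection of reaction schemes keyed by scheme id."""

    def __init__(self, schemes: Iterable[ReactionScheme] = ()) -> None:
        self._schemes: dict[int, ReactionScheme] = {}
        for s in schemes:
            self.register(s)

    def register(self, scheme: ReactionScheme) -> "SchemeRegistry":
        if scheme.scheme_id in self._schemes:
            raise SchemeError(f"scheme id {scheme.scheme_id} already registered")
        self._schemes[scheme.scheme_id] = scheme
        return self

    def get(self, scheme_id: int) -> ReactionScheme:
        return self._schemes[scheme_id]

    def __iter__(self):
        return iter(sorted(self._schemes.values(), key=lambda s: s.scheme_id))

    def __len__(self) -> int:
        return len(self._schemes)

    def __contains__(self, scheme_id: int) -> bool:
        return scheme_id in self._schemes

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemeRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "SchemeRegistry":
        reg = cls()
        for entry in doc["schemes"]:
            reg.register(ReactionScheme(**entry))
        return reg


def builtin_registry() -> SchemeRegistry:
    """The 16 campaign schemes shipped with the package."""
    text = resources.files("nanomcr.data").joinpath("schemes.yaml").read_text()
    return SchemeRegistry._from_doc(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Enumeration and space arithmetic
# ---------------------------------------------------------------------------


def _decode_index(idx: int, sizes: Sequence[int]) -> tuple[int, ...]:
    """Mixed-radix decoding of a flat combination index (last slot fastest)."""
    out = []
    for size in reversed(sizes):
        out.append(idx % size)
        idx //= size
    return tuple(reversed(out))


def sample_combination_indices(
    space: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` distinct integers drawn uniformly from ``range(space)``."""
    if n > space:
        raise ValueError(f"cannot draw {n} distinct combinations from {space}")
    if space <= 2_000_000:
        return rng.permutation(space)[:n]
    chosen: set[int] = set()
    out = []
    while len(out) < n:
        cand = int(rng.integers(space))
        if cand not in chosen:
            chosen.add(cand)
            out.append(cand)
    return np.asarray(out, dtype=np.int64)


def apply_template(
    scheme: ReactionScheme, mols: Sequence[Chem.Mol]
) -> tuple[str | None, str | None]:
    """Run the scheme template on one molecule per slot.

    Returns ``(canonical product SMILES, None)`` on success or
    ``(None, reason)`` when the combination is incompatible.
    """
    try:
        product_sets = scheme.rxn.RunReactants(tuple(mols))
    except Exception as exc:
        return None, f"template application error: {exc}"
    if not product_sets:
        return None, "no template match"
    for (prod,) in product_sets:
        try:
            Chem.SanitizeMol(prod)
        except Exception:
            continue
        return Chem.MolToSmiles(prod), None
    return None, "product sanitization failed"


def enumerate_products(
    scheme: ReactionScheme,
    bank: Bank,
    limit: int | None = None,
    seed: int = 0,
) -> EnumerationResult:
    """Enumerate virtual products of ``scheme`` over ``bank``.

    Without ``limit`` the full Cartesian product of slot classes is pushed
    through the template; with ``limit`` a uniform seeded sample of distinct
    slot choices (without replacement) is used.  Combinations the template
    rejects are recorded in ``result.skipped``.
    """
    slot_members = [bank.members(cls) for cls in scheme.slots]
    sizes = [len(m) for m in slot_members]
    space = math.prod(sizes) if sizes else 0
    if space == 0:
        return EnumerationResult([], [])

    if limit is None:
        indices: Iterable[int] = range(space)
    else:
        rng = np.random.default_rng(seed)
        indices = sample_combination_indices(space, min(limit, space), rng)

    mol_cache: dict[str, Chem.Mol] = {}

    def _mol(block) -> Chem.Mol:
        if block.id not in mol_cache:
            mol_cache[block.id] = Chem.MolFromSmiles(block.structure)
        return mol_cache[block.id]

    products: list[VirtualProduct] = []
    skipped: list[SkippedCombination] = []
    for idx in indices:
        pos = _decode_index(int(idx), sizes)
        blocks = [slot_members[k][p] for k, p in enumerate(pos)]
        choice = tuple(b.id for b in blocks)
        smi, reason = apply_template(scheme, [_mol(b) for b in blocks])
        if smi is None:
            skipped.append(SkippedCombination(scheme.scheme_id, choice, reason))
        else:
            products.append(VirtualProduct(scheme.scheme_id, choice, smi))
    return EnumerationResult(products, skipped)


def sample_products(
    scheme: ReactionScheme,
    bank: Bank,
    n: int,
    seed: int = 0,
    max_attempts_factor: int = 20,
) -> list[VirtualProduct]:
    """Draw up to ``n`` successful virtual products by seeded sampling.

    Oversamples to absorb template-incompatible combinations; stops early
    once the space is exhausted.
    """
    slot_members = [bank.members(cls) for cls in scheme.slots]
    space = math.prod(len(m) for m in slot_members) if slot_members else 0
    if space == 0:
        return []
    budget = min(space, n * max_attempts_factor)
    result = enumerate_products(scheme, bank, limit=budget, seed=seed)
    return result.products[:n]


def theoretical_space_size(
    schemes: ReactionScheme | Iterable[ReactionScheme], bank: Bank
) -> int:
    """Sum over schemes of the product of slot-class sizes (no enumeration)."""
    if isinstance(schemes, ReactionScheme):
        schemes = [schemes]
    sizes = bank.class_sizes()
    total = 0
    for scheme in schemes:
        total += math.prod(sizes.get(cls, 0) for cls in scheme.slots)
    return total


def sparse_fraction(n_reactions: int, space: int) -> float:
    """Per-mille fraction of the combinatorial space actually synthesised."""
    if space <= 0:
        raise ValueError("combinatorial space must be positive")
    if n_reactions < 0:
        raise ValueError("reaction count must be non-negative")
    return 1000.0 * n_reactions / space
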