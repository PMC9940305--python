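"""Sparse-matrix campaign design for acoustic droplet ejection.

Builds the physical layer of the campaign: a column-major, class-grouped
source-plate layout; per-scheme uniform sampling of building-block
combinations without replacement; destination plates filled in contiguous
per-scheme blocks; nanoliter transfer volumes rounded up to droplet
multiples; and the instrument picklist (CSV with the exact Echo-style
header).  A quadrant-interleave mapping folds four 384-well destination
plates onto one virtual 1536-well plate for heatmap reporting.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .bank import Bank, BuildingBlock
from .reactions import (
    ReactionScheme,
    sample_combination_indices,
    _decode_index,
    theoretical_space_size,
)

DROPLET_NL = 2.5

PICKLIST_HEADER = (
    "Source Plate Name,Source Well,Destination Plate Name,Destination Well,"
    "Transfer Volume"
)

_FORMATS = {384: (16, 24), 1536: (32, 48)}


def row_letter(index: int) -> str:
    """0-based row index -> plate row letter (A..P, then AA..AF for 1536)."""
    if index < 26:
        return chr(ord("A") + index)
    return "A" + chr(ord("A") + index - 26)


def row_index(letter: str) -> int:
    if len(letter) == 1:
        return ord(letter) - ord("A")
    return 26 + ord(letter[1]) - ord("A")


class WellAddress(NamedTuple):
    plate_id: str
    row: str
    col: int

    @property
    def well(self) -> str:
        return f"{self.row}{self.col}"

    @classmethod
    def parse(cls, plate_id: str, well: str) -> "WellAddress":
        i = 0
        while i < len(well) and well[i].isalpha():
            i += 1
        return cls(plate_id, well[:i], int(well[i:]))


class Transfer(NamedTuple):
    source: WellAddress
    destination: WellAddress
    volume_nl: float


@dataclass(frozen=True)
class ReactionWell:
    destination: WellAddress
    scheme_id: int
    slot_choice: tuple[str, ...]
    scale_nmol: int
    post_additions: tuple[str, ...] = ()


@dataclass
class Campaign:
    """The full sparse-matrix design: source map, wells and transfers."""

    source_map: dict[str, WellAddress]
    wells: list[ReactionWell]
    transfers: list[Transfer] = field(default_factory=list)
    droplet_nl: float = DROPLET_NL
    dest_format: int = 384
    seed: int | None = None

    @property
    def destination_plates(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.destination.plate_id, None)
        return list(seen)

    @property
    def source_plates(self) -> list[str]:
        seen: dict[str, None] = {}
        for addr in self.source_map.values():
            seen.setdefault(addr.plate_id, None)
        return list(seen)

    def wells_for_scheme(self, scheme_id: int) -> list[ReactionWell]:
        return [w for w in self.wells if w.scheme_id == scheme_id]

    def validate(self) -> None:
        dests = [w.destination for w in self.wells]
        if len(set(dests)) != len(dests):
            raise ValueError("duplicate destination wells")
        per_scheme: dict[int, set] = {}
        for w in self.wells:
            seen = per_scheme.setdefault(w.scheme_id, set())
            if w.slot_choice in seen:
                raise ValueError(
                    f"scheme {w.scheme_id}: duplicated slot choice {w.slot_choice}"
                )
            seen.add(w.slot_choice)


class InfeasibleDesignError(ValueError):
    """Requested more distinct combinations than the scheme's space holds."""


# ---------------------------------------------------------------------------
# Source plate layout
# ---------------------------------------------------------------------------


def layout_source_plate(
    bank: Bank, plate_name: str = "Source[1]", fmt: int = 384
) -> dict[str, WellAddress]:
    """Column-major (A1, B1, ... P1, A2, ...) layout grouped by class.

    Blocks are placed in bank order, which groups members class by class.
    Banks larger than one plate spill onto additional plates with a warning.
    """
    n_rows, n_cols = _FORMATS[fmt]
    per_plate = n_rows * n_cols
    if len(bank) > per_plate:
        warnings.warn(
            f"bank of {len(bank)} blocks exceeds one {fmt}-well source plate",
            stacklevel=2,
        )
    source_map: dict[str, WellAddress] = {}
    base = plate_name.rstrip("]").rsplit("[", 1)[0]
    for i, block in enumerate(bank.blocks):
        plate_idx, within = divmod(i, per_plate)
        col, row = divmod(within, n_rows)
        pid = plate_name if plate_idx == 0 else f"{base}[{plate_idx + 1}]"
        source_map[block.id] = WellAddress(pid, row_letter(row), col + 1)
    return source_map


# ---------------------------------------------------------------------------
# Combination sampling and transfer arithmetic
# ---------------------------------------------------------------------------


def sample_sparse_matrix(
    scheme: ReactionScheme,
    bank: Bank,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, ...]]:
    """``n`` distinct slot choices drawn uniformly without replacement."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slot_members = [bank.members(cls) for cls in scheme.slots]
    sizes = [len(m) for m in slot_members]
    space = math.prod(sizes) if sizes else 0
    if n > space:
        raise InfeasibleDesignError(
            f"scheme {scheme.scheme_id} ({scheme.name}): requested {n} wells "
            f"but the combinatorial space holds only {space}"
        )
    if n == 0:
        return []
    indices = sample_combination_indices(space, n, rng)
    out = []
    for idx in indices:
        pos = _decode_index(int(idx), sizes)
        out.append(tuple(slot_members[k][p].id for k, p in enumerate(pos)))
    return out


def compute_transfer_volume(
    scale_nmol: float, stock_conc: float, droplet_nl: float = DROPLET_NL
) -> float:
    """Volume in nL delivering ``scale_nmol`` from a ``stock_conc`` M stock.

    nmol / (mol/L) = nL; rounded up to the nearest droplet multiple so the
    well never receives less than the design scale.
    """
    if scale_nmol < 0:
        raise ValueError("scale must be non-negative")
    if stock_conc <= 0 or droplet_nl <= 0:
        raise ValueError("stock concentration and droplet size must be positive")
    if scale_nmol == 0:
        return 0.0
    exact = scale_nmol / stock_conc
    k = math.ceil(exact / droplet_nl - 1e-9)
    return k * droplet_nl


# ---------------------------------------------------------------------------
# Campaign construction
# ---------------------------------------------------------------------------


def build_campaign(
    schemes: Iterable[ReactionScheme],
    bank: Bank,
    n_per_scheme: int = 96,
    seed: int = 0,
    droplet_nl: float = DROPLET_NL,
    dest_format: int = 384,
    dest_prefix: str = "Destination",
) -> Campaign:
    """Assemble the sparse-matrix campaign.

    Wells are assigned scheme-contiguously in scheme-id order (row-major
    within each block), so with 96 wells per scheme four schemes share one
    384-well destination plate.  One transfer is generated per variable slot
    of every well, plus one per fixed liquid reagent present in the bank;
    additions done outside the dispenser are kept as annotations.
    """
    schemes = sorted(schemes, key=lambda s: s.scheme_id)
    source_map = layout_source_plate(bank)
    n_rows, n_cols = _FORMATS[dest_format]
    per_plate = n_rows * n_cols
    rng = np.random.default_rng(seed)

    wells: list[ReactionWell] = []
    transfers: list[Transfer] = []
    g = 0
    for scheme in schemes:
        combos = sample_sparse_matrix(scheme, bank, n_per_scheme, rng)
        for combo in combos:
            plate_idx, within = divmod(g, per_plate)
            row, col = divmod(within, n_cols)
            dest = WellAddress(
                f"{dest_prefix}[{plate_idx + 1}]", row_letter(row), col + 1
            )
            post = list(scheme.post_additions)
            for block_id in combo:
                block = bank.get(block_id)
                vol = compute_transfer_volume(
                    scheme.scale_nmol, block.stock_conc, droplet_nl
                )
                transfers.append(Transfer(source_map[block_id], dest, vol))
            for reagent in scheme.reagents:
                rid, equiv = reagent["id"], float(reagent.get("equiv", 1.0))
                if rid in source_map:
                    block = bank.get(rid)
                    vol = compute_transfer_volume(
                        scheme.scale_nmol * equiv, block.stock_conc, droplet_nl
                    )
                    transfers.append(Transfer(source_map[rid], dest, vol))
                else:
                    post.append(f"manual:{rid}")
            wells.append(
                ReactionWell(
                    destination=dest,
                    scheme_id=scheme.scheme_id,
                    slot_choice=combo,
                    scale_nmol=scheme.scale_nmol,
                    post_additions=tuple(post),
                )
            )
            g += 1
    campaign = Campaign(
        source_map=source_map,
        wells=wells,
        transfers=transfers,
        droplet_nl=droplet_nl,
        dest_format=dest_format,
        seed=seed,
    )
    campaign.validate()
    return campaign


# ---------------------------------------------------------------------------
# Picklist I/O
# ---------------------------------------------------------------------------


def _format_volume(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.1f}"


def export_picklist(campaign_or_transfers: Campaign | Sequence[Transfer]) -> str:
    """Instrument picklist as CSV text (bit-exact header, lossless volumes)."""
    transfers = (
        campaign_or_transfers.transfers
        if isinstance(campaign_or_transfers, Campaign)
        else campaign_or_transfers
    )
    buf = io.StringIO()
    buf.write(PICKLIST_HEADER + "\n")
    for t in transfers:
        buf.write(
            f"{t.source.plate_id},{t.source.well},"
            f"{t.destination.plate_id},{t.destination.well},"
            f"{_format_volume(t.volume_nl)}\n"
        )
    return buf.getvalue()


def write_picklist(campaign: Campaign, path: str | Path) -> None:
    Path(path).write_text(export_picklist(campaign))


def read_picklist(text_or_path: str | Path) -> list[Transfer]:
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str) and "\n" not in text_or_path
    ):
        text = Path(text_or_path).read_text()
    else:
        text = text_or_path
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    if ",".join(header) != PICKLIST_HEADER:
        raise ValueError("unrecognised picklist header")
    transfers = []
    for row in reader:
        if not row:
            continue
        sp, sw, dp, dw, vol = row
        transfers.append(
            Transfer(
                WellAddress.parse(sp, sw), WellAddress.parse(dp, dw), float(vol)
            )
        )
    return transfers


def source_volume_audit(campaign: Campaign) -> dict[str, float]:
    """Total volume (nL) drawn from each source well across the campaign."""
    totals: dict[str, float] = {}
    for t in campaign.transfers:
        key = f"{t.source.plate_id}:{t.source.well}"
        totals[key] = totals.get(key, 0.0) + t.volume_nl
    return totals


# ---------------------------------------------------------------------------
# 4 x 384 -> 1536 quadrant interleave
# ---------------------------------------------------------------------------


class QuadrantMapper:
    """Bijective quadrant-interleave between four 384-well plates and one
    1536-well plate: plate ``k`` lands on row offset ``k // 2`` and column
    offset ``k % 2`` of the interleaved grid (plate 1's A1 stays at A1)."""

    def __init__(self, plate_ids: Sequence[str], dest_plate_id: str = "1536"):
        if len(plate_ids) != 4:
            raise ValueError(f"expected exactly 4 plates, got {len(plate_ids)}")
        self.plate_ids = list(plate_ids)
        self.dest_plate_id = dest_plate_id

    def forward(self, addr: WellAddress) -> WellAddress:
        k = self.plate_ids.index(addr.plate_id)
        r, c = row_index(addr.row), addr.col - 1
        if not (0 <= r < 16 and 0 <= c < 24):
            raise ValueError(f"{addr.well} outside the 384-well format")
        return WellAddress(
            self.dest_plate_id, row_letter(2 * r + k // 2), 2 * c + k % 2 + 1
        )

    def inverse(self, addr: WellAddress) -> WellAddress:
        R, C = row_index(addr.row), addr.col - 1
        if not (0 <= R < 32 and 0 <= C < 48):
            raise ValueError(f"{addr.well} outside the 1536-well format")
        k = 2 * (R % 2) + C % 2
        return WellAddress(self.plate_ids[k], row_letter(R // 2), C // 2 + 1)


def map_to_1536(plate_ids: Sequence[str]) -> QuadrantMapper:
    return QuadrantMapper(plate_ids)


# ---------------------------------------------------------------------------
# Campaign manifest I/O
# ---------------------------------------------------------------------------


def write_campaign_manifest(campaign: Campaign, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["plate", "well", "scheme_id", "scale_nmol", "slot_ids", "post_additions"]
        )
        for w in campaign.wells:
            writer.writerow(
                [
                    w.destination.plate_id,
                    w.destination.well,
                    w.scheme_id,
                    w.scale_nmol,
                    "|".join(w.slot_choice),
                    "|".join(w.post_additions),
                ]
            )


def read_campaign_manifest(path: str | Path) -> Campaign:
    """Rebuild a transfer-less campaign view from a manifest CSV."""
    wells = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            wells.append(
                ReactionWell(
                    destination=WellAddress.parse(row["plate"], row["well"]),
                    scheme_id=int(row["scheme_id"]),
                    slot_choice=tuple(
                        x for x in row["slot_ids"].split("|") if x
                    ),
                    scale_nmol=int(row["scale_nmol"]),
                    post_additions=tuple(
                        x for x in row["post_additions"].split("|") if x
                    ),
                )
            )
    return Campaign(source_map={}, wells=wells, transfers=[])
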