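"""Per-well outcome statistics: scheme ranking, block performance, heatmaps.

Consumes categorical three-level MS calls (``none``/``medium``/``major``)
made upstream; no raw chromatogram is ever interpreted here.  A call table
is validated against its campaign (every called well must exist; missing
wells are reported) and then aggregated three ways: per-scheme success
fractions ranked in descending order, per-building-block stacked call
counts, and the 32 x 48 quadrant-interleaved plate heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bank import Bank
from .plates import Campaign, WellAddress, map_to_1536
from .reactions import ReactionScheme
from .simulate import CALLS

_CALL_CODE = {"none": 0, "medium": 1, "major": 2}


class CallVocabularyError(ValueError):
    """A call outside the three-level vocabulary."""


class UnknownWellError(ValueError):
    """A called well that does not exist in the campaign."""


class IncompleteTableError(ValueError):
    """An aggregation that requires one call per campaign well."""


@dataclass
class OutcomeTable:
    calls: pd.DataFrame  # columns: plate, well, call
    campaign: Campaign
    missing: list[WellAddress] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.missing

    def call_for(self, addr: WellAddress) -> str:
        sel = self.calls[
            (self.calls["plate"] == addr.plate_id) & (self.calls["well"] == addr.well)
        ]
        return sel["call"].iloc[0]


def ingest_calls(
    calls: pd.DataFrame | str | Path, campaign: Campaign
) -> OutcomeTable:
    """Validate a calls table (columns ``plate, well, call``) against a campaign."""
    if not isinstance(calls, pd.DataFrame):
        calls = pd.read_csv(calls)
    calls = calls[["plate", "well", "call"]].copy()

    bad = set(calls["call"]) - set(CALLS)
    if bad:
        raise CallVocabularyError(
            f"calls outside the vocabulary {CALLS}: {sorted(bad)}"
        )
    campaign_wells = {
        (w.destination.plate_id, w.destination.well) for w in campaign.wells
    }
    called = list(zip(calls["plate"], calls["well"]))
    unknown = set(called) - campaign_wells
    if unknown:
        raise UnknownWellError(f"calls for wells not in the campaign: {sorted(unknown)[:5]}")
    if len(set(called)) != len(called):
        raise UnknownWellError("duplicate calls for the same well")
    missing = [
        w.destination
        for w in campaign.wells
        if (w.destination.plate_id, w.destination.well) not in set(called)
    ]
    return OutcomeTable(calls=calls.reset_index(drop=True), campaign=campaign, missing=missing)


def _well_frame(table: OutcomeTable) -> pd.DataFrame:
    """Join campaign wells with their calls (requires a complete table)."""
    if not table.complete:
        raise IncompleteTableError(
            f"{len(table.missing)} campaign wells lack a call "
            f"(first: {table.missing[0].plate_id} {table.missing[0].well})"
        )
    rows = [
        {
            "plate": w.destination.plate_id,
            "well": w.destination.well,
            "scheme_id": w.scheme_id,
            "slot_choice": w.slot_choice,
        }
        for w in table.campaign.wells
    ]
    frame = pd.DataFrame(rows)
    return frame.merge(table.calls, on=["plate", "well"], validate="one_to_one")


def scheme_success_rates(table: OutcomeTable) -> pd.DataFrame:
    """Per-scheme call fractions, descending by success (major + medium).

    Ties are broken by ascending scheme id.  Columns: ``scheme_id, n_wells,
    frac_major, frac_medium, frac_none, frac_success`` plus integer-percent
    convenience columns (``pct_*``) rounded the way campaign reports quote
    them.
    """
    frame = _well_frame(table)
    out = []
    for sid, grp in frame.groupby("scheme_id"):
        n = len(grp)
        counts = grp["call"].value_counts()
        fm = counts.get("major", 0) / n
        fmed = counts.get("medium", 0) / n
        fn = counts.get("none", 0) / n
        out.append(
            {
                "scheme_id": sid,
                "n_wells": n,
                "frac_major": fm,
                "frac_medium": fmed,
                "frac_none": fn,
                "frac_success": fm + fmed,
            }
        )
    df = pd.DataFrame(out).sort_values(
        ["frac_success", "scheme_id"], ascending=[False, True]
    )
    for col in ("major", "medium", "none", "success"):
        df[f"pct_{col}"] = (df[f"frac_{col}"] * 100).round().astype(int)
    return df.reset_index(drop=True)


def block_performance(
    table: OutcomeTable,
    bb_class: str,
    bank: Bank,
    scheme_id: int | None = None,
    schemes: dict[int, ReactionScheme] | None = None,
) -> pd.DataFrame:
    """Stacked per-building-block call counts, descending by success count.

    Counts every occurrence of a class member across the (optionally
    scheme-restricted) wells; blocks never used are absent.  ``schemes`` is
    needed only to resolve which slot positions hold ``bb_class`` when a
    campaign well could contain ids of several classes.
    """
    if bb_class not in bank.class_index:
        raise KeyError(f"class {bb_class!r} not present in the bank")
    members = set(bank.class_index[bb_class])
    frame = _well_frame(table)
    if scheme_id is not None:
        frame = frame[frame["scheme_id"] == scheme_id]
    counts: dict[str, dict[str, int]] = {}
    for _, row in frame.iterrows():
        for bid in row["slot_choice"]:
            if bid in members:
                c = counts.setdefault(bid, {"major": 0, "medium": 0, "none": 0})
                c[row["call"]] += 1
    out = [
        {
            "block_id": bid,
            "bb_class": bb_class,
            "n_major": c["major"],
            "n_medium": c["medium"],
            "n_none": c["none"],
            "n_used": sum(c.values()),
            "n_success": c["major"] + c["medium"],
        }
        for bid, c in counts.items()
    ]
    df = pd.DataFrame(out).sort_values(
        ["n_success", "n_major", "block_id"], ascending=[False, False, True]
    )
    return df.reset_index(drop=True)


def heatmap_matrix(table: OutcomeTable) -> np.ndarray:
    """32 x 48 call-coded grid (0 none, 1 medium, 2 major, NaN empty).

    Folds the four 384-well destination plates onto the virtual 1536-well
    plate by quadrant interleave.
    """
    plates = table.campaign.destination_plates
    if len(plates) != 4:
        raise ValueError(f"expected a 4-plate campaign, got {len(plates)} plates")
    mapper = map_to_1536(plates)
    grid = np.full((32, 48), np.nan)
    frame = _well_frame(table)
    from .plates import row_index  # local import to avoid cycle noise

    for _, row in frame.iterrows():
        addr = WellAddress.parse(row["plate"], row["well"])
        target = mapper.forward(addr)
        grid[row_index(target.row), target.col - 1] = _CALL_CODE[row["call"]]
    return grid
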