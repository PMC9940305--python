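"""Synthetic per-well outcome generation.

Mass-spectrometry analysis of a campaign assigns each reaction well one of
three calls: ``none`` (no product ion), ``medium`` or ``major`` product
formation.  This module draws such calls from per-scheme Bernoulli
probabilities so the outcome-statistics stage can be exercised and
calibrated without instrument data.

``DEFAULT_SCHEME_PROFILE`` encodes the campaign-level picture the generator
emulates: twelve of the sixteen chemistries succeeding in more than half of
their wells, four clearly under-performing ones (the dipeptide
diketopiperazine, the Orru 3-component reaction, the tetrazolo-lactam and
the tetrazolo-ketopiperazine), and the Groebke-Blackburn-Bienayme reaction
at 18% major / 39% medium product formation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .plates import Campaign

CALLS = ("none", "medium", "major")

#: scheme_id -> (p_major, p_medium)
DEFAULT_SCHEME_PROFILE: dict[int, tuple[float, float]] = {
    1: (0.18, 0.39),
    2: (0.30, 0.35),
    3: (0.40, 0.35),
    4: (0.30, 0.30),
    5: (0.02, 0.18),
    6: (0.25, 0.30),
    7: (0.20, 0.35),
    8: (0.25, 0.40),
    9: (0.35, 0.35),
    10: (0.30, 0.30),
    11: (0.03, 0.22),
    12: (0.00, 0.08),
    13: (0.15, 0.40),
    14: (0.25, 0.35),
    15: (0.20, 0.35),
    16: (0.05, 0.20),
}


def generate_outcomes(
    campaign: Campaign,
    class_profile: dict[int, tuple[float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one three-level call per campaign well.

    ``class_profile`` maps scheme id to ``(p_major, p_medium)``; wells of a
    scheme are independent draws.  Deterministic for a fixed seed.
    Returns a DataFrame with columns ``plate, well, call``.
    """
    profile = DEFAULT_SCHEME_PROFILE if class_profile is None else class_profile
    for sid, (p_major, p_medium) in profile.items():
        if not (0 <= p_major <= 1 and 0 <= p_medium <= 1):
            raise ValueError(f"scheme {sid}: probabilities must lie in [0, 1]")
        if p_major + p_medium > 1 + 1e-12:
            raise ValueError(f"scheme {sid}: p_major + p_medium exceeds 1")
    rng = np.random.default_rng(seed)
    rows = []
    for w in campaign.wells:
        if w.scheme_id not in profile:
            raise KeyError(f"no outcome profile for scheme {w.scheme_id}")
        p_major, p_medium = profile[w.scheme_id]
        u = rng.random()
        if u < p_major:
            call = "major"
        elif u < p_major + p_medium:
            call = "medium"
        else:
            call = "none"
        rows.append((w.destination.plate_id, w.destination.well, call))
    return pd.DataFrame(rows, columns=["plate", "well", "call"])
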