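"""Classify each lake OTU by source, abundance tier, shift, and activity.

Source is the most upstream habitat where the OTU is detected in DNA.
Tier thresholds are strict on the dominant side (>1%) with ties assigned
downward (rare iff <= 0.1%).  A shift is a more-than-ten-fold change of
lake relative abundance against the source habitat.  Activity is read off
the ratio sequence from the source habitat down to the lake: all positive
= active, all zero = inactive, a mix = seed; habitats where neither
molecule was detected are skipped (flagged as a continuum gap) since
their zero is a sentinel for absence, not evidence of inactivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import HABITAT_ORDER, CountTable

CLASSIFICATION_COLUMNS = (
    "otu_id",
    "campaign",
    "source",
    "tier",
    "source_tier",
    "shift",
    "activity",
    "lake_rel_abund",
    "lake_ratio",
    "continuum_gap",
)


@dataclass
class TierConfig:
    dominant_threshold: float = 0.01
    rare_threshold: float = 0.001
    shift_fold: float = 10.0
    activity_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.rare_threshold < self.dominant_threshold < 1:
            raise ValueError("need 0 < rare_threshold < dominant_threshold < 1")
        if self.shift_fold <= 1:
            raise ValueError("shift_fold must exceed 1")
        if self.activity_threshold < 0:
            raise ValueError("activity_threshold must be >= 0")


def attribute_source(
    detected: Mapping[str, bool], habitats: Sequence[str] = HABITAT_ORDER
) -> str:
    """Most upstream habitat with DNA detection; requires lake detection."""
    if not detected.get(habitats[-1], False):
        raise ValueError("OTU not detected in the lake DNA: not part of the lake community")
    for habitat in habitats:
        if detected.get(habitat, False):
            return habitat
    raise AssertionError("unreachable: lake detection implies some detection")


def classify_tier(rel_abund: float, cfg: TierConfig | None = None) -> str:
    cfg = cfg or TierConfig()
    if not 0 <= rel_abund <= 1:
        raise ValueError(f"relative abundance out of [0, 1]: {rel_abund}")
    if rel_abund > cfg.dominant_threshold:
        return "dominant"
    if rel_abund <= cfg.rare_threshold:
        return "rare"
    return "subdominant"


def classify_shift(source_abund: float, lake_abund: float, cfg: TierConfig | None = None) -> str:
    cfg = cfg or TierConfig()
    if source_abund <= 0 or lake_abund <= 0:
        raise ValueError("shift classification needs positive abundances on both ends")
    fold = lake_abund / source_abund
    if fold > cfg.shift_fold or fold < 1 / cfg.shift_fold:
        return "shifting"
    return "stable"


def classify_activity(ratios: Sequence[float], cfg: TierConfig | None = None) -> str:
    """Activity state from the ordered ratio sequence source -> lake."""
    cfg = cfg or TierConfig()
    if len(ratios) == 0:
        raise ValueError("empty ratio sequence")
    positive = [r > cfg.activity_threshold for r in ratios]
    if all(positive):
        return "active"
    if not any(positive):
        return "inactive"
    return "seed"


def classify_campaign(
    profiles: pd.DataFrame,
    campaign: str,
    cfg: TierConfig | None = None,
    habitats: Sequence[str] = HABITAT_ORDER,
) -> pd.DataFrame:
    """One classification record per lake-detected OTU of one campaign.

    ``profiles`` must carry rows for every habitat of the campaign (as
    produced by :func:`assemblytrace.ratio_activity.campaign_profiles`).
    """
    cfg = cfg or TierConfig()
    rows = profiles[profiles["campaign"] == campaign]
    present = set(rows["habitat"])
    missing = [h for h in habitats if h not in present]
    if missing:
        raise ValueError(f"campaign {campaign!r} lacks profiles for habitats {missing}")

    def pivot(col):
        return rows.pivot(index="otu_id", columns="habitat", values=col).reindex(
            columns=list(habitats)
        )

    abund = pivot("mean_rel_abund").fillna(0.0)
    ratio = pivot("mean_ratio").fillna(0.0)
    det_dna = pivot("detected_dna").fillna(False).astype(bool)
    det_rna = pivot("detected_rna").fillna(False).astype(bool)

    lake = habitats[-1]
    otus = abund.index[det_dna[lake]]
    a = abund.loc[otus].to_numpy()
    r = ratio.loc[otus].to_numpy()
    dd = det_dna.loc[otus].to_numpy()
    dr = det_rna.loc[otus].to_numpy()
    n_hab = len(habitats)

    source_pos = dd.argmax(axis=1)  # first True along the ordered continuum
    informative = dd | dr
    downstream = np.arange(n_hab)[None, :] >= source_pos[:, None]
    consider = informative & downstream
    pos = r > cfg.activity_threshold
    active = ((pos | ~consider).all(axis=1))
    inactive = ((~pos | ~consider).all(axis=1))
    gap = (downstream & ~informative).any(axis=1)

    records = []
    for i, otu in enumerate(otus):
        src = habitats[source_pos[i]]
        lake_ab = float(a[i, -1])
        src_ab = float(a[i, source_pos[i]])
        if src == lake:
            shift = "stable"
        else:
            shift = classify_shift(src_ab, lake_ab, cfg)
        if active[i]:
            activity = "active"
        elif inactive[i]:
            activity = "inactive"
        else:
            activity = "seed"
        records.append(
            {
                "otu_id": str(otu),
                "campaign": campaign,
                "source": src,
                "tier": classify_tier(lake_ab, cfg),
                "source_tier": classify_tier(src_ab, cfg),
                "shift": shift,
                "activity": activity,
                "lake_rel_abund": lake_ab,
                "lake_ratio": float(r[i, -1]),
                "continuum_gap": bool(gap[i]),
            }
        )
    frame = pd.DataFrame.from_records(records, columns=list(CLASSIFICATION_COLUMNS))
    return frame.sort_values("otu_id", kind="stable").reset_index(drop=True)


def retrace_in_reference(otu_set: set[str], reference: CountTable) -> float:
    """Fraction of an OTU set present (count > 0) in a deep reference sample."""
    if not otu_set:
        raise ValueError("empty OTU set")
    totals = reference.data.sum(axis=1)
    present = sum(1 for otu in otu_set if otu in totals.index and totals[otu] > 0)
    return present / len(otu_set)
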