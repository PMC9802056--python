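"""Per-OTU RNA:DNA ratios, phantom exclusion, and per-habitat profiles.

The ratio of an aligned sample pair is cDNA reads / DNA reads.  When the
OTU has no DNA reads the ratio carries no real value and a sentinel is
substituted: 100 when RNA was detected anyway, 0 when both molecules are
absent.  Sentinels enter habitat averages (flagged) but are excluded from
trend statistics, where they would fabricate a gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import PairedTables

PROFILE_COLUMNS = (
    "otu_id",
    "campaign",
    "habitat",
    "mean_rel_abund",
    "mean_ratio",
    "detected_dna",
    "detected_rna",
    "ratio_has_sentinel",
)


@dataclass
class RatioConfig:
    sentinel_rna_only: float = 100.0
    sentinel_absent: float = 0.0
    exclude_sentinels_from_trend: bool = True


def sample_ratio(dna_count: float, rna_count: float, cfg: RatioConfig | None = None) -> float:
    """RNA:DNA ratio for one aligned sample pair, sentinel rules applied."""
    cfg = cfg or RatioConfig()
    if dna_count < 0 or rna_count < 0:
        raise ValueError("counts must be non-negative")
    if dna_count > 0:
        return rna_count / dna_count
    if rna_count > 0:
        return cfg.sentinel_rna_only
    return cfg.sentinel_absent


def exclude_phantoms(paired: PairedTables) -> tuple[PairedTables, list[str]]:
    """Drop OTUs never seen in DNA across one campaign's samples.

    Phantom taxa (RNA somewhere, DNA nowhere) are returned for the report;
    OTUs absent from both tables everywhere are dropped silently.
    """
    dna_any = paired.dna.sum(axis=1) > 0
    rna_any = paired.rna.sum(axis=1) > 0
    phantoms = sorted(paired.dna.index[~dna_any & rna_any].astype(str))
    keep = paired.dna.index[dna_any]
    cleaned = PairedTables(
        paired.dna.loc[keep], paired.rna.loc[keep], paired.pairs, habitats=paired.habitats
    )
    return cleaned, phantoms


def _ratio_matrix(dna: pd.DataFrame, rna: pd.DataFrame, cfg: RatioConfig) -> np.ndarray:
    d = dna.to_numpy(dtype=float)
    r = rna.to_numpy(dtype=float)
    out = np.full(d.shape, cfg.sentinel_absent, dtype=float)
    has_dna = d > 0
    np.divide(r, d, out=out, where=has_dna)
    out[(~has_dna) & (r > 0)] = cfg.sentinel_rna_only
    return out


def habitat_profile(
    paired: PairedTables, campaign: str, habitat: str, cfg: RatioConfig | None = None
) -> pd.DataFrame:
    """One profile row per OTU for a (campaign, habitat) cell.

    Relative abundance is computed per sample, then averaged across sites;
    ratios are averaged the same way with sentinels included and flagged.
    """
    cfg = cfg or RatioConfig()
    sub = paired.subset_campaign(campaign)
    cols = sub.pairs_for(habitat)
    if not cols:
        raise ValueError(f"no sample pairs for habitat {habitat!r} in campaign {campaign!r}")
    dna = sub.dna[cols]
    rna = sub.rna[cols]
    sums = dna.sum(axis=0).to_numpy(dtype=float)
    if (sums <= 0).any():
        bad = [c for c, s in zip(cols, sums) if s <= 0]
        raise ValueError(f"DNA sample(s) with zero total reads: {bad}")
    rel = dna.to_numpy(dtype=float) / sums
    ratios = _ratio_matrix(dna, rna, cfg)
    mean_rel = rel.mean(axis=1)
    frame = pd.DataFrame(
        {
            "otu_id": dna.index.astype(str),
            "campaign": campaign,
            "habitat": habitat,
            "mean_rel_abund": mean_rel,
            "mean_ratio": ratios.mean(axis=1),
            "detected_dna": mean_rel > 0,
            "detected_rna": rna.to_numpy(dtype=float).sum(axis=1) > 0,
            "ratio_has_sentinel": (dna.to_numpy(dtype=float) == 0).any(axis=1),
        }
    )
    return frame.reset_index(drop=True)


def campaign_profiles(
    paired: PairedTables, campaign: str, cfg: RatioConfig | None = None
) -> pd.DataFrame:
    """Habitat profiles for every habitat of one campaign, concatenated."""
    sub = paired.subset_campaign(campaign)
    present = [h for h in paired.habitats if sub.pairs_for(h)]
    parts = [habitat_profile(paired, campaign, h, cfg) for h in present]
    return pd.concat(parts, ignore_index=True)


def trend_statistics(
    profiles: pd.DataFrame, n_bins: int = 13, cfg: RatioConfig | None = None
) -> pd.DataFrame:
    """Equal-count abundance bins with mean and SE of the ratio per bin.

    Sentinel-bearing ratios are removed first (configurable): they stand
    for the absence of a value, not a value.
    """
    cfg = cfg or RatioConfig()
    rows = profiles[profiles["detected_dna"]]
    if cfg.exclude_sentinels_from_trend:
        rows = rows[~rows["ratio_has_sentinel"]]
    if len(rows) < n_bins:
        raise ValueError(f"only {len(rows)} usable OTUs for {n_bins} bins")
    rows = rows.sort_values(["mean_rel_abund", "otu_id"], kind="stable").reset_index(drop=True)
    chunks = np.array_split(np.arange(len(rows)), n_bins)
    records = []
    for i, idx in enumerate(chunks):
        part = rows.iloc[idx]
        ratios = part["mean_ratio"].to_numpy()
        se = float(ratios.std(ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
        records.append(
            {
                "bin": i,
                "n": len(part),
                "mean_rel_abund": float(part["mean_rel_abund"].mean()),
                "mean_ratio": float(ratios.mean()),
                "se_ratio": se,
            }
        )
    return pd.DataFrame.from_records(records)
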