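"""End-to-end orchestration: rarefy, pair, profile, classify, summarize."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregate_report, continuum_classify, ratio_activity
from .continuum_classify import TierConfig
from .rarefaction import RarefactionConfig, drop_shallow_samples, rarefy_mean, resolve_depth
from .ratio_activity import RatioConfig
from .tables_io import CountTable, SampleSheet, align_pairs

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    profiles: dict[str, pd.DataFrame]
    classifications: dict[str, pd.DataFrame]
    phantoms: dict[str, list[str]]
    summary: dict
    tier_contribution: dict
    depth: int | None = None
    trend: pd.DataFrame | None = None

    def all_profiles(self) -> pd.DataFrame:
        return pd.concat(self.profiles.values(), ignore_index=True)

    def all_classifications(self) -> pd.DataFrame:
        return pd.concat(self.classifications.values(), ignore_index=True)


def run_pipeline(
    dna: CountTable,
    rna: CountTable,
    sheet: SampleSheet,
    rarefaction: RarefactionConfig | None = None,
    ratio: RatioConfig | None = None,
    tiers: TierConfig | None = None,
    rarefy: bool = True,
    trend_bins: int = 13,
) -> PipelineResult:
    """Run the full analysis.  Set ``rarefy=False`` for pre-normalized
    (e.g. expected-value) tables that should go straight to profiling."""
    rarefaction = rarefaction or RarefactionConfig()
    ratio = ratio or RatioConfig()
    tiers = tiers or TierConfig()

    depth = None
    if rarefy:
        dna.validate_raw()
        rna.validate_raw()
        depth = resolve_depth(dna, rarefaction.depth)
        logger.info("rarefying at depth %d, %d repetitions, seed %d",
                    depth, rarefaction.repetitions, rarefaction.seed)
        dna, shallow_dna = drop_shallow_samples(dna, depth)
        rna, shallow_rna = drop_shallow_samples(rna, depth)
        if shallow_dna or shallow_rna:
            warnings.warn(
                f"dropping samples shallower than depth {depth}: {shallow_dna + shallow_rna}",
                stacklevel=2,
            )
        cfg = RarefactionConfig(depth=depth, repetitions=rarefaction.repetitions,
                                seed=rarefaction.seed)
        dna = rarefy_mean(dna, cfg)
        rna = rarefy_mean(rna, cfg)

    paired = align_pairs(dna, rna, sheet)
    profiles: dict[str, pd.DataFrame] = {}
    lake_profiles: dict[str, pd.DataFrame] = {}
    classifications: dict[str, pd.DataFrame] = {}
    phantoms: dict[str, list[str]] = {}
    lake = sheet.habitats[-1]
    for campaign in paired.campaigns:
        sub = paired.subset_campaign(campaign)
        clean, excluded = ratio_activity.exclude_phantoms(sub)
        phantoms[campaign] = excluded
        prof = ratio_activity.campaign_profiles(clean, campaign, ratio)
        profiles[campaign] = prof
        lake_profiles[campaign] = prof[prof["habitat"] == lake].reset_index(drop=True)
        classifications[campaign] = continuum_classify.classify_campaign(
            prof, campaign, tiers, habitats=sheet.habitats
        )

    summary = aggregate_report.summarize(classifications)
    summary["phantom_counts"] = {c: len(v) for c, v in phantoms.items()}
    contribution = aggregate_report.tier_read_contribution(lake_profiles, classifications)

    trend = None
    lake_all = pd.concat(lake_profiles.values(), ignore_index=True)
    try:
        trend = ratio_activity.trend_statistics(lake_all, n_bins=trend_bins, cfg=ratio)
    except ValueError as exc:
        logger.warning("trend statistics skipped: %s", exc)

    return PipelineResult(
        profiles=profiles,
        classifications=classifications,
        phantoms=phantoms,
        summary=summary,
        tier_contribution=contribution,
        depth=depth,
        trend=trend,
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.all_profiles().to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    result.all_classifications().to_csv(outdir / "classifications.tsv", sep="\t", index=False)
    if result.trend is not None:
        result.trend.to_csv(outdir / "trend.tsv", sep="\t", index=False)
    payload = {
        "depth": result.depth,
        "summary": result.summary,
        "tier_contribution": result.tier_contribution,
        "phantoms": result.phantoms,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path) -> dict:
    """Load a YAML config with optional rarefaction/ratio/tiers sections."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "rarefaction" in raw:
        out["rarefaction"] = RarefactionConfig(**raw["rarefaction"])
    if "ratio" in raw:
        out["ratio"] = RatioConfig(**raw["ratio"])
    if "tiers" in raw:
        out["tiers"] = TierConfig(**raw["tiers"])
    if "trend_bins" in raw:
        out["trend_bins"] = int(raw["trend_bins"])
    return out
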