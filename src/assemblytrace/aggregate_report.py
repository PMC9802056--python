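"""Cross-campaign aggregation: category compositions, read contributions,
copy-number contrasts, alpha diversity, and the absolute-abundance check.

Campaigns are weighted equally; the cross-campaign SD is the sample
(n-1) standard deviation.  Proportions are reported as fractions that
sum to one per campaign; a display block pools categories below a
threshold into "other" without touching the full data.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .continuum_classify import TierConfig
from .tables_io import CountTable, PairedTables

logger = logging.getLogger(__name__)

TIERS = ("dominant", "subdominant", "rare")
DISPLAY_THRESHOLD = 0.001  # categories under 0.1% of lake OTUs pooled for display


def composite_category(row: Mapping[str, str]) -> str:
    return "|".join((row["source"], row["shift"], row["tier"], row["activity"]))


def _family_proportions(frame: pd.DataFrame, column: str) -> pd.Series:
    return frame[column].value_counts(sort=False) / len(frame)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def _stack(per_campaign: dict[str, pd.Series], campaigns: list[str]) -> dict:
    names = sorted({name for series in per_campaign.values() for name in series.index})
    out = {}
    for name in names:
        vals = [float(per_campaign[c].get(name, 0.0)) for c in campaigns]
        mean, sd = _mean_sd(vals)
        out[name] = {"per_campaign": vals, "mean": mean, "sd": sd}
    return out


def summarize(
    classifications: Mapping[str, pd.DataFrame],
    display_threshold: float = DISPLAY_THRESHOLD,
) -> dict:
    """Aggregate per-campaign classifications into the assembly summary.

    Returns a JSON-ready dict with composite-category proportions, the
    marginal families (source, tier, shift, activity), per-source OTU
    counts, and a display block with sub-threshold categories pooled.
    """
    if not classifications:
        raise ValueError("no classified campaigns to summarize")
    campaigns = list(classifications)
    composite: dict[str, pd.Series] = {}
    families: dict[str, dict[str, pd.Series]] = {
        f: {} for f in ("source", "tier", "shift", "activity")
    }
    source_counts: dict[str, pd.Series] = {}
    for campaign, frame in classifications.items():
        if len(frame) == 0:
            raise ValueError(f"campaign {campaign!r} has no classified OTUs")
        labels = frame.apply(composite_category, axis=1)
        composite[campaign] = labels.value_counts(sort=False) / len(frame)
        for fam in families:
            families[fam][campaign] = _family_proportions(frame, fam)
        source_counts[campaign] = frame["source"].value_counts(sort=False).astype(float)

    categories = _stack(composite, campaigns)
    display: dict[str, dict] = {}
    other = np.zeros(len(campaigns))
    for name, entry in categories.items():
        if entry["mean"] > display_threshold:
            display[name] = entry
        else:
            other += np.asarray(entry["per_campaign"])
    if other.any():
        mean, sd = _mean_sd(list(other))
        display["other"] = {"per_campaign": [float(v) for v in other], "mean": mean, "sd": sd}

    return {
        "campaigns": campaigns,
        "n_lake_otus": {c: int(len(classifications[c])) for c in campaigns},
        "categories": categories,
        "families": {fam: _stack(series, campaigns) for fam, series in families.items()},
        "source_otu_counts": _stack(source_counts, campaigns),
        "display": display,
    }


def tier_read_contribution(
    lake_profiles: Mapping[str, pd.DataFrame],
    classifications: Mapping[str, pd.DataFrame],
) -> dict:
    """Fraction of lake community reads carried by each abundance tier."""
    campaigns = list(classifications)
    per_campaign: dict[str, pd.Series] = {}
    for campaign in campaigns:
        cls = classifications[campaign].set_index("otu_id")
        prof = lake_profiles[campaign].set_index("otu_id")
        joined = cls.join(prof["mean_rel_abund"], how="left")
        mass = joined.groupby("tier", sort=False)["mean_rel_abund"].sum()
        per_campaign[campaign] = (mass / mass.sum()).reindex(list(TIERS), fill_value=0.0)
    return _stack(per_campaign, campaigns)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0, "degenerate"
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue), method


def copy_number_by_tier(
    classifications: pd.DataFrame, copies: pd.Series, alpha: float = 0.05
) -> dict:
    """Rank tests of 16S copy number across tiers and shift classes.

    Kruskal-Wallis omnibus across the three tiers, pairwise two-sided
    Wilcoxon rank-sum tests Bonferroni-adjusted, and the same two-group
    contrast for shifting vs stable.  OTUs lacking an estimate are
    excluded; the coverage fraction is reported.
    """
    frame = classifications.copy()
    frame["copies"] = frame["otu_id"].map(copies)
    covered = frame.dropna(subset=["copies"])
    coverage = len(covered) / len(frame) if len(frame) else 0.0
    groups = {
        tier: covered.loc[covered["tier"] == tier, "copies"].to_numpy() for tier in TIERS
    }
    usable = {t: g for t, g in groups.items() if len(g) >= 2}
    skipped = sorted(set(groups) - set(usable))
    if skipped:
        warnings.warn(f"tiers with <2 copy-number estimates skipped: {skipped}", stacklevel=2)
    result: dict = {
        "coverage": coverage,
        "tier_means": {t: (float(g.mean()) if len(g) else None) for t, g in groups.items()},
        "tier_n": {t: int(len(g)) for t, g in groups.items()},
        "omnibus_p": None,
        "pairwise": {},
        "shift_contrast": None,
    }
    if len(usable) >= 2:
        pooled = np.concatenate(list(usable.values()))
        if np.all(pooled == pooled[0]):
            result["omnibus_p"] = 1.0  # identical distributions, no evidence
        else:
            _, p = stats.kruskal(*usable.values())
            result["omnibus_p"] = float(p)
        n_comp = len(list(combinations(usable, 2)))
        for a, b in combinations(usable, 2):
            p_raw, method = _rank_sum_p(usable[a], usable[b])
            logger.info("pairwise %s vs %s: %s rank-sum p=%.4g", a, b, method, p_raw)
            result["pairwise"][f"{a}_vs_{b}"] = {
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, p_raw * n_comp),
                "method": method,
            }
    shifting = covered.loc[covered["shift"] == "shifting", "copies"].to_numpy()
    stable = covered.loc[covered["shift"] == "stable", "copies"].to_numpy()
    if len(shifting) >= 2 and len(stable) >= 2:
        p_raw, method = _rank_sum_p(shifting, stable)
        result["shift_contrast"] = {
            "shifting_mean": float(shifting.mean()),
            "stable_mean": float(stable.mean()),
            "p": p_raw,
            "method": method,
        }
    else:
        warnings.warn("shifting/stable contrast skipped: fewer than 2 estimates in a group",
                      stacklevel=2)
    return result


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample richness, Shannon (natural log), and Gini-Simpson."""
    records = []
    for sample in table.sample_ids:
        counts = table.data[sample].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has no reads")
        p = counts[counts > 0] / total
        records.append(
            {
                "sample_id": sample,
                "richness": int((counts > 0).sum()),
                "shannon": float(-(p * np.log(p)).sum()),
                "gini_simpson": float(1.0 - (p**2).sum()),
            }
        )
    return pd.DataFrame.from_records(records)


def absolute_abundance_check(
    paired: PairedTables,
    campaign: str,
    cells: pd.Series,
    classifications: pd.DataFrame,
    cfg: TierConfig | None = None,
) -> dict:
    """Re-run the shift call on cell-count-scaled (absolute) abundances.

    Per sample, absolute abundance = total cells x DNA read fraction;
    habitat means are then compared source vs lake with the same fold
    rule.  With habitat-equal cell counts the factor cancels and the
    classification matches the relative-abundance one exactly.
    """
    cfg = cfg or TierConfig()
    sub = paired.subset_campaign(campaign)
    habitats = sub.habitats
    missing = [
        s for s in sub.pairs["dna_sample"] if s not in cells.index or not np.isfinite(cells[s])
    ]
    if missing:
        raise ValueError(f"missing cell counts for samples: {missing}")
    abs_mean = {}
    for habitat in habitats:
        pair_ids = sub.pairs_for(habitat)
        if not pair_ids:
            raise ValueError(f"no samples for habitat {habitat!r} in campaign {campaign!r}")
        dna = sub.dna[pair_ids]
        scale = np.array([cells[sub.pairs.loc[p, "dna_sample"]] for p in pair_ids])
        rel = dna.to_numpy(dtype=float) / dna.sum(axis=0).to_numpy(dtype=float)
        abs_mean[habitat] = pd.Series((rel * scale).mean(axis=1), index=dna.index)
    cls = classifications.set_index("otu_id")
    records = []
    for otu, row in cls.iterrows():
        if row["source"] == habitats[-1]:
            shift_abs = "stable"
        else:
            src = float(abs_mean[row["source"]].get(otu, 0.0))
            lake = float(abs_mean[habitats[-1]].get(otu, 0.0))
            if src <= 0 or lake <= 0:
                shift_abs = row["shift"]  # detection unchanged by a positive scale factor
            else:
                fold = lake / src
                shift_abs = (
                    "shifting" if fold > cfg.shift_fold or fold < 1 / cfg.shift_fold else "stable"
                )
        records.append({"otu_id": otu, "shift_relative": row["shift"], "shift_absolute": shift_abs})
    per_otu = pd.DataFrame.from_records(records)
    return {
        "campaign": campaign,
        "relative_shifting": float((per_otu["shift_relative"] == "shifting").mean()),
        "absolute_shifting": float((per_otu["shift_absolute"] == "shifting").mean()),
        "per_otu": per_otu,
    }
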