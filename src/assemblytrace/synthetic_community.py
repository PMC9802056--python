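"""Synthetic paired DNA/RNA communities with planted, recoverable truth.

The generator builds true per-habitat composition vectors for an ordered
habitat continuum, realizes DNA reads multinomially per sample, and draws
RNA reads from the DNA composition weighted by a planted per-OTU expected
ratio.  Truth labels (source, tier, shift, activity) are derived from the
final true compositions with a straight transcription of the
classification rules, so they are consistent with the generating
parameters by construction.

Design notes:
- lake composition is built to sum to exactly one, so lake tier truth is
  never distorted by renormalization;
- upstream habitats absorb residual mass in habitat-private filler OTUs
  (never reaching the lake, hence never classified) or, when
  oversubscribed, are renormalized before truth labels are derived;
- planted folds (default 25x for shifting, <=4x for stable) keep a wide
  margin around the ten-fold rule so finite-depth noise rarely flips a
  label, while abundances near the detection limit remain a deliberate
  feature of the rare tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import DNA, RNA, HABITAT_ORDER, CountTable, SampleSheet

DEFAULT_DEPTH_RANGES = {
    "river": (75_953, 97_761),
    "vegetated": (10_114, 109_706),
    "lake": (52_918, 98_630),
}

DEFAULT_CAMPAIGNS = ("midJuly", "lateJuly", "September", "October")

TRUTH_LABEL_COLUMNS = ("source", "tier", "source_tier", "shift", "activity")


class ScenarioError(ValueError):
    """The requested planted fractions cannot be realized."""


@dataclass
class ScenarioConfig:
    n_otus: int = 2000
    source_fractions: dict = field(
        default_factory=lambda: {"river": 0.35, "vegetated": 0.33, "lake": 0.32}
    )
    tier_fractions: dict = field(
        default_factory=lambda: {"dominant": 0.005, "subdominant": 0.04, "rare": 0.955}
    )
    activity_fractions: dict = field(
        default_factory=lambda: {"active": 0.56, "inactive": 0.28, "seed": 0.16}
    )
    shifting_fraction: float = 0.06
    planted_shift_fold: float = 25.0
    stable_fold_ranges: dict = field(
        default_factory=lambda: {
            "dominant": (1.0, 1.4),
            "subdominant": (1.0, 2.0),
            "rare": (1.5, 4.0),
        }
    )
    rare_mean_target: float = 3.2e-4
    subdominant_bounds: tuple = (0.0021, 0.0049)
    dominant_min: float = 0.021
    ratio_mu: dict = field(
        default_factory=lambda: {"dominant": 0.3, "subdominant": 0.5, "rare": 1.0}
    )
    ratio_sigma: float = 0.4
    ratio_min: float = 0.2
    depth_ranges: dict = field(default_factory=lambda: dict(DEFAULT_DEPTH_RANGES))
    sites: dict = field(default_factory=lambda: {"river": 1, "vegetated": 5, "lake": 5})
    campaigns: tuple = DEFAULT_CAMPAIGNS
    n_phantoms: int = 20
    dominant_threshold: float = 0.01
    rare_threshold: float = 0.001
    shift_fold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, fracs in (
            ("source_fractions", self.source_fractions),
            ("tier_fractions", self.tier_fractions),
            ("activity_fractions", self.activity_fractions),
        ):
            if abs(sum(fracs.values()) - 1.0) > 1e-9:
                raise ScenarioError(f"{name} must sum to 1")
        if not 0 <= self.shifting_fraction < 1:
            raise ScenarioError("shifting_fraction must be in [0, 1)")
        if self.planted_shift_fold <= self.shift_fold:
            raise ScenarioError("planted_shift_fold must exceed the ten-fold rule threshold")


def _quota(fractions: dict, n: int, order: tuple) -> dict:
    counts = {k: int(round(fractions[k] * n)) for k in order}
    counts[order[-1]] += n - sum(counts.values())
    for k, frac in fractions.items():
        if frac > 0 and counts[k] < 1:
            raise ScenarioError(f"fraction {frac} of category {k!r} yields no OTU at n={n}")
        if counts[k] < 0:
            raise ScenarioError("rounding produced a negative category count")
    return counts


def _truth_labels(comp_row: np.ndarray, ratio_row: np.ndarray, cfg: ScenarioConfig,
                  habitats: tuple) -> dict:
    """Literal transcription of the four classification rules on true values."""
    present = comp_row > 0
    if not present[-1]:
        raise AssertionError("truth requested for an OTU absent from the lake")
    source_pos = int(np.argmax(present))

    def tier(x: float) -> str:
        if x > cfg.dominant_threshold:
            return "dominant"
        if x <= cfg.rare_threshold:
            return "rare"
        return "subdominant"

    lake_ab = float(comp_row[-1])
    src_ab = float(comp_row[source_pos])
    if source_pos == len(habitats) - 1:
        shift = "stable"
    else:
        fold = lake_ab / src_ab
        shift = "shifting" if (fold > cfg.shift_fold or fold < 1 / cfg.shift_fold) else "stable"
    ratios = [float(ratio_row[j]) for j in range(source_pos, len(habitats)) if present[j]]
    pos = [r > 0 for r in ratios]
    activity = "active" if all(pos) else ("inactive" if not any(pos) else "seed")
    return {
        "source": habitats[source_pos],
        "tier": tier(lake_ab),
        "source_tier": tier(src_ab),
        "shift": shift,
        "activity": activity,
    }


def _assign_labels(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_otus
    habitats = HABITAT_ORDER
    tier_n = _quota(cfg.tier_fractions, n, ("dominant", "subdominant", "rare"))
    source_n = _quota(cfg.source_fractions, n, habitats)
    act_n = _quota(cfg.activity_fractions, n, ("active", "inactive", "seed"))

    tiers = np.array(
        ["dominant"] * tier_n["dominant"]
        + ["subdominant"] * tier_n["subdominant"]
        + ["rare"] * tier_n["rare"]
    )
    rng.shuffle(tiers)
    labels = pd.DataFrame({"tier": tiers})
    labels["source"] = ""

    # dominants travel from the river; subdominants have an upstream origin;
    # lake recruits stay rare (the generator's structural constraints).
    is_dom = labels["tier"] == "dominant"
    is_sub = labels["tier"] == "subdominant"
    labels.loc[is_dom, "source"] = "river"
    sub_idx = np.flatnonzero(is_sub.to_numpy())
    rng.shuffle(sub_idx)
    n_sub_river = len(sub_idx) // 2
    labels.loc[sub_idx[:n_sub_river], "source"] = "river"
    labels.loc[sub_idx[n_sub_river:], "source"] = "vegetated"
    rare_idx = np.flatnonzero((labels["tier"] == "rare").to_numpy())
    rng.shuffle(rare_idx)
    need_river = source_n["river"] - int(is_dom.sum()) - n_sub_river
    need_veg = source_n["vegetated"] - (len(sub_idx) - n_sub_river)
    need_lake = source_n["lake"]
    if need_river < 0 or need_veg < 0 or need_river + need_veg + need_lake != len(rare_idx):
        raise ScenarioError(
            "source fractions incompatible with tier structure "
            "(dominants are river-origin, subdominants upstream-origin)"
        )
    labels.loc[rare_idx[:need_river], "source"] = "river"
    labels.loc[rare_idx[need_river:need_river + need_veg], "source"] = "vegetated"
    labels.loc[rare_idx[need_river + need_veg:], "source"] = "lake"

    upstream = labels["source"] != "lake"
    n_shift = int(round(cfg.shifting_fraction * n))
    n_up = n_shift // 2
    n_down = n_shift - n_up
    up_pool = np.flatnonzero((is_sub & upstream).to_numpy())
    down_pool = np.flatnonzero(((labels["tier"] == "rare") & upstream).to_numpy())
    if n_up > len(up_pool) or n_down > len(down_pool):
        raise ScenarioError("shifting_fraction exceeds eligible upstream subdominant/rare OTUs")
    labels["shift"] = "stable"
    labels.loc[rng.choice(up_pool, n_up, replace=False), "shift"] = "shift_up"
    labels.loc[rng.choice(down_pool, n_down, replace=False), "shift"] = "shift_down"

    labels["activity"] = "active"
    seed_pool = np.flatnonzero((upstream & ~is_dom).to_numpy())
    if act_n["seed"] > len(seed_pool):
        raise ScenarioError("seed fraction exceeds upstream-origin, non-dominant OTUs")
    seed_idx = rng.choice(seed_pool, act_n["seed"], replace=False)
    labels.loc[seed_idx, "activity"] = "seed"
    inact_pool = np.flatnonzero(
        (~is_dom & (labels["activity"] != "seed")).to_numpy()
    )
    if act_n["inactive"] > len(inact_pool):
        raise ScenarioError("inactive fraction exceeds non-dominant, non-seed OTUs")
    labels.loc[rng.choice(inact_pool, act_n["inactive"], replace=False), "activity"] = "inactive"
    return labels


def _build_composition(
    cfg: ScenarioConfig, labels: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], int]:
    """True composition matrix (rows: lake OTUs then fillers), cols: habitats."""
    habitats = HABITAT_ORDER
    n = cfg.n_otus
    lake_ab = np.zeros(n)
    dom_idx = labels.index[labels["tier"] == "dominant"]
    sub_idx = labels.index[labels["tier"] == "subdominant"]
    rare_idx = labels.index[labels["tier"] == "rare"]

    # Solve per-tier mass so the lake column sums to one: the rare tail gets a
    # fixed per-OTU mean (safely inside the rare tier and above the detection
    # margin), subdominants a bounded per-OTU mass, dominants the residual.
    rare_mass = len(rare_idx) * cfg.rare_mean_target
    remaining = 1.0 - rare_mass
    if remaining <= 0:
        raise ScenarioError("rare tail mass exceeds the whole community; lower n_otus")
    sub_lo, sub_hi = cfg.subdominant_bounds
    sub_each = float(np.clip(remaining * 0.35 / max(len(sub_idx), 1), sub_lo, sub_hi))
    sub_mass = sub_each * len(sub_idx)
    dom_mass = remaining - sub_mass
    if len(dom_idx):
        dom_each = dom_mass / len(dom_idx)
        if dom_each < cfg.dominant_min * 1.05:
            raise ScenarioError("residual dominant mass too small for a safe dominant plant")
        lake_ab[dom_idx] = dom_each * rng.uniform(0.95, 1.05, len(dom_idx))
        lake_ab[dom_idx] *= dom_mass / lake_ab[dom_idx].sum()
    elif dom_mass > 1e-9:
        raise ScenarioError("no dominant OTUs to absorb the residual community mass")
    if len(sub_idx):
        lake_ab[sub_idx] = sub_each * rng.uniform(0.9, 1.1, len(sub_idx))
        lake_ab[sub_idx] *= sub_mass / lake_ab[sub_idx].sum()
    shape = rng.uniform(0.55, 1.45, len(rare_idx))
    lake_ab[rare_idx] = rare_mass * shape / shape.sum()
    if len(rare_idx) and lake_ab[rare_idx].max() > cfg.rare_threshold:
        raise ScenarioError("rare-tier abundances spill over the rare threshold")
    if len(sub_idx) and not (
        lake_ab[sub_idx].min() > cfg.rare_threshold and lake_ab[sub_idx].max() < cfg.dominant_threshold
    ):
        raise ScenarioError("subdominant plant escaped its tier bounds")

    source_ab = np.zeros(n)
    for tier, (lo, hi) in cfg.stable_fold_ranges.items():
        idx = labels.index[(labels["tier"] == tier) & (labels["shift"] == "stable")
                           & (labels["source"] != "lake")]
        source_ab[idx] = lake_ab[idx] * rng.uniform(lo, hi, len(idx))
    up = labels.index[labels["shift"] == "shift_up"]
    down = labels.index[labels["shift"] == "shift_down"]
    source_ab[up] = lake_ab[up] / cfg.planted_shift_fold
    source_ab[down] = lake_ab[down] * cfg.planted_shift_fold

    comp = np.zeros((n, len(habitats)))
    comp[:, -1] = lake_ab
    river_rows = labels.index[labels["source"] == "river"]
    veg_rows = labels.index[labels["source"] == "vegetated"]
    comp[river_rows, 0] = source_ab[river_rows]
    comp[veg_rows, 1] = source_ab[veg_rows]
    # river-origin OTUs transit through the vegetated habitat
    jitter = rng.uniform(0.8, 1.25, len(river_rows))
    comp[river_rows, 1] = np.sqrt(comp[river_rows, 0] * comp[river_rows, 2]) * jitter

    # fill or renormalize upstream habitats so every column sums to one
    filler_rows: list[np.ndarray] = []
    filler_ids: list[str] = []
    for j, habitat in enumerate(habitats[:-1]):
        total = comp[:, j].sum()
        residual = 1.0 - total
        if residual > 0:
            n_fill = max(1, int(round(residual / 2.5e-4)))
            shape = rng.uniform(0.7, 1.3, n_fill)
            block = np.zeros((n_fill, len(habitats)))
            block[:, j] = residual * shape / shape.sum()
            filler_rows.append(block)
            filler_ids.extend(f"FILL_{habitat}_{k:04d}" for k in range(n_fill))
        else:
            comp[:, j] /= total
    if filler_rows:
        comp = np.vstack([comp] + filler_rows)
    return comp, filler_ids, n


def _build_ratios(
    cfg: ScenarioConfig, labels: pd.DataFrame, comp: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    habitats = HABITAT_ORDER
    n_all = comp.shape[0]
    n = cfg.n_otus
    ratios = np.zeros((n_all, len(habitats)))
    for i in range(n):
        tier = labels.at[i, "tier"]
        activity = labels.at[i, "activity"]
        present = np.flatnonzero(comp[i] > 0)
        if activity == "inactive":
            continue
        draws = np.maximum(
            rng.lognormal(np.log(cfg.ratio_mu[tier]), cfg.ratio_sigma, len(present)),
            cfg.ratio_min,
        )
        ratios[i, present] = draws
        if activity == "seed":
            if len(present) < 2:
                raise ScenarioError("seed planted on a single-habitat OTU")
            n_zero = int(rng.integers(1, len(present)))
            zero_at = rng.choice(present, n_zero, replace=False)
            ratios[i, zero_at] = 0.0
    for i in range(n, n_all):
        present = np.flatnonzero(comp[i] > 0)
        ratios[i, present] = rng.uniform(0.2, 2.0, len(present))
    return ratios


def generate_scenario(
    cfg: ScenarioConfig, noiseless: bool = False
) -> tuple[CountTable, CountTable, SampleSheet, pd.DataFrame]:
    """Generate (dna, rna, sample sheet, truth) for one planted scenario.

    With ``noiseless=True`` the tables hold expected (fractional) counts at
    a fixed depth instead of multinomial draws — feed them straight to the
    classifier to check exact recovery away from decision boundaries.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_label, ss_dna, ss_rna = root.spawn(3)
    rng_label = np.random.default_rng(ss_label)
    rng_dna = np.random.default_rng(ss_dna)
    rng_rna = np.random.default_rng(ss_rna)

    habitats = HABITAT_ORDER
    labels = _assign_labels(cfg, rng_label)
    comp, filler_ids, n = _build_composition(cfg, labels, rng_label)
    ratios = _build_ratios(cfg, labels, comp, rng_label)

    otu_ids = [f"OTU_{i:05d}" for i in range(n)] + filler_ids
    phantom_ids = [f"PHANTOM_{i:03d}" for i in range(cfg.n_phantoms)]
    all_ids = otu_ids + phantom_ids
    n_all = len(all_ids)
    n_body = comp.shape[0]

    # RNA expected composition per habitat: DNA composition x ratio, plus a
    # small RNA-only contribution for each phantom taxon in the lake.
    rna_expect = np.zeros((n_all, len(habitats)))
    for j in range(len(habitats)):
        e = comp[:, j] * ratios[:, j]
        rna_expect[:n_body, j] = e
        if j == len(habitats) - 1 and cfg.n_phantoms:
            rna_expect[n_body:, j] = 2e-4 * e.sum()
        total = rna_expect[:, j].sum()
        if total <= 0:
            raise ScenarioError(f"no RNA mass in habitat {habitats[j]!r}")
        rna_expect[:, j] /= total
    dna_expect = np.vstack([comp, np.zeros((cfg.n_phantoms, len(habitats)))])
    dna_expect /= dna_expect.sum(axis=0, keepdims=True)

    records = []
    dna_cols: dict[str, np.ndarray] = {}
    rna_cols: dict[str, np.ndarray] = {}
    for campaign in cfg.campaigns:
        for j, habitat in enumerate(habitats):
            lo, hi = cfg.depth_ranges[habitat]
            for site in range(1, cfg.sites[habitat] + 1):
                stem = f"{campaign}_{habitat}{site}"
                if noiseless:
                    dna_counts = dna_expect[:, j] * 10_114
                    rna_counts = rna_expect[:, j] * 10_114
                else:
                    dna_counts = rng_dna.multinomial(int(rng_dna.integers(lo, hi + 1)),
                                                     dna_expect[:, j])
                    rna_counts = rng_rna.multinomial(int(rng_rna.integers(lo, hi + 1)),
                                                     rna_expect[:, j])
                dna_cols[f"{stem}_DNA"] = dna_counts
                rna_cols[f"{stem}_RNA"] = rna_counts
                for mol in (DNA, RNA):
                    records.append(
                        {
                            "sample_id": f"{stem}_{mol}",
                            "habitat": habitat,
                            "campaign": campaign,
                            "site_index": site,
                            "pair_id": stem,
                        }
                    )

    dna = CountTable(pd.DataFrame(dna_cols, index=all_ids), DNA)
    rna = CountTable(pd.DataFrame(rna_cols, index=all_ids), RNA)
    sheet = SampleSheet(pd.DataFrame.from_records(records))

    truth_rows = []
    for campaign in cfg.campaigns:
        for i in range(n):
            entry = {"otu_id": otu_ids[i], "campaign": campaign, "role": "lake_otu"}
            entry.update(_truth_labels(comp[i], ratios[i], cfg, habitats))
            for j, habitat in enumerate(habitats):
                entry[f"abund_{habitat}"] = comp[i, j]
                entry[f"ratio_{habitat}"] = ratios[i, j]
            truth_rows.append(entry)
        for i, fid in enumerate(filler_ids):
            row = comp[n + i]
            entry = {"otu_id": fid, "campaign": campaign, "role": "filler"}
            for j, habitat in enumerate(habitats):
                entry[f"abund_{habitat}"] = row[j]
                entry[f"ratio_{habitat}"] = ratios[n + i, j]
            truth_rows.append(entry)
        for pid in phantom_ids:
            truth_rows.append({"otu_id": pid, "campaign": campaign, "role": "phantom"})
    truth = pd.DataFrame.from_records(truth_rows)
    return dna, rna, sheet, truth


def truth_confusion(classifications: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Confusion matrices and accuracies per label family vs planted truth.

    Planted lake OTUs missing from the classification output (lost at the
    detection margin) are scored as "unclassified" mismatches.
    """
    planted = truth[truth["role"] == "lake_otu"]
    truth_keys = set(zip(planted["otu_id"], planted["campaign"]))
    cls_keys = set(zip(classifications["otu_id"], classifications["campaign"]))
    stray = cls_keys - truth_keys
    phantoms = truth.loc[truth["role"] != "lake_otu", "otu_id"]
    stray -= {(o, c) for o, c in stray if o in set(phantoms)}
    if stray:
        raise ValueError(f"classified OTUs absent from the truth table: {sorted(stray)[:5]} ...")
    merged = planted.merge(
        classifications,
        on=["otu_id", "campaign"],
        how="left",
        suffixes=("_true", "_pred"),
    )
    out = {}
    for family in ("source", "tier", "shift", "activity"):
        true = merged[f"{family}_true"]
        pred = merged[f"{family}_pred"].fillna("unclassified")
        out[family] = {
            "confusion": pd.crosstab(true, pred),
            "accuracy": float((true == pred).mean()),
        }
    return out
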