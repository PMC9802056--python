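import numpy as np
import pandas as pd
import pytest

from assemblytrace.synthetic_community import ScenarioConfig, generate_scenario
from assemblytrace.tables_io import DNA, RNA, CountTable, SampleSheet


def make_count_table(counts, otus, samples, molecule=DNA):
    return CountTable(pd.DataFrame(np.asarray(counts), index=otus, columns=samples), molecule)


def make_sheet(rows):
    """rows: (sample_id, habitat, campaign, site_index, pair_id)"""
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "habitat", "campaign", "site_index", "pair_id"])
    )


def one_campaign_sheet(campaign="c1", habitats=(("river", 1), ("vegetated", 5), ("lake", 5))):
    rows = []
    for habitat, n_sites in habitats:
        for site in range(1, n_sites + 1):
            stem = f"{campaign}_{habitat}{site}"
            rows.append((f"{stem}_DNA", habitat, campaign, site, stem))
            rows.append((f"{stem}_RNA", habitat, campaign, site, stem))
    return make_sheet(rows)


@pytest.fixture(scope="session")
def small_scenario():
    cfg = ScenarioConfig(n_otus=400, seed=11, campaigns=("c1", "c2"))
    dna, rna, sheet, truth = generate_scenario(cfg)
    return cfg, dna, rna, sheet, truth


@pytest.fixture
def profile_builder():
    """Build a profiles frame for one campaign from per-habitat OTU states."""

    def build(states, campaign="c1"):
        # states: {otu_id: {habitat: (abund, ratio, det_dna, det_rna, sentinel)}}
        rows = []
        for otu, per_hab in states.items():
            for habitat, (ab, ratio, dd, dr, sent) in per_hab.items():
                rows.append(
                    {
                        "otu_id": otu,
                        "campaign": campaign,
                        "habitat": habitat,
                        "mean_rel_abund": ab,
                        "mean_ratio": ratio,
                        "detected_dna": dd,
                        "detected_rna": dr,
                        "ratio_has_sentinel": sent,
                    }
                )
        return pd.DataFrame.from_records(rows)

    return build
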