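# assemblytrace

Reconstruct how a downstream (lake) microbial community assembles from its
upstream sources, using paired 16S rDNA / rRNA-transcript OTU count tables
sampled along an ordered habitat continuum (river → vegetated habitat →
lake).

The pipeline:

1. **Rarefaction** — each sample is subsampled without replacement to a
   common depth; the procedure is repeated (default 100×) and the mean
   table kept, so rare OTUs are not silently rounded away.
2. **RNA:DNA ratios** — per OTU and aligned sample pair, cDNA reads /
   DNA reads. When DNA is absent a sentinel substitutes: 100 if RNA was
   detected anyway, 0 if both molecules are absent. OTUs never seen in
   DNA within a campaign ("phantom taxa") are excluded and reported.
3. **Per-habitat profiles** — relative abundance and ratio averaged
   across sites, one value per (OTU, campaign, habitat); sentinel-bearing
   means are flagged and excluded from trend statistics.
4. **Classification** of every lake-detected OTU per campaign:
   - *source*: most upstream habitat with DNA detection;
   - *tier*: dominant (>1 %), subdominant, or rare (≤0.1 %) by lake
     relative abundance;
   - *shift*: more than ten-fold change of lake abundance vs the source
     habitat (strict), otherwise stable;
   - *activity*: ratio pattern from the source habitat to the lake —
     all positive = active, all zero = inactive, mixed = seed.
5. **Aggregation** — per-campaign composite category proportions with
   cross-campaign mean ± sample SD, tier read contributions, rank tests
   of 16S copy number across tiers (Kruskal–Wallis + pairwise Wilcoxon
   with Bonferroni), alpha diversity, a deep-reference retrace, and an
   absolute-abundance (flow-cytometry-scaled) cross-check of shift calls.
6. **Synthetic scenarios** — a generator that plants source/tier/shift/
   activity labels in paired multinomial read tables with fully
   recoverable ground truth, used throughout the test suite.

## CLI

```sh
# generate a planted synthetic scenario
assemblytrace simulate --n-otus 2000 --seed 1 --out scenario/

# full pipeline on TSV inputs (OTU x sample tables + sample metadata)
assemblytrace run --dna scenario/dna.tsv --rna scenario/rna.tsv \
    --meta scenario/meta.tsv --depth 10114 --repetitions 100 --seed 1 \
    --out results/

# individual stages
assemblytrace rarefy --table dna.tsv --depth 10114 --out rarefied.tsv
assemblytrace classify --dna rarefied_dna.tsv --rna rarefied_rna.tsv \
    --meta meta.tsv --out classifications.tsv
assemblytrace summarize --classifications classifications.tsv --out summary.json
```

Sample metadata is TSV with columns `sample_id, habitat, campaign,
site_index, pair_id`; `pair_id` joins each DNA sample to its RNA partner.
A YAML config (`--config`) can set `rarefaction`, `ratio`, `tiers`, and
`trend_bins` options.

Outputs: `profiles.tsv` (per OTU/campaign/habitat), `classifications.tsv`
(per lake OTU/campaign), `trend.tsv` (binned ratio–abundance trend), and
`summary.json` (category proportions, tier contributions, phantom counts).

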