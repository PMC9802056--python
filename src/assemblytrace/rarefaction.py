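"""Repeated rarefaction: subsample each sample to a common depth and average.

Subsampling is without replacement (multivariate hypergeometric draw per
sample).  Each sample gets its own random stream derived from the global
seed and the sample identifier, so dropping or reordering samples never
perturbs another sample's draw.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CountTable


class DepthError(ValueError):
    """A sample is shallower than the requested rarefaction depth."""


@dataclass
class RarefactionConfig:
    depth: int | None = 10_114
    repetitions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 1:
            raise ValueError("depth must be a positive integer")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    digest = hashlib.blake2b(str(sample_id).encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**63, int.from_bytes(digest, "big")])
    )


def resolve_depth(table: CountTable, depth: int | None) -> int:
    """Default the depth to the shallowest sample when unset."""
    if depth is not None:
        return int(depth)
    return int(table.column_sums().min())


def _check_depth(counts: np.ndarray, depth: int, sample: str) -> None:
    total = int(counts.sum())
    if total < depth:
        raise DepthError(
            f"sample {sample!r} has {total} reads, fewer than rarefaction depth {depth}"
        )


def rarefy_once(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """One uniform random subsample without replacement per sample."""
    if not table.is_integer():
        raise ValueError("rarefy_once requires an integer (raw) count table")
    out = {}
    for sample in table.sample_ids:
        counts = table.data[sample].to_numpy().astype(np.int64)
        _check_depth(counts, depth, sample)
        rng = _sample_rng(seed, sample)
        out[sample] = rng.multivariate_hypergeometric(counts, depth)
    frame = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return CountTable(frame, table.molecule)


def rarefy_mean(table: CountTable, cfg: RarefactionConfig) -> CountTable:
    """Entrywise mean of ``cfg.repetitions`` independent rarefactions.

    Counts become fractional; each column still sums to the depth by
    linearity.  The result is bit-reproducible for a fixed seed.
    """
    if not table.is_integer():
        raise ValueError("rarefy_mean requires an integer (raw) count table")
    depth = resolve_depth(table, cfg.depth)
    out = {}
    for sample in table.sample_ids:
        counts = table.data[sample].to_numpy().astype(np.int64)
        _check_depth(counts, depth, sample)
        rng = _sample_rng(cfg.seed, sample)
        totals = np.zeros(len(counts), dtype=np.int64)
        for _ in range(cfg.repetitions):
            totals += rng.multivariate_hypergeometric(counts, depth)
        out[sample] = totals / cfg.repetitions
    frame = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return CountTable(frame, table.molecule)


def drop_shallow_samples(table: CountTable, depth: int) -> tuple[CountTable, list[str]]:
    """Split off samples too shallow for ``depth`` (caller logs/decides)."""
    sums = table.column_sums()
    shallow = [s for s in table.sample_ids if sums[s] < depth]
    if not shallow:
        return table, []
    kept = table.data.drop(columns=shallow)
    return CountTable(kept, table.molecule), shallow
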