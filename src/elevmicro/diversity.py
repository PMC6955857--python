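"""Rarefaction and alpha/beta diversity.

Alpha diversity is observed OTU richness and Shannon entropy of relative
abundances (log base 2 by default, configurable since published pipelines
differ). Beta diversity is Jaccard on presence/absence and Bray–Curtis on
abundances. Rarefaction subsamples each sample's reads without replacement
to a common depth, mirroring the single re-sampling step of standard
amplicon pipelines; samples shallower than the depth are dropped, not
padded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import CommunityTable, DistanceMatrix

logger = logging.getLogger(__name__)


def rarefy(table: CommunityTable, depth: int, seed: int = 0) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Uses a multivariate hypergeometric draw per sample (equivalent to
    shuffling the sample's reads and keeping the first ``depth``). Samples
    with fewer than ``depth`` total reads are dropped with a warning; a
    sample at exactly ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    counts = table.matrix
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped[:5])
    if not keep.any():
        raise ValueError("all samples below rarefaction depth")
    out_rows = []
    for row, total in zip(counts[keep], totals[keep]):
        if total == depth:
            out_rows.append(row.copy())
        else:
            out_rows.append(rng.multivariate_hypergeometric(row, depth))
    sub = pd.DataFrame(
        np.vstack(out_rows),
        index=[s for s, k in zip(table.sample_ids, keep) if k],
        columns=table.taxon_ids,
    )
    return CommunityTable(sub, table.taxonomy)


def observed_otus(counts) -> int:
    """Number of taxa with a strictly positive count."""
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValueError("negative counts")
    return int(np.count_nonzero(counts))


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy −Σ p_i log_base p_i over positive entries."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon entropy undefined for an empty sample")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def alpha_diversity(table: CommunityTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample observed OTUs and Shannon diversity."""
    records = []
    for sid, row in zip(table.sample_ids, table.matrix):
        records.append(
            {"sample_id": sid, "observed_otus": observed_otus(row),
             "shannon": shannon(row, base=base)}
        )
    return pd.DataFrame.from_records(records).set_index("sample_id", drop=False)


def rarefaction_curve(
    table: CommunityTable, depths, reps: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Mean observed richness per sample at each subsampling depth.

    Depths exceeding a sample's total yield NaN for that sample. Returns a
    samples × depths frame of means over ``reps`` independent draws.
    """
    depths = list(depths)
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    if sorted(depths) != depths:
        raise ValueError("depths must be ascending")
    rng = np.random.default_rng(seed)
    counts = table.matrix
    totals = counts.sum(axis=1)
    out = np.full((len(table.sample_ids), len(depths)), np.nan)
    for i, (row, total) in enumerate(zip(counts, totals)):
        for k, d in enumerate(depths):
            if d > total:
                continue
            if d == total:
                out[i, k] = observed_otus(row)
                continue
            vals = [
                np.count_nonzero(rng.multivariate_hypergeometric(row, d))
                for _ in range(reps)
            ]
            out[i, k] = float(np.mean(vals))
    return pd.DataFrame(out, index=table.sample_ids, columns=depths)


def _check_rows(table: CommunityTable) -> np.ndarray:
    counts = table.matrix
    if counts.shape[0] < 2:
        raise ValueError("need at least two samples")
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty sample in table")
    return counts


def bray_curtis_matrix(table: CommunityTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity d = 1 − 2·Σ min(x,y) / (Σx + Σy)."""
    counts = _check_rows(table).astype(float)
    vals = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, vals, "bray_curtis")


def jaccard_matrix(table: CommunityTable) -> DistanceMatrix:
    """Jaccard dissimilarity on presence/absence, d = 1 − |A∩B|/|A∪B|."""
    counts = _check_rows(table)
    vals = squareform(pdist(counts > 0, metric="jaccard"))
    return DistanceMatrix(table.sample_ids, vals, "jaccard")
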