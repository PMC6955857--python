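"""Community assembly partitioning via βNTI and Raup–Crick (Bray–Curtis).

For every within-group sample pair the analysis computes:

* weighted βMNTD — the abundance-weighted mean patristic distance from each
  taxon in one community to its nearest relative in the other,
* βNTI — the z-score of the observed βMNTD against a null distribution in
  which taxon labels are shuffled across the tree tips (the ``taxa.labels``
  convention; shuffling is restricted to the taxa in the table),
* RC_bray — the scaled rank of the observed Bray–Curtis dissimilarity
  within a null ensemble of probabilistically assembled community pairs
  (each null sample draws its observed richness with probability
  proportional to occupancy, then fills to its observed read total with
  probability proportional to mean relative abundance), mapped to [−1, 1].

Pairs are then classified: βNTI > +2 → variable selection; βNTI < −2 →
homogeneous selection; otherwise RC_bray > +0.95 → dispersal limitation,
RC_bray < −0.95 → homogenizing dispersal, else undominated. Selection
processes are deterministic; dispersal and undominated are stochastic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CommunityTable, DistanceMatrix, Phylogeny

logger = logging.getLogger(__name__)

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)
DETERMINISTIC_PROCESSES = ("variable_selection", "homogeneous_selection")


@dataclass
class AssemblyParameters:
    bnti_reps: int = 999
    rc_reps: int = 999
    bnti_upper: float = 2.0
    bnti_lower: float = -2.0
    rc_upper: float = 0.95
    rc_lower: float = -0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bnti_reps < 1 or self.rc_reps < 1:
            raise ValueError("replicate counts must be >= 1")


# ---------------------------------------------------------------------------
# βMNTD / βNTI


def bmntd(x, y, patristic: np.ndarray, weighted: bool = True) -> float:
    """Beta mean nearest taxon distance between two count vectors.

    ``patristic`` is the taxon × taxon distance matrix in the vectors'
    taxon order. A taxon present in both communities contributes a nearest
    distance of 0 (it is its own nearest relative). Weighted uses relative
    abundances; unweighted gives each present taxon weight 1/richness.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("empty sample in bmntd")
    ix = np.flatnonzero(x)
    iy = np.flatnonzero(y)
    sub = patristic[np.ix_(ix, iy)]
    if weighted:
        fx = x[ix] / x.sum()
        fy = y[iy] / y.sum()
    else:
        fx = np.full(ix.size, 1.0 / ix.size)
        fy = np.full(iy.size, 1.0 / iy.size)
    return float(0.5 * (fx @ sub.min(axis=1) + fy @ sub.min(axis=0)))


def _all_pairs_bmntd(counts: np.ndarray, dist: np.ndarray, weighted: bool) -> np.ndarray:
    n = counts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bmntd(counts[i], counts[j], dist, weighted)
    return out


def bnti_matrix(
    table: CommunityTable,
    tree: Phylogeny,
    params: AssemblyParameters | None = None,
    weighted: bool = True,
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Pairwise βNTI (and observed βMNTD) for all samples in the table.

    The null shuffles taxon labels across the tips represented in the table
    (one shuffle per replicate, shared by all pairs, as in the picante
    lineage of implementations). Pairs whose null βMNTD has zero standard
    deviation — e.g. a star phylogeny, where shuffling cannot change any
    distance — are returned as NaN and excluded from process fractions.
    """
    params = params or AssemblyParameters()
    taxa = table.taxon_ids
    _, dist = tree.patristic_matrix(taxa)
    counts = table.matrix.astype(float)
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")

    observed = _all_pairs_bmntd(counts, dist, weighted)

    rng = np.random.default_rng(params.seed)
    iu = np.triu_indices(n, k=1)
    null = np.empty((params.bnti_reps, iu[0].size))
    for r in range(params.bnti_reps):
        perm = rng.permutation(len(taxa))
        dp = dist[np.ix_(perm, perm)]
        null[r] = _all_pairs_bmntd(counts, dp, weighted)[iu]

    mean_null = null.mean(axis=0)
    sd_null = null.std(axis=0, ddof=1)
    # summation-order jitter can make a constant null's sd ~1e-16, not 0
    degenerate = sd_null <= 1e-9 * np.maximum(1.0, np.abs(mean_null))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed[iu] - mean_null) / sd_null
    z = np.where(~degenerate, z, np.nan)
    n_undef = int(np.isnan(z).sum())
    if n_undef:
        logger.warning("%d pairs have zero null variance; βNTI undefined", n_undef)

    bnti = np.zeros((n, n))
    bnti[iu] = z
    bnti = bnti + bnti.T
    obs_dm = DistanceMatrix(table.sample_ids, observed, "bmntd")
    return DistanceMatrix(table.sample_ids, bnti, "bnti"), obs_dm


# ---------------------------------------------------------------------------
# Raup–Crick (Bray–Curtis)


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    denom = x.sum() + y.sum()
    return 1.0 - 2.0 * np.minimum(x, y).sum() / denom


def _null_sample(
    richness: int,
    total: int,
    occupancy: np.ndarray,
    mean_rel: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n_taxa = occupancy.size
    chosen = rng.choice(n_taxa, size=richness, replace=False, p=occupancy)
    counts = np.zeros(n_taxa)
    counts[chosen] = 1.0
    remaining = total - richness
    if remaining > 0:
        w = mean_rel[chosen]
        counts[chosen] += rng.multinomial(remaining, w / w.sum())
    return counts


def raup_crick_bray(
    table: CommunityTable, params: AssemblyParameters | None = None
) -> DistanceMatrix:
    """Pairwise RC_bray in [−1, 1].

    For each pair, ``rc_reps`` null community pairs are assembled from the
    table-wide occupancy and mean-relative-abundance pools; RC is the
    centered, doubled rank of the observed Bray–Curtis within the null
    (ties counted half): RC = 2·[(#{null < obs} + ½·#{null = obs})/reps] − 1.
    """
    params = params or AssemblyParameters()
    counts = table.matrix.astype(float)
    n, n_taxa = counts.shape
    if n < 2:
        raise ValueError("need at least two samples")
    present_any = (counts > 0).any(axis=0)
    if present_any.sum() < 2:
        raise ValueError("Raup–Crick needs at least two taxa in the metacommunity")

    occupancy = (counts > 0).mean(axis=0)
    occ_p = occupancy / occupancy.sum()
    rel = counts / counts.sum(axis=1, keepdims=True)
    mean_rel = rel.mean(axis=0)
    mean_rel = np.where(mean_rel > 0, mean_rel, 1e-12)

    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1).astype(int)

    rng = np.random.default_rng(params.seed + 1)
    rc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            obs = _bray_curtis(counts[i], counts[j])
            below = ties = 0
            for _ in range(params.rc_reps):
                a = _null_sample(int(richness[i]), int(totals[i]), occ_p, mean_rel, rng)
                b = _null_sample(int(richness[j]), int(totals[j]), occ_p, mean_rel, rng)
                bc = _bray_curtis(a, b)
                if bc < obs - 1e-12:
                    below += 1
                elif abs(bc - obs) <= 1e-12:
                    ties += 1
            rc[i, j] = rc[j, i] = 2.0 * ((below + 0.5 * ties) / params.rc_reps) - 1.0
    return DistanceMatrix(table.sample_ids, rc, "rc_bray")


# ---------------------------------------------------------------------------
# Classification and roll-up


def classify_processes(
    bnti: float, rc: float, params: AssemblyParameters | None = None
) -> str:
    """Assign one sample pair to an assembly process from (βNTI, RC_bray)."""
    params = params or AssemblyParameters()
    if np.isnan(bnti) or np.isnan(rc):
        raise ValueError("undefined bnti or rc for pair")
    if bnti > params.bnti_upper:
        return "variable_selection"
    if bnti < params.bnti_lower:
        return "homogeneous_selection"
    if rc > params.rc_upper:
        return "dispersal_limitation"
    if rc < params.rc_lower:
        return "homogenizing_dispersal"
    return "undominated"


@dataclass
class ProcessFractions:
    group_label: str
    n_pairs: int
    fractions: dict[str, float]

    @property
    def deterministic_fraction(self) -> float:
        return sum(self.fractions[p] for p in DETERMINISTIC_PROCESSES)

    @property
    def stochastic_fraction(self) -> float:
        return 1.0 - self.deterministic_fraction


def process_fractions(pairs: pd.DataFrame, groups: dict[str, str]) -> list[ProcessFractions]:
    """Per-group process fractions over within-group classified pairs.

    ``pairs`` must have columns sample_i, sample_j, process. Cross-group
    pairs are ignored; groups with no classified within-group pair are
    excluded with a warning.
    """
    out = []
    for label in sorted(set(groups.values())):
        members = {s for s, g in groups.items() if g == label}
        mask = pairs["sample_i"].isin(members) & pairs["sample_j"].isin(members)
        sub = pairs.loc[mask & pairs["process"].notna()]
        if len(sub) == 0:
            logger.warning("group %r has no classified within-group pairs", label)
            continue
        counts = sub["process"].value_counts()
        fractions = {p: float(counts.get(p, 0)) / len(sub) for p in PROCESSES}
        out.append(ProcessFractions(label, len(sub), fractions))
    return out


def fractions_frame(fracs: list[ProcessFractions]) -> pd.DataFrame:
    rows = []
    for f in fracs:
        row = {"group": f.group_label, "n_pairs": f.n_pairs, **f.fractions}
        row["deterministic"] = f.deterministic_fraction
        row["stochastic"] = f.stochastic_fraction
        rows.append(row)
    return pd.DataFrame(rows)


def group_assembly(
    table: CommunityTable,
    tree: Phylogeny,
    groups: dict[str, str],
    params: AssemblyParameters | None = None,
) -> tuple[pd.DataFrame, list[ProcessFractions]]:
    """Run the full βNTI + RC_bray partitioning within each sample group.

    Each group is analysed as its own metacommunity (its samples and the
    taxa present in them), matching per-group reporting of process
    fractions. Returns the per-pair table (sample_i, sample_j, bmntd, bnti,
    rc_bray, process; process is None where βNTI is undefined) and the
    per-group fractions.
    """
    params = params or AssemblyParameters()
    records = []
    for g_idx, label in enumerate(sorted(set(groups.values()))):
        members = [s for s in table.sample_ids if groups.get(s) == label]
        if len(members) < 2:
            logger.warning("group %r has fewer than two samples; skipped", label)
            continue
        sub = table.select_samples(members)
        present = [t for t, keep in zip(sub.taxon_ids, (sub.matrix > 0).any(axis=0)) if keep]
        sub = sub.select_taxa(present)
        gp = AssemblyParameters(
            bnti_reps=params.bnti_reps, rc_reps=params.rc_reps,
            bnti_upper=params.bnti_upper, bnti_lower=params.bnti_lower,
            rc_upper=params.rc_upper, rc_lower=params.rc_lower,
            seed=params.seed + 1000 * g_idx,
        )
        bnti_dm, bmntd_dm = bnti_matrix(sub, tree, gp)
        rc_dm = raup_crick_bray(sub, gp)
        ids = sub.sample_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                b = bnti_dm.values[i, j]
                r = rc_dm.values[i, j]
                process = None if np.isnan(b) else classify_processes(b, r, gp)
                records.append(
                    {
                        "group": label,
                        "sample_i": ids[i],
                        "sample_j": ids[j],
                        "bmntd": bmntd_dm.values[i, j],
                        "bnti": b,
                        "rc_bray": r,
                        "process": process,
                    }
                )
    pairs = pd.DataFrame.from_records(records)
    fracs = process_fractions(pairs, groups) if len(pairs) else []
    return pairs, fracs
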