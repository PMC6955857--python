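"""Elevation-gradient inference: taxon classification and permutation tests.

Implements the statistical core used along the gradient:

* Benjamini–Hochberg step-up FDR control,
* Spearman taxon–elevation screening into ``tolerant`` (positive
  correlation), ``sensitive`` (negative) and ``not_significant`` classes,
* OLS trends of per-sample statistics on elevation,
* PERMANOVA with sequential (type-I) sums of squares on a Gower-centered
  distance matrix (the ``adonis`` convention: term order matters),
* ANOSIM, (partial) Mantel, and the Wilcoxon rank-sum test.

All permutation p-values use the protected estimator
``(1 + #{perm ≥ obs}) / (1 + permutations)`` and are seed-deterministic.
Ranks use average ties throughout.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CommunityTable, DistanceMatrix

logger = logging.getLogger(__name__)

#: host covariates controlled for in the partial Mantel test
HOST_CATEGORICAL = ("subject_id", "gender", "body_site")
HOST_NUMERIC = ("age", "height", "weight")


# ---------------------------------------------------------------------------
# Multiple testing


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Spearman screening


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ties."""
    rx, ry = _rank(np.asarray(x, float)), _rank(np.asarray(y, float))
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_test(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rho and two-sided p.

    Exact permutation null (all n! rank orders) for n <= ``exact_max_n``;
    the large-sample t approximation with n − 2 degrees of freedom above.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for Spearman screening")
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return rho, float("nan")
    if n <= exact_max_n:
        rx, ry = _rank(x), _rank(y)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        null = (rxc[perms] @ ryc) / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


@dataclass
class TaxonClassification:
    taxon_id: str
    spearman_rho: float
    p_value: float
    q_value: float
    taxon_class: str  # tolerant | sensitive | not_significant


def classify_elevation_response(
    table: CommunityTable,
    metadata: pd.DataFrame,
    mean_abund_floor: float = 0.0009,
    alpha: float = 0.05,
) -> list[TaxonClassification]:
    """Classify taxa as elevation-tolerant / elevation-sensitive.

    For each taxon above the mean relative-abundance floor, the Spearman
    correlation of relative abundance against elevation is tested across
    samples; p-values are BH-corrected over the tested taxa. A taxon is
    ``tolerant`` if rho > 0 and q <= alpha, ``sensitive`` if rho < 0 and
    q <= alpha, otherwise ``not_significant``. The default floor of 0.09%
    mean relative abundance targets core genus-level screening.
    """
    rel = table.relative_abundance()
    elev = metadata.loc[rel.index, "elevation_m"].to_numpy(float)
    if elev.size < 4:
        raise ValueError("need at least 4 samples")
    keep = rel.mean(axis=0) >= mean_abund_floor
    tested = rel.loc[:, keep]
    if tested.shape[1] == 0:
        raise ValueError("no taxa above the abundance floor")
    results = []
    rhos, ps = [], []
    for taxon in tested.columns:
        rho, p = spearman_test(tested[taxon].to_numpy(), elev)
        rhos.append(rho)
        ps.append(p)
    valid = np.array([not math.isnan(p) for p in ps])
    qs = np.full(len(ps), np.nan)
    if valid.any():
        qs[valid] = bh_fdr(np.asarray(ps)[valid])
    for taxon, rho, p, q in zip(tested.columns, rhos, ps, qs):
        if math.isnan(p) or math.isnan(q):
            cls = "not_significant"
        elif q <= alpha and rho > 0:
            cls = "tolerant"
        elif q <= alpha and rho < 0:
            cls = "sensitive"
        else:
            cls = "not_significant"
        results.append(TaxonClassification(str(taxon), float(rho), float(p), float(q), cls))
    return results


def classification_frame(classifications: list[TaxonClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [c.taxon_id for c in classifications],
            "spearman_rho": [c.spearman_rho for c in classifications],
            "p_value": [c.p_value for c in classifications],
            "q_value": [c.q_value for c in classifications],
            "class": [c.taxon_class for c in classifications],
        }
    )


# ---------------------------------------------------------------------------
# Trends


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_trend(y, x) -> TrendFit:
    """Ordinary least squares of y on x with a two-sided t test on the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return TrendFit(float(res.slope), float(res.intercept),
                    float(res.rvalue**2), float(res.pvalue), x.size)


def within_group_dissimilarity_trend(
    dist: DistanceMatrix, metadata: pd.DataFrame, group_col: str = "elevation_m"
) -> TrendFit:
    """OLS of within-site pairwise dissimilarities on the site's elevation.

    Every within-site pair contributes one point (response = dissimilarity,
    predictor = that site's elevation). Sites with a single sample carry no
    pairs and are skipped with a warning.
    """
    meta = metadata.loc[dist.ids]
    ys, xs = [], []
    for value, sub in meta.groupby(group_col, sort=True):
        ids = list(sub.index)
        if len(ids) < 2:
            logger.warning("group %r has a single sample; skipped", value)
            continue
        sub_d = dist.submatrix(ids)
        ys.extend(sub_d.condensed().tolist())
        xs.extend([float(sub["elevation_m"].iloc[0])] * (len(ids) * (len(ids) - 1) // 2))
    if len(set(xs)) < 2:
        raise ValueError("need within-group pairs from at least two elevations")
    return fit_trend(ys, xs)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    term: str
    df: int
    sum_of_squares: float
    r_squared: float
    pseudo_f: float
    p_value: float


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())))
    q = q[:, :rank]
    return q @ q.T


def _model_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    col = metadata[term]
    if pd.api.types.is_numeric_dtype(col):
        v = col.to_numpy(float)
        if np.ptp(v) == 0:
            raise ValueError(f"term {term!r} is constant")
        return v[:, None]
    dummies = pd.get_dummies(col.astype(str), drop_first=True)
    if dummies.shape[1] == 0:
        raise ValueError(f"term {term!r} has a single level")
    return dummies.to_numpy(float)


def permanova(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    permutations: int = 999,
    seed: int = 0,
) -> list[PermanovaResult]:
    """Distance-based multivariate ANOVA with sequential term decomposition.

    Partitions the total sum of squares of the Gower-centered matrix over
    ``terms`` in the given order (type-I, the ``adonis`` default — term
    order changes each term's share). Per-term p-values come from jointly
    permuting the distance matrix's rows and columns. Categorical terms are
    dummy-coded; numeric metadata columns enter as single covariates.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    meta = metadata.loc[dist.ids]
    n = dist.n
    g = _gower_center(dist.values)
    ss_total = float(np.trace(g))

    term_cols = [_model_columns(meta, t) for t in terms]
    hats = []
    x = np.ones((n, 1))
    prev_hat = _hat(x)
    prev_rank = 1
    dfs = []
    for cols in term_cols:
        x = np.hstack([x, cols])
        h = _hat(x)
        rank = int(round(np.trace(h)))
        dfs.append(rank - prev_rank)
        hats.append((h, prev_hat))
        prev_hat, prev_rank = h, rank
    if any(df == 0 for df in dfs):
        raise ValueError("a term adds no degrees of freedom (aliased with earlier terms)")
    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    resid_proj = np.eye(n) - prev_hat

    def decompose(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([np.trace((h - hp) @ gmat) for h, hp in hats])
        ss_res = float(np.trace(resid_proj @ gmat))
        return ss_terms, ss_res

    ss_obs, ss_res_obs = decompose(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = decompose(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        exceed += f_p >= f_obs - 1e-12
    p_vals = (1.0 + exceed) / (1.0 + permutations)

    results = [
        PermanovaResult(t, int(df), float(ss), float(ss / ss_total), float(f), float(p))
        for t, df, ss, f, p in zip(terms, dfs, ss_obs, f_obs, p_vals)
    ]
    results.append(
        PermanovaResult("Residual", int(df_res), float(ss_res_obs),
                        float(ss_res_obs / ss_total), float("nan"), float("nan"))
    )
    return results


def permanova_frame(results: list[PermanovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "df": [r.df for r in results],
            "sum_of_squares": [r.sum_of_squares for r in results],
            "r_squared": [r.r_squared for r in results],
            "pseudo_f": [r.pseudo_f for r in results],
            "p_value": [r.p_value for r in results],
        }
    )


# ---------------------------------------------------------------------------
# ANOSIM


def _anosim_r(rank_d: np.ndarray, same_group: np.ndarray, n: int) -> float:
    rb = rank_d[~same_group].mean()
    rw = rank_d[same_group].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    dist: DistanceMatrix, grouping, permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """ANOSIM R statistic and permutation p-value.

    R = (mean rank of between-group dissimilarities − mean rank of
    within-group dissimilarities) / (n(n−1)/4), with dissimilarities ranked
    jointly (average ties). R near 1 means complete separation; the null is
    a random relabelling of samples.
    """
    groups = np.asarray(list(grouping))
    if groups.size != dist.n:
        raise ValueError("grouping length must match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    n = dist.n
    cond = dist.condensed()
    rank_d = stats.rankdata(cond)
    iu, ju = np.triu_indices(n, k=1)

    same = groups[iu] == groups[ju]
    r_obs = _anosim_r(rank_d, same, n)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        gp = rng.permutation(groups)
        same_p = gp[iu] == gp[ju]
        if _anosim_r(rank_d, same_p, n) >= r_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + permutations)
    return r_obs, float(p)


# ---------------------------------------------------------------------------
# Mantel / partial Mantel


def _offdiag(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _residualize(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_mantel(
    d_community: DistanceMatrix,
    d_predictor: DistanceMatrix,
    d_control: DistanceMatrix | None = None,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """(Partial) Mantel correlation with permutation inference.

    Pearson correlation of the upper-triangle entries of the community and
    predictor matrices; when a control matrix is given both are first
    residualized on it (the residual method). The null permutes the
    community matrix's rows and columns jointly; the test is one-sided for
    positive association, the standard ecological convention.
    """
    if d_predictor.ids != d_community.ids or (
        d_control is not None and d_control.ids != d_community.ids
    ):
        raise ValueError("distance matrices must share the same ids in the same order")
    n = d_community.n
    b = _offdiag(d_predictor.values)
    c = _offdiag(d_control.values) if d_control is not None else None

    def corr_with(a_mat: np.ndarray) -> float:
        a = _offdiag(a_mat)
        if c is not None:
            a_r = _residualize(a, c)
            b_r = _residualize(b, c)
        else:
            a_r, b_r = a, b
        a_r = a_r - a_r.mean()
        b_r = b_r - b_r.mean()
        denom = np.sqrt((a_r**2).sum() * (b_r**2).sum())
        if denom == 0:
            return float("nan")
        return float((a_r * b_r).sum() / denom)

    r_obs = corr_with(d_community.values)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if corr_with(d_community.values[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + permutations)
    return r_obs, float(p)


def elevation_factor_matrices(
    metadata: pd.DataFrame, ids: list[str] | None = None
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Predictor and control matrices for the partial Mantel test.

    Returns (|Δ elevation| in meters, Gower distance over host factors).
    The Gower distance averages, with equal weights, 0/1 mismatch for
    subject, gender, and body site with range-normalized absolute
    differences for age, height, and weight.
    """
    meta = metadata if ids is None else metadata.loc[ids]
    for col in ("elevation_m",) + HOST_CATEGORICAL + HOST_NUMERIC:
        if col not in meta.columns:
            raise ValueError(f"metadata missing field {col!r}")
        if meta[col].isna().any():
            raise ValueError(f"metadata field {col!r} has missing values")
    idx = list(meta.index.astype(str))
    elev = meta["elevation_m"].to_numpy(float)
    d_elev = np.abs(elev[:, None] - elev[None, :])

    parts = []
    for col in HOST_CATEGORICAL:
        v = meta[col].to_numpy()
        parts.append((v[:, None] != v[None, :]).astype(float))
    for col in HOST_NUMERIC:
        v = meta[col].to_numpy(float)
        rng_v = np.ptp(v)
        diff = np.abs(v[:, None] - v[None, :])
        parts.append(diff / rng_v if rng_v > 0 else np.zeros_like(diff))
    d_gower = np.mean(parts, axis=0)
    return (
        DistanceMatrix(idx, d_elev, "abs_elevation_difference"),
        DistanceMatrix(idx, d_gower, "host_gower"),
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_rank_sum(x, y, exact_limit: int = 200_000) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (rank-sum of the first sample, p-value). The null distribution
    is enumerated exactly when there are no ties and the number of rank
    assignments C(n1+n2, n1) is at most ``exact_limit``; otherwise the
    normal approximation with tie correction is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0

    has_ties = np.unique(pooled).size < n
    if not has_ties and math.comb(n, n1) <= exact_limit:
        all_ranks = np.arange(1, n + 1)
        null = np.fromiter(
            (sum(c) for c in itertools.combinations(all_ranks, n1)),
            dtype=float,
            count=math.comb(n, n1),
        )
        p = float(np.mean(np.abs(null - mean_w) >= abs(w - mean_w) - 1e-12))
        return w, min(p, 1.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(p, 1.0))
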