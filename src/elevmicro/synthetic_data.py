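"""Synthetic OTU tables with planted elevation gradients and assembly regimes.

The generator emulates a skin-swab study design: seven elevation sites
(501–3431 m), five subjects per site, three body sites per subject
(105 samples), sequencing depths around 18,525 reads. Into that design it
plants structure every downstream stage can be tested against:

* taxa whose log-abundance rises (``tolerant``) or falls (``sensitive``)
  with elevation, optionally phylogenetically autocorrelated,
* richness loss with elevation (``alpha_decay``) and rising subject-level
  compositional noise with elevation (``beta_inflation``),
* a selectable community-assembly regime controlling the between-sample
  covariance, so that phylogenetic (βNTI) and taxonomic (RC_bray) null
  models see the signatures of selection, dispersal, or drift.

Counts are Dirichlet-multinomial: each sample's composition is a Dirichlet
perturbation (concentration ``1/overdispersion``) of its expected
composition, then a multinomial draw at a lognormal depth. All randomness
flows from a single integer seed through ``numpy.random.SeedSequence``
spawning, one child stream per generation step, so changing one step never
shifts another's draws.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .core_io import BODY_SITES, CommunityTable, Phylogeny, metadata_from_records

#: the seven study-site elevations in meters
DEFAULT_SITE_ELEVATIONS_M = (501.0, 2298.0, 2690.0, 3110.0, 3150.0, 3271.0, 3431.0)

REGIMES = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


@dataclass
class GradientDesign:
    """Sampling design of the emulated study."""

    site_elevations_m: tuple[float, ...] = DEFAULT_SITE_ELEVATIONS_M
    subjects_per_site: int = 5
    body_sites: tuple[str, ...] = BODY_SITES
    depth_mean: float = 18_525.0
    depth_cv: float = 765.0 / 18_525.0  # lognormal depth spread (SD/mean)
    rarefaction_depth: int = 15_596

    def __post_init__(self) -> None:
        if self.subjects_per_site < 1:
            raise ValueError("subjects_per_site must be >= 1")
        if self.depth_mean < self.rarefaction_depth:
            raise ValueError("depth_mean must be >= rarefaction_depth")

    @property
    def n_samples(self) -> int:
        return len(self.site_elevations_m) * self.subjects_per_site * len(self.body_sites)


@dataclass
class TaxonTruth:
    """Planted per-taxon ground truth.

    ``elevation_slope`` is the signed effect on log-abundance per km of
    elevation; ``niche_trait`` is a standardized Brownian-motion tip trait
    used by selection regimes as the taxon's environmental optimum.
    """

    taxon_id: str
    taxon_class: str  # tolerant | sensitive | neutral
    elevation_slope: float
    base_log_abundance: float
    niche_trait: float

    def __post_init__(self) -> None:
        if self.taxon_class == "tolerant" and not self.elevation_slope > 0:
            raise ValueError("tolerant taxa must have positive slope")
        if self.taxon_class == "sensitive" and not self.elevation_slope < 0:
            raise ValueError("sensitive taxa must have negative slope")
        if self.taxon_class == "neutral" and self.elevation_slope != 0:
            raise ValueError("neutral taxa must have zero slope")


@dataclass
class AssemblyRegime:
    """Assembly regime plus its strength parameters.

    filter_width
        Width (in standardized niche-trait units) of the Gaussian
        environmental filter used by the selection regimes; narrower means
        stronger selection.
    dispersal_sd
        Standard deviation of the per-site migrant-pool log-effect under
        dispersal limitation.
    dispersal_range_km
        Elevation-distance scale of migrant-pool decorrelation: site pools
        follow an AR(1) walk along the elevation order with correlation
        ``exp(-Δelev_km / range)``.
    migration_rate
        Fraction (0–1) by which homogenizing dispersal shrinks subject- and
        site-level heterogeneity toward the shared migrant pool.
    drift_size
        Effective community size (individuals) of the per-sample
        demographic lottery under drift and the selection regimes: each
        sample's local community is a multinomial resample of ``drift_size``
        individuals from its expected pool before sequencing, so smaller
        values mean stronger drift (more membership turnover).
    microenv_sd
        Per-sample, per-taxon lognormal microenvironmental noise applied
        under the selection regimes only, so that different close relatives
        of the filtered clade dominate different samples (selection acts on
        membership of the clade, drift on which member wins locally).
    selection_dominance
        Fraction (0–1) by which the selection regimes attenuate regional
        base-abundance differences: under strong selection, local fitness
        rather than regional prevalence sets the within-clade ranking.
    """

    regime: str
    filter_width: float = 0.05
    dispersal_sd: float = 2.5
    dispersal_range_km: float = 0.5
    migration_rate: float = 0.9
    drift_size: int = 50
    microenv_sd: float = 1.0
    selection_dominance: float = 0.7

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one integer seed into independent per-step generators."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


# ---------------------------------------------------------------------------
# Phylogeny simulation


def simulate_phylogeny(n_taxa: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Random pure-birth (Yule) tree with ``n_taxa`` extant tips.

    The tree is ultrametric (all tips contemporaneous), rescaled to unit
    root-to-tip height, tips labelled ``OTU0001`` … in a deterministic
    order. Identical seeds give byte-identical Newick strings.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = random.Random(int(seed))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # unit height for O(1) patristic distances; the stem edge above the root
    # carries no tip-to-tip information and is dropped
    tree.seed_node.edge.length = 0.0
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if height == 0:  # degenerate two-tip start: give the cherry unit height
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = 1.0
    else:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / height
    width = len(str(max(n_taxa, 1)))
    width = max(width, 4)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{i + 1:0{width}d}"
    return Phylogeny(tree)


def _brownian_tip_values(
    dist: np.ndarray, rng: np.random.Generator, conservation_depth: float | None = None
) -> np.ndarray:
    """Draw one Brownian-motion trait at the tips.

    For an ultrametric tree of height T the tip covariance is the shared
    root-to-MRCA path, C = T − D/2 with D the patristic matrix. With
    ``conservation_depth`` t* (a fraction of T), the walk is frozen at depth
    t*·T — the trait is inherited unchanged after that point, so every clade
    younger than t* shares one exact value (phylogenetic niche
    conservatism). Eigenvalues are clipped at zero so slightly
    non-ultrametric inputs stay usable.
    """
    height = dist.max() / 2.0
    cov = height - dist / 2.0
    if conservation_depth is not None:
        cov = np.minimum(cov, conservation_depth * height)
        np.fill_diagonal(cov, conservation_depth * height)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ rng.standard_normal(dist.shape[0])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Planted gradient truth


def simulate_gradient_truth(
    n_taxa: int,
    frac_tolerant: float,
    frac_sensitive: float,
    slope_scale: float,
    phylo: Phylogeny,
    phylo_signal: float = 0.0,
    seed: int = 0,
    base_log_sd: float = 1.5,
    niche_conservation_depth: float = 0.5,
) -> list[TaxonTruth]:
    """Assign planted elevation responses to the first ``n_taxa`` tree tips.

    A latent taxon score mixes an i.i.d. normal component and a standardized
    Brownian-motion tip trait: ``u = (1 − s)·e + s·b`` with ``s =
    phylo_signal``, re-standardized. The ``round(frac_tolerant · n)`` taxa
    with the highest scores (round half up) become tolerant with slope
    ``+slope_scale·(1 + 0.25·(u − threshold))``; the ``round(frac_sensitive
    · n)`` lowest become sensitive with the mirrored negative slope; the
    rest are neutral (slope 0). Slope magnitudes are kept close to
    ``slope_scale`` (≤25% spread per unit score) so planted classes do not
    compete each other out of the compositional denominator; slopes remain
    a monotone function of the latent score, so at ``phylo_signal = 1``
    slope differences increase with patristic distance and selection
    regimes induce phylogenetic clustering.

    Every taxon also receives a tree-correlated ``niche_trait`` used by
    selection regimes as its environmental optimum: a Brownian trait frozen
    at ``niche_conservation_depth`` of the tree height, so clades younger
    than that depth share one exact niche value (conserved niches are what
    let an environmental filter produce phylogenetically clustered
    communities). Base log-abundance is drawn N(0, base_log_sd).
    """
    if not (0 <= frac_tolerant and 0 <= frac_sensitive and frac_tolerant + frac_sensitive <= 1):
        raise ValueError("frac_tolerant + frac_sensitive must lie in [0, 1]")
    if not 0 <= phylo_signal <= 1:
        raise ValueError("phylo_signal must lie in [0, 1]")
    tips = phylo.tip_labels
    if n_taxa > len(tips):
        raise ValueError("n_taxa exceeds number of tree tips")
    taxa = tips[:n_taxa]
    _, dist = phylo.patristic_matrix(taxa)

    rng_iid, rng_bm, rng_niche, rng_base = _spawn_rngs(seed, 4)
    e = rng_iid.standard_normal(n_taxa)
    b = _standardize(_brownian_tip_values(dist, rng_bm))
    u = _standardize((1.0 - phylo_signal) * e + phylo_signal * b)
    niche = _standardize(
        _brownian_tip_values(dist, rng_niche, conservation_depth=niche_conservation_depth)
    )
    base = rng_base.normal(0.0, base_log_sd, n_taxa)

    k_tol = int(np.floor(frac_tolerant * n_taxa + 0.5))
    k_sen = int(np.floor(frac_sensitive * n_taxa + 0.5))
    order = np.argsort(u, kind="stable")
    sensitive_idx = set(order[:k_sen].tolist())
    tolerant_idx = set(order[n_taxa - k_tol:].tolist()) if k_tol else set()

    thr_hi = u[order[n_taxa - k_tol]] if k_tol else np.inf
    thr_lo = u[order[k_sen - 1]] if k_sen else -np.inf

    truths = []
    for i, taxon in enumerate(taxa):
        if i in tolerant_idx:
            cls = "tolerant"
            slope = slope_scale * (1.0 + 0.25 * (u[i] - thr_hi))
        elif i in sensitive_idx:
            cls = "sensitive"
            slope = -slope_scale * (1.0 + 0.25 * (thr_lo - u[i]))
        else:
            cls = "neutral"
            slope = 0.0
        truths.append(TaxonTruth(taxon, cls, float(slope), float(base[i]), float(niche[i])))
    return truths


def write_truth(truths: list[TaxonTruth], path) -> None:
    pd.DataFrame(
        {
            "taxon_id": [t.taxon_id for t in truths],
            "class": [t.taxon_class for t in truths],
            "elevation_slope": [t.elevation_slope for t in truths],
            "base_log_abundance": [t.base_log_abundance for t in truths],
            "niche_trait": [t.niche_trait for t in truths],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth(path) -> list[TaxonTruth]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        TaxonTruth(
            str(r.taxon_id), str(r["class"]), float(r.elevation_slope),
            float(r.base_log_abundance), float(r.niche_trait),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Table simulation


def _metadata_rows(design: GradientDesign, rng: np.random.Generator) -> list[dict]:
    uv_lo, uv_hi = 53.0, 3785.0  # measured UV range across the study's sites
    elevs = np.asarray(design.site_elevations_m, float)
    span = elevs.max() - elevs.min() or 1.0
    rows = []
    for s, elev in enumerate(elevs):
        uv_site = uv_lo + (uv_hi - uv_lo) * (elev - elevs.min()) / span
        for k in range(design.subjects_per_site):
            subject = f"S{s + 1:02d}U{k + 1}"
            gender = "female" if rng.random() < 0.5 else "male"
            age = float(rng.integers(20, 61))
            height = float(np.round(rng.normal(168.0, 8.0), 1))
            weight = float(np.round(rng.normal(65.0, 10.0), 1))
            for body in design.body_sites:
                rows.append(
                    {
                        "sample_id": f"{subject}_{body}",
                        "subject_id": subject,
                        "elevation_m": elev,
                        "body_site": body,
                        "gender": gender,
                        "age": age,
                        "height": height,
                        "weight": weight,
                        "uv_uw_cm2": float(np.round(uv_site * rng.uniform(0.85, 1.15), 1)),
                    }
                )
    return rows


def _gaussian_filter(niche: np.ndarray, optimum: float, width: float) -> np.ndarray:
    return -0.5 * ((niche - optimum) / width) ** 2


def _niche_plateaus(niche: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique conserved-niche values with their taxon counts, largest first.

    Under the frozen-Brownian niche model each distinct value is exactly one
    clade (values are rounded to absorb floating-point reconstruction
    noise), so plateau values double as clade identifiers.
    """
    vals, counts = np.unique(np.round(niche, 6), return_counts=True)
    order = np.argsort(-counts, kind="stable")
    return vals[order], counts[order]


def simulate_table(
    design: GradientDesign,
    truth: list[TaxonTruth],
    regime: AssemblyRegime | str = "drift",
    overdispersion: float = 0.0,
    alpha_decay: float = 0.0,
    beta_inflation: float = 0.0,
    seed: int = 0,
    subject_sd: float = 0.55,
    site_sd: float = 0.15,
) -> tuple[CommunityTable, pd.DataFrame]:
    """Simulate a count table and matching metadata under a planted regime.

    Expected per-sample log-abundance is ``base + slope · elev_km +
    subject effect + site effect`` plus a regime-specific term:

    * ``homogeneous_selection`` — one shared Gaussian environmental filter
      over the niche trait applied to every sample,
    * ``variable_selection`` — site-specific filter optima spread across the
      niche-trait range in elevation order,
    * ``dispersal_limitation`` — a site-level migrant-pool log-effect that
      decorrelates with elevation distance (AR(1) walk),
    * ``homogenizing_dispersal`` — subject/site heterogeneity shrunk by the
      migration rate and one shared occupancy realization for the group,
    * ``drift`` — no extra term; each sample is a finite-size multinomial
      resample of its expected pool (``drift_size`` individuals), i.e. a
      neutral demographic lottery, then sequenced.

    The drift lottery also applies under both selection regimes (selection
    acts on top of demographic drift), which is what makes filtered
    communities turn over among close relatives rather than being identical.

    ``alpha_decay`` is the expected fraction of taxa lost per km of
    elevation above the lowest site (independent per-sample thinning);
    ``beta_inflation`` scales subject-effect variance linearly with
    elevation above the lowest site. ``overdispersion`` θ > 0 draws each
    sample's composition from Dirichlet(p/θ) before the multinomial.
    """
    if isinstance(regime, str):
        regime = AssemblyRegime(regime)
    n_taxa = len(truth)
    if n_taxa == 0:
        raise ValueError("empty truth")
    taxa = [t.taxon_id for t in truth]
    if len(set(taxa)) != n_taxa:
        raise ValueError("duplicate taxa in truth")

    (rng_meta, rng_site, rng_subj, rng_regime, rng_thin,
     rng_depth, rng_dirichlet, rng_counts) = _spawn_rngs(seed, 8)

    meta_rows = _metadata_rows(design, rng_meta)
    metadata = metadata_from_records(meta_rows)
    n_samples = len(meta_rows)

    elevs = np.asarray(design.site_elevations_m, float)
    elev_km = metadata["elevation_m"].to_numpy() / 1000.0
    elev0_km = elevs.min() / 1000.0
    site_of_sample = np.searchsorted(np.sort(elevs), metadata["elevation_m"].to_numpy())
    site_index = {e: i for i, e in enumerate(elevs)}
    site_of_sample = np.array([site_index[e] for e in metadata["elevation_m"]])
    subjects = metadata["subject_id"].to_numpy()
    subj_ids = list(dict.fromkeys(subjects))
    subj_of_sample = np.array([subj_ids.index(s) for s in subjects])

    base = np.array([t.base_log_abundance for t in truth])
    slope = np.array([t.elevation_slope for t in truth])
    niche = np.array([t.niche_trait for t in truth])

    # under strong selection, local fitness supersedes regional prevalence:
    # baseline abundances are attenuated so dominance within the selected
    # clade turns over between samples instead of tracking the same few
    # regionally common members everywhere
    base_scale = (
        1.0 - regime.selection_dominance
        if regime.regime in ("homogeneous_selection", "variable_selection")
        else 1.0
    )
    lam = base_scale * base[None, :] + np.outer(elev_km, slope)

    # site effect (per site × taxon)
    if site_sd > 0:
        site_eff = rng_site.normal(0.0, site_sd, (len(elevs), n_taxa))
    else:
        site_eff = np.zeros((len(elevs), n_taxa))

    # subject effect (per subject × taxon), variance inflated with elevation
    subj_eff = rng_subj.standard_normal((len(subj_ids), n_taxa))
    subj_elev_km = np.array(
        [metadata.loc[metadata["subject_id"] == s, "elevation_m"].iloc[0] / 1000.0
         for s in subj_ids]
    )
    subj_scale = subject_sd * (1.0 + beta_inflation * (subj_elev_km - elev0_km))
    subj_eff = subj_eff * subj_scale[:, None]

    shrink = 1.0
    shared_support = None
    if regime.regime == "homogeneous_selection":
        # shared filter centered on the largest conserved-niche clade
        vals, _ = _niche_plateaus(niche)
        lam += _gaussian_filter(niche, float(vals[0]), regime.filter_width)[None, :]
        lam += rng_regime.normal(0.0, regime.microenv_sd, (n_samples, n_taxa))
    elif regime.regime == "variable_selection":
        # site-specific filters on the largest clades, assigned in niche
        # order along the elevation order (the environment drifts with
        # elevation, selecting progressively different clades)
        vals, _ = _niche_plateaus(niche)
        chosen = np.sort(vals[: len(elevs)])
        for s in range(len(elevs)):
            optimum = float(chosen[s % len(chosen)])
            mask = site_of_sample == s
            lam[mask] += _gaussian_filter(niche, optimum, regime.filter_width)[None, :]
        lam += rng_regime.normal(0.0, regime.microenv_sd, (n_samples, n_taxa))
    elif regime.regime == "dispersal_limitation":
        # AR(1) migrant-pool walk along the elevation order
        order = np.argsort(elevs)
        pools = np.zeros((len(elevs), n_taxa))
        prev = rng_regime.normal(0.0, regime.dispersal_sd, n_taxa)
        pools[order[0]] = prev
        for a, b in zip(order[:-1], order[1:]):
            rho = np.exp(-abs(elevs[b] - elevs[a]) / 1000.0 / regime.dispersal_range_km)
            innov = rng_regime.normal(0.0, regime.dispersal_sd, n_taxa)
            prev = rho * prev + np.sqrt(1.0 - rho**2) * innov
            pools[b] = prev
        lam += pools[site_of_sample]
    elif regime.regime == "homogenizing_dispersal":
        shrink = 1.0 - regime.migration_rate
    # drift: no extra term

    lam += shrink * site_eff[site_of_sample]
    lam += shrink * subj_eff[subj_of_sample]

    # occupancy thinning with elevation
    keep = np.ones((n_samples, n_taxa), bool)
    if alpha_decay > 0:
        p_lost = np.clip(alpha_decay * (elev_km - elev0_km), 0.0, 0.95)
        keep = rng_thin.random((n_samples, n_taxa)) >= p_lost[:, None]
    else:
        # burn the stream so alpha_decay does not shift later draws
        rng_thin.random((n_samples, n_taxa))

    # sequencing depth: lognormal with the study's mean/CV, floored at the
    # rarefaction depth so no simulated sample is dropped at rarefaction
    sigma = np.sqrt(np.log(1.0 + design.depth_cv**2))
    mu = np.log(design.depth_mean) - sigma**2 / 2.0
    depths = np.maximum(
        rng_depth.lognormal(mu, sigma, n_samples).astype(np.int64),
        int(design.rarefaction_depth),
    )

    if regime.regime == "homogenizing_dispersal":
        # one shared occupancy realization: the migrant pool synchronizes
        # which taxa arrive across all samples in the group
        mean_w = np.exp(lam).mean(axis=0)
        mean_p = mean_w / mean_w.sum()
        support_draw = rng_regime.multinomial(int(depths.mean()), mean_p)
        shared_support = support_draw > 0
        keep &= shared_support[None, :]

    lottery = regime.regime in ("drift", "homogeneous_selection", "variable_selection")
    counts = np.zeros((n_samples, n_taxa), np.int64)
    for j in range(n_samples):
        w = np.exp(lam[j]) * keep[j]
        if w.sum() == 0:  # degenerate thinning: keep the single best taxon
            w = np.zeros(n_taxa)
            w[np.argmax(lam[j])] = 1.0
        p = w / w.sum()
        if overdispersion > 0:
            pos = p > 0
            alpha = p[pos] / overdispersion
            p = np.zeros(n_taxa)
            p[pos] = rng_dirichlet.dirichlet(alpha)
        if lottery:
            community = rng_counts.multinomial(int(regime.drift_size), p)
            p = community / community.sum()
        counts[j] = rng_counts.multinomial(depths[j], p)

    table = CommunityTable(
        pd.DataFrame(counts, index=metadata.index.to_list(), columns=taxa)
    )
    return table, metadata


def simulate_dataset(
    design: GradientDesign | None = None,
    n_taxa: int = 500,
    frac_tolerant: float = 0.1,
    frac_sensitive: float = 0.1,
    slope_scale: float = 1.0,
    phylo_signal: float = 0.5,
    regime: AssemblyRegime | str | None = None,
    overdispersion: float = 0.0,
    alpha_decay: float = 0.1,
    beta_inflation: float = 0.3,
    seed: int = 0,
    subject_sd: float = 0.55,
    site_sd: float = 0.15,
):
    """One-call dataset: phylogeny + truth + table + metadata.

    The seed is split into independent children for the tree, the truth,
    and the table, so regenerating any one piece leaves the others fixed.
    The default regime is drift with a large local community
    (``drift_size=2000``): at the full study scale the demographic lottery
    should perturb, not dominate, the planted gradient structure.
    """
    design = design or GradientDesign()
    if regime is None:
        regime = AssemblyRegime("drift", drift_size=2000)
    ss = np.random.SeedSequence(seed).spawn(3)
    tree_seed, truth_seed, table_seed = (
        int(c.generate_state(1, np.uint32)[0] % (2**31)) for c in ss
    )
    phylo = simulate_phylogeny(n_taxa, tree_seed)
    truth = simulate_gradient_truth(
        n_taxa, frac_tolerant, frac_sensitive, slope_scale,
        phylo, phylo_signal, truth_seed,
    )
    table, metadata = simulate_table(
        design, truth, regime, overdispersion, alpha_decay, beta_inflation,
        table_seed, subject_sd=subject_sd, site_sd=site_sd,
    )
    return phylo, truth, table, metadata


def simulate_strong_signal_dataset(seed: int = 0, n_taxa: int = 300):
    """Study-design dataset with a strong, clean planted gradient.

    The condition used to measure planted-class recovery: 10% tolerant and
    10% sensitive taxa with near-uniform slopes of ±0.6 per km, no richness
    thinning, no beta inflation, small host effects, and a weak demographic
    lottery — strong signal, small noise. Returns (phylogeny, truth, table,
    metadata).
    """
    return simulate_dataset(
        n_taxa=n_taxa,
        frac_tolerant=0.1,
        frac_sensitive=0.1,
        slope_scale=0.6,
        phylo_signal=0.0,
        regime=AssemblyRegime("drift", drift_size=5000),
        overdispersion=0.0,
        alpha_decay=0.0,
        beta_inflation=0.0,
        seed=seed,
        subject_sd=0.2,
        site_sd=0.05,
    )


def simulate_regime_group(
    regime: AssemblyRegime | str,
    n_samples: int = 10,
    n_taxa: int = 150,
    depth: int = 2000,
    seed: int = 0,
) -> tuple[CommunityTable, pd.DataFrame, Phylogeny]:
    """A single group of samples generated under one pure assembly regime.

    Samples are one subject × one body site at ``n_samples`` evenly spaced
    pseudo-elevations, with no planted gradient slopes, no host effects and
    no extra overdispersion: the between-sample covariance comes from the
    regime alone (plus multinomial noise), which is what the βNTI/RC_bray
    machinery is supposed to detect.
    """
    if isinstance(regime, str):
        regime = AssemblyRegime(regime)
    design = GradientDesign(
        site_elevations_m=tuple(np.linspace(500.0, 3500.0, n_samples)),
        subjects_per_site=1,
        body_sites=("forehead",),
        depth_mean=float(depth),
        depth_cv=0.05,
        rarefaction_depth=max(2, int(depth * 0.8)),
    )
    ss = np.random.SeedSequence(seed).spawn(3)
    tree_seed, truth_seed, table_seed = (
        int(c.generate_state(1, np.uint32)[0] % (2**31)) for c in ss
    )
    phylo = simulate_phylogeny(n_taxa, tree_seed)
    truth = simulate_gradient_truth(
        n_taxa, 0.0, 0.0, 0.0, phylo, phylo_signal=1.0, seed=truth_seed
    )
    table, metadata = simulate_table(
        design, truth, regime,
        overdispersion=0.0, alpha_decay=0.0, beta_inflation=0.0,
        seed=table_seed, subject_sd=0.0, site_sd=0.0,
    )
    return table, metadata, phylo
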