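"""End-to-end orchestration: simulate/load → rarefy → diversity → gradient
statistics → co-occurrence networks → assembly processes → manifest.

Configuration is a YAML file validated against a typed schema (unknown keys
rejected, strings coerced to numbers with a logged warning). One global
seed is split into per-stage seeds by hashing the stage name (CRC-32 of the
stage name mixed into a ``numpy.random.SeedSequence`` with the global
seed), so disabling or reordering one stage never shifts another stage's
randomness. Every stage writes plain-text artifacts into the output
directory and registers itself in a single JSON manifest; rerunning an
identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import assembly as assembly_mod
from . import core_io, diversity, gradient_stats, network, synthetic_data

logger = logging.getLogger(__name__)

#: default PERMANOVA term order: the gradient first, host factors, then the
#: individual last (subjects are site-nested, so placing subject earlier
#: aliases elevation and the per-subject host covariates)
DEFAULT_PERMANOVA_TERMS = (
    "elevation_m", "gender", "age", "height", "weight", "body_site", "subject_id",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([global_seed, crc32(stage)])."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


class _CoercingModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    @field_validator("*", mode="before")
    @classmethod
    def _warn_on_string_numbers(cls, v, info):
        if isinstance(v, str):
            try:
                coerced = float(v)
            except ValueError:
                return v
            logger.warning("config field %s: coerced string %r to number", info.field_name, v)
            return coerced
        return v


class SimulateConfig(_CoercingModel):
    n_taxa: int = 500
    frac_tolerant: float = 0.1
    frac_sensitive: float = 0.1
    slope_scale: float = 1.0
    phylo_signal: float = 0.5
    regime: str = "drift"
    drift_size: int = 2000
    overdispersion: float = 0.0
    alpha_decay: float = 0.1
    beta_inflation: float = 0.3
    subject_sd: float = 0.55
    site_sd: float = 0.15
    site_elevations_m: tuple[float, ...] = synthetic_data.DEFAULT_SITE_ELEVATIONS_M
    subjects_per_site: int = 5
    body_sites: tuple[str, ...] = core_io.BODY_SITES
    depth_mean: float = 18_525.0

    @field_validator("regime")
    @classmethod
    def _check_regime(cls, v):
        if v not in synthetic_data.REGIMES:
            raise ValueError(f"unknown regime {v!r}")
        return v


class InputConfig(_CoercingModel):
    table: str
    metadata: str
    tree: str | None = None


class NetworkConfig(_CoercingModel):
    min_mean_rel_abund: float = Field(0.0001, ge=0)
    rho_threshold: float = Field(0.77, gt=0, le=1)
    fdr_alpha: float = Field(0.001, gt=0, lt=1)
    signed_edges: bool = True
    degree_min: int = 100
    betweenness_max: float = 5000.0


class AssemblyConfig(_CoercingModel):
    bnti_reps: int = Field(999, ge=1)
    rc_reps: int = Field(999, ge=1)
    bnti_upper: float = 2.0
    bnti_lower: float = -2.0
    rc_upper: float = 0.95
    rc_lower: float = -0.95


class PipelineConfig(_CoercingModel):
    seed: int = 0
    rarefaction_depth: int = Field(15_596, ge=1)
    shannon_base: float = Field(2.0, gt=1)
    elevation_cutoff_m: float = 3000.0
    mean_abund_floor: float = 0.0009
    classify_alpha: float = 0.05
    permanova_permutations: int = Field(999, ge=1)
    permanova_terms: tuple[str, ...] = DEFAULT_PERMANOVA_TERMS
    simulate: SimulateConfig | None = None
    inputs: InputConfig | None = None
    network: NetworkConfig = NetworkConfig()
    assembly: AssemblyConfig = AssemblyConfig()

    def model_post_init(self, __context) -> None:
        if self.simulate is None and self.inputs is None:
            object.__setattr__(self, "simulate", SimulateConfig())


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def validate_config(path_or_dict) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        if hasattr(exc, "errors"):
            msgs = [
                f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
            ]
            raise ConfigError(msgs) from exc
        raise


# ---------------------------------------------------------------------------
# Stages


def _load_or_simulate(config: PipelineConfig, outdir: Path):
    if config.inputs is not None:
        table = core_io.read_community_table(config.inputs.table)
        metadata = core_io.read_metadata(config.inputs.metadata)
        phylo = core_io.read_newick(config.inputs.tree) if config.inputs.tree else None
        truth = None
    else:
        sim = config.simulate
        design = synthetic_data.GradientDesign(
            site_elevations_m=tuple(sim.site_elevations_m),
            subjects_per_site=int(sim.subjects_per_site),
            body_sites=tuple(sim.body_sites),
            depth_mean=float(sim.depth_mean),
            rarefaction_depth=min(config.rarefaction_depth, int(sim.depth_mean)),
        )
        phylo, truth, table, metadata = synthetic_data.simulate_dataset(
            design=design,
            n_taxa=int(sim.n_taxa),
            frac_tolerant=sim.frac_tolerant,
            frac_sensitive=sim.frac_sensitive,
            slope_scale=sim.slope_scale,
            phylo_signal=sim.phylo_signal,
            regime=synthetic_data.AssemblyRegime(sim.regime, drift_size=int(sim.drift_size)),
            overdispersion=sim.overdispersion,
            alpha_decay=sim.alpha_decay,
            beta_inflation=sim.beta_inflation,
            seed=stage_seed(config.seed, "simulate"),
            subject_sd=sim.subject_sd,
            site_sd=sim.site_sd,
        )
        core_io.write_community_table(table, outdir / "table.tsv")
        core_io.write_metadata(metadata, outdir / "metadata.tsv")
        core_io.write_newick(phylo, outdir / "tree.nwk")
        synthetic_data.write_truth(truth, outdir / "truth.tsv")
    return table, metadata, phylo, truth


def run_pipeline(
    config: PipelineConfig,
    outdir,
    stages: tuple[str, ...] = ("diversity", "gradient", "network", "assembly"),
) -> dict:
    """Run the analysis end to end; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "stages": {},
    }
    if "assembly" in stages and config.inputs is not None and config.inputs.tree is None:
        raise ConfigError(["assembly stage requires a tree input"])

    table, metadata, phylo, truth = _load_or_simulate(config, outdir)
    manifest["stages"]["inputs"] = {
        "n_samples": len(table.sample_ids),
        "n_taxa": len(table.taxon_ids),
        "simulated": config.inputs is None,
    }

    rare = diversity.rarefy(
        table, config.rarefaction_depth, seed=stage_seed(config.seed, "rarefy")
    )
    manifest["stages"]["rarefy"] = {
        "depth": config.rarefaction_depth,
        "n_samples_retained": len(rare.sample_ids),
    }
    groups = core_io.assign_elevation_groups(metadata, config.elevation_cutoff_m)
    meta = metadata.loc[rare.sample_ids]
    six_groups = {
        sid: f"{groups[sid]}_{meta.loc[sid, 'body_site']}" for sid in rare.sample_ids
    }

    if "diversity" in stages:
        alpha = diversity.alpha_diversity(rare, base=config.shannon_base)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index=False)
        bray = diversity.bray_curtis_matrix(rare)
        jac = diversity.jaccard_matrix(rare)
        bray.to_tsv(outdir / "bray_curtis.tsv")
        jac.to_tsv(outdir / "jaccard.tsv")
        elev = meta["elevation_m"].to_numpy(float)
        trends = {
            "observed_otus_vs_elevation": vars(
                gradient_stats.fit_trend(alpha["observed_otus"], elev)
            ),
            "shannon_vs_elevation": vars(gradient_stats.fit_trend(alpha["shannon"], elev)),
            "within_site_bray_curtis_vs_elevation": vars(
                gradient_stats.within_group_dissimilarity_trend(bray, meta)
            ),
            "within_site_jaccard_vs_elevation": vars(
                gradient_stats.within_group_dissimilarity_trend(jac, meta)
            ),
        }
        with open(outdir / "diversity_trends.json", "w") as fh:
            json.dump(trends, fh, indent=2)
        manifest["stages"]["diversity"] = {
            "n_alpha_records": len(alpha),
            "trends": {k: v["slope"] for k, v in trends.items()},
        }
    else:
        bray = diversity.bray_curtis_matrix(rare)

    if "gradient" in stages:
        g_seed = stage_seed(config.seed, "gradient")
        classes = gradient_stats.classify_elevation_response(
            rare, meta, config.mean_abund_floor, config.classify_alpha
        )
        gradient_stats.classification_frame(classes).to_csv(
            outdir / "taxon_classification.tsv", sep="\t", index=False
        )
        jac = diversity.jaccard_matrix(rare)
        perm_results = {}
        for name, dm in (("bray_curtis", bray), ("jaccard", jac)):
            res = gradient_stats.permanova(
                dm, meta, list(config.permanova_terms),
                permutations=config.permanova_permutations, seed=g_seed,
            )
            perm_results[name] = gradient_stats.permanova_frame(res)
        pd.concat(
            [df.assign(metric=name) for name, df in perm_results.items()]
        ).to_csv(outdir / "permanova.tsv", sep="\t", index=False)

        r_anosim, p_anosim = gradient_stats.anosim(
            bray, [groups[s] for s in bray.ids],
            permutations=config.permanova_permutations, seed=g_seed,
        )
        d_elev, d_host = gradient_stats.elevation_factor_matrices(meta, bray.ids)
        r_mantel, p_mantel = gradient_stats.partial_mantel(
            bray, d_elev, d_host,
            permutations=config.permanova_permutations, seed=g_seed,
        )
        summary = {
            "anosim_high_vs_low": {"r": r_anosim, "p": p_anosim},
            "partial_mantel_elevation_controlling_host": {"r": r_mantel, "p": p_mantel},
            "n_tolerant": sum(c.taxon_class == "tolerant" for c in classes),
            "n_sensitive": sum(c.taxon_class == "sensitive" for c in classes),
            "n_tested": len(classes),
        }
        with open(outdir / "gradient_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest["stages"]["gradient"] = summary

    if "network" in stages:
        params = network.NetworkParameters(
            min_mean_rel_abund=config.network.min_mean_rel_abund,
            rho_threshold=config.network.rho_threshold,
            fdr_alpha=config.network.fdr_alpha,
            signed_edges=config.network.signed_edges,
        )
        filtered = network.filter_rare_taxa(rare, params.min_mean_rel_abund)
        edges = network.spearman_edge_screen(filtered, params)
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        meta_net = network.build_network(edges)
        net_stats = {}
        node_frames = []
        keystones = {}
        for label in sorted(set(six_groups.values())):
            members = [s for s, g in six_groups.items() if g == label]
            sub = network.induce_subnetwork(meta_net, filtered, members, label)
            if sub.number_of_nodes() < 2:
                logger.warning("subnetwork %r too small; skipped", label)
                continue
            nm = network.node_metrics(sub)
            node_frames.append(network.node_metrics_frame(nm).assign(group=label))
            net_stats[label] = vars(network.network_metrics(sub))
            keystones[label] = network.keystone_species(
                nm, config.network.degree_min, config.network.betweenness_max
            )
        if node_frames:
            pd.concat(node_frames).to_csv(outdir / "node_metrics.tsv", sep="\t", index=False)
        with open(outdir / "network_metrics.json", "w") as fh:
            json.dump({"groups": net_stats, "keystones": keystones}, fh, indent=2)
        manifest["stages"]["network"] = {
            "meta_nodes": meta_net.number_of_nodes(),
            "meta_edges": meta_net.number_of_edges(),
            "subnetworks": {k: {"nodes": v["nodes"], "edges": v["edges"]}
                            for k, v in net_stats.items()},
        }

    if "assembly" in stages:
        if phylo is None:
            raise ConfigError(["assembly stage requires a tree"])
        a_params = assembly_mod.AssemblyParameters(
            bnti_reps=config.assembly.bnti_reps,
            rc_reps=config.assembly.rc_reps,
            bnti_upper=config.assembly.bnti_upper,
            bnti_lower=config.assembly.bnti_lower,
            rc_upper=config.assembly.rc_upper,
            rc_lower=config.assembly.rc_lower,
            seed=stage_seed(config.seed, "assembly"),
        )
        pairs, fracs = assembly_mod.group_assembly(rare, phylo, six_groups, a_params)
        pairs.to_csv(outdir / "assembly_pairs.tsv", sep="\t", index=False)
        frame = assembly_mod.fractions_frame(fracs)
        frame.to_json(outdir / "assembly_fractions.json", orient="records", indent=2)
        manifest["stages"]["assembly"] = {
            "n_pairs": len(pairs),
            "groups": {f.group_label: f.stochastic_fraction for f in fracs},
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
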