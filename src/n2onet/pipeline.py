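"""End-to-end orchestration: simulate/ingest -> preprocess -> network ->
topology -> stability -> ecostats -> drivers, with a machine-readable report.

One global seed deterministically derives per-stage seeds, so identical
config + seed gives byte-identical JSON reports. Every threshold that
affected edge calling is recorded in the report's provenance block.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecostats, io, netinfer, preprocess, stability, synthetic, topology
from .datatypes import ConfigurationError, ConsistencyError, CountTable, N2OMeasurements
from .drivers import composite_index, permutation_significance

logger = logging.getLogger("n2onet")

_STAGES = (
    "simulate",
    "preprocess",
    "network",
    "topology",
    "stability",
    "ecostats",
    "drivers",
)


@dataclass
class RunConfig:
    """All pipeline parameters; unknown keys in a config file are rejected."""

    simulate: str | None = "paper_mimic"  # preset name, or None to load inputs
    input_dir: str | None = None
    kingdoms: tuple[str, ...] = ("bacteria", "fungi")
    out_dir: str = "n2onet_out"
    seed: int = 0
    # preprocess
    min_rel_abund: float = 0.0001
    min_prevalence: int = 2
    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    # network
    rho_min: float = 0.7
    p_max: float = 0.05
    # topology
    zi_threshold: float = 2.5
    min_module_size: int = 3  # modules this small are background singletons
    # stability
    robustness_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    robustness_reps: int = 100
    robustness_at: float = 0.5
    cohesion_null_iters: int = 0
    # ecostats
    anosim_perms: int = 999
    # drivers
    rf_trees: int = 500
    rf_perms: int = 199

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kingdoms", "robustness_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def _load_inputs(cfg: RunConfig):
    """Load or simulate the per-kingdom count tables plus shared N2O/env."""
    if cfg.simulate is not None:
        if cfg.simulate == "paper_mimic":
            make = synthetic.paper_mimic_config
        elif cfg.simulate == "power":
            make = synthetic.power_config
        else:
            raise ConfigurationError(f"unknown simulate preset: {cfg.simulate!r}")
        paired = synthetic.generate_paired(
            make("bacteria"), make("fungi"), seed=_stage_seeds(cfg.seed)["simulate"]
        )
        tables = {k: paired[k][0] for k in ("bacteria", "fungi") if k in cfg.kingdoms}
        truths = {k: paired[k][1] for k in ("bacteria", "fungi") if k in cfg.kingdoms}
        return tables, paired["n2o"], paired["env"], truths
    if cfg.input_dir is None:
        raise ConfigurationError("either simulate preset or input_dir is required")
    root = Path(cfg.input_dir)
    tables = {}
    for k in cfg.kingdoms:
        counts = root / f"{k}_counts.tsv"
        if not counts.exists():
            raise FileNotFoundError(f"missing input file: {counts}")
        tables[k] = io.read_counts(counts, root / "metadata.tsv", kingdom=k)
    n2o = io.read_n2o(root / "n2o.tsv")
    env_path = root / "env.tsv"
    env = pd.read_csv(env_path, sep="\t", index_col=0) if env_path.exists() else None
    for k, t in tables.items():
        missing = [s for s in t.samples if s not in n2o.rates.index]
        if missing:
            raise ConsistencyError(
                f"N2O rates missing for {k} samples: {missing}"
            )
    return tables, n2o, env, {}


def run_all(cfg: RunConfig, write_outputs: bool = True) -> dict:
    """Execute every stage for every kingdom and return the run report."""
    seeds = _stage_seeds(cfg.seed)
    tables, n2o, env, truths = _load_inputs(cfg)
    out = Path(cfg.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "provenance": {
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "rho_min": cfg.rho_min,
            "p_max": cfg.p_max,
            "min_rel_abund": cfg.min_rel_abund,
            "min_prevalence": cfg.min_prevalence,
            "zi_threshold": cfg.zi_threshold,
            "robustness": {
                "fractions": list(cfg.robustness_fractions),
                "reps": cfg.robustness_reps,
                "at": cfg.robustness_at,
            },
            "rf": {"n_trees": cfg.rf_trees, "n_perm": cfg.rf_perms},
            "simulate": cfg.simulate,
        },
        "warnings": [],
        "kingdoms": {},
    }

    diversity_blocks: dict[str, pd.DataFrame] = {}
    network_feature_blocks: dict[str, pd.DataFrame] = {}
    module_blocks: dict[str, pd.DataFrame] = {}

    for kingdom, table in tables.items():
        kb = _run_kingdom(cfg, kingdom, table, n2o, seeds, report["warnings"],
                          out if write_outputs else None)
        report["kingdoms"][kingdom] = kb["report"]
        diversity_blocks[kingdom] = kb["diversity"]
        network_feature_blocks[kingdom] = kb["sample_features"]
        module_blocks[kingdom] = kb["module_abund"]

    # shared N2O statistics
    any_table = next(iter(tables.values()))
    treatments = any_table.treatments
    y = n2o.aligned_to(any_table.samples)
    anova = ecostats.anova_lsd(y, treatments.to_numpy())
    report["n2o"] = {
        "rates": n2o.rates,
        "treatment_means": {
            t: float(np.mean(y[treatments.to_numpy() == t]))
            for t in dict.fromkeys(treatments)
        },
        "anova": {
            "F": anova.f_stat,
            "p": anova.p_value,
            "letters": anova.letters,
            "degenerate": anova.degenerate,
        },
    }

    report["drivers"] = _run_drivers(
        cfg, tables, n2o, env, diversity_blocks, network_feature_blocks,
        module_blocks, seeds["drivers"], report["warnings"],
    )

    if write_outputs:
        io.write_json(report, out / "report.json")
    return report


def _run_kingdom(cfg, kingdom, table, n2o, seeds, warnings_list, out_dir):
    logger.info("processing kingdom %s (%d taxa)", kingdom, len(table.taxa))
    filtered = preprocess.filter_low_abundance(
        table, cfg.min_rel_abund, cfg.min_prevalence
    )
    norm = preprocess.normalize(filtered, cfg.logratio_trim, cfg.abs_trim)
    zmat, flat = preprocess.zscore(norm.rel_abund)
    if flat:
        warnings_list.append(f"{kingdom}: zero-variance taxa z-scored to 0: {len(flat)}")

    corr = netinfer.spearman_matrix(norm)
    net = netinfer.threshold_network(corr, cfg.rho_min, cfg.p_max)

    summary = topology.topology_summary(net)
    treatments = list(dict.fromkeys(table.treatments))
    treat_summaries = {}
    treat_nets = {}
    for t in treatments:
        sub = netinfer.treatment_subnetwork(net, filtered, t)
        treat_nets[t] = sub
        treat_summaries[t] = topology.topology_summary(sub).as_dict()
    sample_rows = {}
    for s in filtered.samples:
        sub = netinfer.sample_subnetwork(net, filtered, s)
        sample_rows[s] = topology.topology_summary(sub).as_dict()
    sample_topology = pd.DataFrame.from_dict(sample_rows, orient="index")

    part = None
    keystones = None
    module_regs = {}
    primary_modules: list[int] = []
    if net.number_of_edges() > 0:
        part = topology.detect_modules(net, seed=seeds["topology"])
        keystones = topology.within_module_degree_z(net, part, cfg.zi_threshold)
        primary_modules = [
            m for m in part.modules if len(part.members(m)) >= cfg.min_module_size
        ]
        module_regs = {
            m: r
            for m, r in ecostats.module_abundance_regression(zmat, part, n2o).items()
            if m in primary_modules
        }

    rob = stability.robustness_curve(
        net,
        fractions=cfg.robustness_fractions,
        reps=cfg.robustness_reps,
        seed=seeds["stability"],
    )
    rob_tests = {}
    for i, ta in enumerate(treatments):
        for tb in treatments[i + 1 :]:
            na, nb = treat_nets[ta], treat_nets[tb]
            if na.number_of_nodes() < 2 or nb.number_of_nodes() < 2:
                continue
            ra = stability.robustness_curve(
                na, cfg.robustness_fractions, cfg.robustness_reps,
                seed=seeds["stability"] + 1,
            )
            rb = stability.robustness_curve(
                nb, cfg.robustness_fractions, cfg.robustness_reps,
                seed=seeds["stability"] + 2,
            )
            t_stat, df, p, degen = stability.compare_robustness(
                ra, rb, cfg.robustness_at
            )
            rob_tests[f"{ta}_vs_{tb}"] = {"t": t_stat, "df": df, "p": p,
                                          "degenerate": degen}
    coh = stability.cohesion(
        norm, corr, null_iters=cfg.cohesion_null_iters, seed=seeds["stability"]
    )

    diversity = ecostats.alpha_diversity(filtered)
    breadth = {
        t: ecostats.levins_breadth(filtered, t).community_mean for t in treatments
    }
    dist = ecostats.bray_curtis(norm)
    r_anosim, p_anosim = ecostats.anosim(
        dist, table.treatments.to_numpy(), n_perm=cfg.anosim_perms,
        seed=seeds["ecostats"],
    )

    features = sample_topology.copy()
    features["pos_cohesion"] = coh.pos_cohesion
    features["neg_cohesion"] = coh.neg_cohesion
    features = features.replace([np.inf, -np.inf], np.nan)
    screen = ecostats.pearson_screen(features, n2o)

    module_abund = pd.DataFrame(index=pd.Index(filtered.samples))
    if part is not None:
        for m in primary_modules:
            taxa = [t for t in part.members(m) if t in zmat.index]
            if taxa:
                module_abund[f"{kingdom}_module_{m}"] = zmat.loc[taxa].mean(axis=0)

    if out_dir is not None:
        io.write_network(
            net, out_dir / f"{kingdom}_network.graphml",
            out_dir / f"{kingdom}_edges.tsv",
        )
        diversity.to_csv(out_dir / f"{kingdom}_diversity.tsv", sep="\t")
        sample_topology.to_csv(out_dir / f"{kingdom}_sample_topology.tsv", sep="\t")
        pd.DataFrame(
            {"pos_cohesion": coh.pos_cohesion, "neg_cohesion": coh.neg_cohesion}
        ).to_csv(out_dir / f"{kingdom}_cohesion.tsv", sep="\t")

    rep = {
        "n_taxa_input": len(table.taxa),
        "n_taxa_filtered": len(filtered.taxa),
        "tmm_factors": norm.tmm_factor,
        "topology": summary.as_dict(),
        "treatment_topology": treat_summaries,
        "modularity": None if part is None else {
            "Q": part.modularity_q,
            "n_modules": len(part.modules),
            "module_sizes": {m: len(part.members(m)) for m in part.modules},
        },
        "keystones": None if keystones is None else {
            "taxa": keystones.keystones,
            "zi_threshold": keystones.zi_threshold,
        },
        "module_regressions": {
            m: dataclasses.asdict(r) for m, r in module_regs.items()
        },
        "robustness": {
            "fractions": rob.fractions,
            "mean": rob.mean(),
            "sd": rob.sd(),
            "treatment_tests": rob_tests,
        },
        "cohesion": {
            "pos": coh.pos_cohesion,
            "neg": coh.neg_cohesion,
        },
        "diversity_mean": diversity.mean(axis=0),
        "niche_breadth": breadth,
        "anosim": {"R": r_anosim, "p": p_anosim},
        "pearson_screen": screen.drop(columns=["excluded"]),
    }
    return {
        "report": rep,
        "diversity": diversity,
        "sample_features": features,
        "module_abund": module_abund,
    }


def _run_drivers(cfg, tables, n2o, env, diversity_blocks, network_blocks,
                 module_blocks, seed, warnings_list) -> dict:
    any_table = next(iter(tables.values()))
    samples = any_table.samples
    predictors = pd.DataFrame(index=pd.Index(samples))
    composites = {}

    def add_composite(name, block):
        block = block.loc[samples]
        try:
            ci = composite_index(block, name=name)
        except ValueError as exc:
            warnings_list.append(f"composite {name} skipped: {exc}")
            return
        predictors[name] = ci.scores
        composites[name] = {
            "variance_explained": ci.variance_explained,
            "loadings": ci.loadings,
        }

    if env is not None:
        add_composite("soil_properties", env)
    for kingdom, block in diversity_blocks.items():
        add_composite(f"{kingdom}_diversity", block)
    for kingdom, block in network_blocks.items():
        clean = block.dropna(axis=1)
        add_composite(f"{kingdom}_network", clean)
    for kingdom, block in module_blocks.items():
        for col in block.columns:
            predictors[col] = block[col]

    y = n2o.aligned_to(samples)
    result = permutation_significance(
        predictors, y, n_perm=cfg.rf_perms, n_trees=cfg.rf_trees, seed=seed
    )
    table = result.table()
    return {
        "composites": composites,
        "importance": table,
        "model_r2": result.model_r2,
        "model_p": result.model_p,
        "top_predictor": str(table.index[0]),
    }


def simulate_to_dir(preset: str, out_dir, seed: int) -> None:
    """Write a simulated dataset (both kingdoms) as the pipeline's input files."""
    if preset == "paper_mimic":
        make = synthetic.paper_mimic_config
    elif preset == "power":
        make = synthetic.power_config
    else:
        raise ConfigurationError(f"unknown preset: {preset!r}")
    paired = synthetic.generate_paired(make("bacteria"), make("fungi"), seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for kingdom in ("bacteria", "fungi"):
        table, truth = paired[kingdom]
        io.write_counts(table, out / f"{kingdom}_counts.tsv")
        io.write_json(
            {
                "true_partition": truth.true_partition,
                "true_effect_signs": truth.true_effect_signs,
                "generator_seed": truth.generator_seed,
            },
            out / f"{kingdom}_ground_truth.json",
        )
        tree = synthetic.generate_tree(table.taxa, seed=seed + 1)
        (out / f"{kingdom}_tree.nwk").write_text(tree + "\n")
    io.write_metadata(paired["bacteria"][0], out / "metadata.tsv")
    io.write_n2o(paired["n2o"], out / "n2o.tsv")
    paired["env"].rename_axis("sample_id").to_csv(out / "env.tsv", sep="\t")
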