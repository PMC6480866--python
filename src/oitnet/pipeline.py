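"""End-to-end orchestration of the Bayesian-network and topological tracks.

Both workflows share the same preprocessing discipline: min-max
normalization of relative features within each experiment, pooling of
experiments on the intersection of their panels, and (for the network
track) mutual-information-preserving discretization whose breakpoints
travel with the trained model so that transfer evaluation on a second
allergy model reuses the training bins.

Every run is fully seeded and writes a manifest (config hash, seed,
package version, row/feature counts after each filtering stage) so that
artifacts are byte-reproducible from the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from oitnet import tda as tda_mod
from oitnet.bayesnet import (
    ExpertDAG,
    default_dag,
    default_scenarios,
    fit_cpts,
    hand_till_auc,
    predict_posterior,
    scenario_table,
)
from oitnet.errors import ConfigurationError
from oitnet.preprocess import (
    VariableSpec,
    hartemink_discretize,
    minmax_normalize,
    pool_and_merge,
)
from oitnet.synthetic_data import StudyCollection

logger = logging.getLogger("oitnet")

FLAG_NODES = ("sensitized", "diet", "oit")
_FLAG_LABELS = {0: "no", 1: "yes"}


def _write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2, default=str)
        fh.write("\n")


def _config_hash(params: Mapping) -> str:
    canon = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _manifest(outdir: Path, params: Mapping, stages: Mapping) -> None:
    from oitnet import __version__

    _write_json(
        {
            "config_hash": _config_hash(params),
            "params": dict(params),
            "stages": dict(stages),
            "oitnet_version": __version__,
        },
        outdir / "manifest.json",
    )


def _normalize_and_pool(
    study: StudyCollection,
    specs: Mapping[str, VariableSpec],
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-experiment min-max normalization followed by intersection pooling."""
    tables = {}
    for exp in study.experiments:
        data = exp.data
        if columns is not None:
            present = [c for c in columns if c in data.columns]
            data = data[present]
        tables[exp.experiment_id] = minmax_normalize(data, specs)
    return pool_and_merge(tables)


def _flags_frame(study: StudyCollection) -> pd.DataFrame:
    meta = study.metadata()
    out = pd.DataFrame(index=meta.index)
    for flag in FLAG_NODES:
        out[flag] = meta[flag].map(_FLAG_LABELS)
    return out


def run_bn_workflow(
    study: StudyCollection,
    transfer_study: StudyCollection | None = None,
    dag: ExpertDAG | None = None,
    target: str = "mMCP1",
    levels: int = 3,
    initial_levels: int = 10,
    alpha: float = 0.0,
    scenarios: Mapping[str, Mapping[str, str]] | None = None,
    outdir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Train, interrogate and evaluate the discrete Bayesian network.

    Pipeline: normalize (per experiment) -> pool -> discretize (Hartemink)
    -> fit CPTs by maximum likelihood -> what-if scenario table ->
    per-sample posterior prediction of the target -> Hand-Till multiclass
    AUC (internal). When ``transfer_study`` is supplied, its pooled data
    are discretized with the *training* DiscretizationMap (a trained
    network's thresholds travel with it) and scored the same way
    (transfer AUC).

    Returns a dict with the fitted network, discretization map, scenario
    report, AUCs and the discrete training table; writes CSV/JSON/YAML
    artifacts plus a manifest when ``outdir`` is given.
    """
    dag = dag if dag is not None else default_dag()
    if target not in dag.levels:
        raise ConfigurationError(f"target {target!r} is not a node of the DAG")
    markers = [n for n in dag.nodes if n not in FLAG_NODES]
    if not markers:
        raise ConfigurationError("DAG declares no marker nodes")

    specs = study.variable_specs
    stages: dict[str, object] = {}
    for exp in study.experiments:
        missing = [m for m in markers if m not in exp.data.columns]
        if missing:
            raise ConfigurationError(
                f"experiment {exp.experiment_id!r} lacks DAG marker feature(s) "
                f"{missing}; the network track refuses to run without them"
            )

    pooled = _normalize_and_pool(study, specs, columns=markers)
    stages["pooled_rows"] = int(len(pooled))
    stages["pooled_markers"] = len(markers)
    logger.info("pooled %d rows x %d marker features", len(pooled), len(markers))

    discrete, dmap = hartemink_discretize(
        pooled, levels=levels, initial_levels=initial_levels, columns=markers
    )
    train = discrete[markers].join(_flags_frame(study))
    train_nodes = train[list(dag.nodes)]
    net = fit_cpts(dag, train_nodes, alpha=alpha)
    report = scenario_table(net, scenarios or default_scenarios())

    evidence_cols = [n for n in dag.nodes if n != target]
    posts = predict_posterior(net, target, train_nodes[evidence_cols])
    internal_auc = hand_till_auc(train_nodes[target], posts)
    stages["internal_auc_rows"] = int(len(posts))

    transfer_auc = None
    if transfer_study is not None:
        for exp in transfer_study.experiments:
            missing = [m for m in markers if m not in exp.data.columns]
            if missing:
                raise ConfigurationError(
                    f"transfer experiment {exp.experiment_id!r} lacks DAG "
                    f"marker feature(s) {missing}"
                )
        t_pooled = _normalize_and_pool(
            transfer_study, transfer_study.variable_specs, columns=markers
        )
        t_discrete = dmap.apply(t_pooled)
        t_table = t_discrete[markers].join(_flags_frame(transfer_study))
        t_nodes = t_table[list(dag.nodes)]
        t_posts = predict_posterior(net, target, t_nodes[evidence_cols])
        transfer_auc = hand_till_auc(t_nodes[target], t_posts, skip_missing=True)
        stages["transfer_rows"] = int(len(t_posts))

    result = {
        "bn": net,
        "discretization": dmap,
        "scenario_report": report,
        "internal_auc": float(internal_auc),
        "transfer_auc": None if transfer_auc is None else float(transfer_auc),
        "train_table": train_nodes,
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        net.to_json(out / "model.json")
        dmap.to_yaml(out / "discretization.yaml")
        report.to_csv(out / "scenario_report.csv")
        report.to_json(out / "scenario_report.json")
        _write_json(
            {
                "target": target,
                "internal_auc": round(float(internal_auc), 6),
                "transfer_auc": (None if transfer_auc is None
                                 else round(float(transfer_auc), 6)),
            },
            out / "auc.json",
        )
        params = {
            "workflow": "bn", "target": target, "levels": levels,
            "initial_levels": initial_levels, "alpha": alpha, "seed": seed,
            "dag_nodes": list(dag.nodes), "dag_edges": [list(e) for e in dag.edges],
        }
        _manifest(out, params, stages)
    return result


def run_tda_workflow(
    study: StudyCollection,
    clinical: Sequence[str] | None = None,
    k: int | str = "auto",
    similarity: str = "signed",
    resolution: float = 1.0,
    seed: int = 0,
    outdir: str | Path | None = None,
    min_features: int = 3,
) -> dict:
    """Build, cluster, and interrogate the mutual-kNN feature network.

    Pipeline: normalize (per experiment) -> pool and merge on the feature
    intersection -> Spearman similarity -> k = ceil(ln n) (or a fixed k) ->
    mutual kNN graph -> multilevel modularity clusters -> distance-based
    prioritization against the clinical features.
    """
    specs = study.variable_specs
    if clinical is None:
        clinical = [n for n, s in specs.items() if s.clinical]
    clinical = list(clinical)
    if not clinical:
        raise ConfigurationError("clinical feature list is empty")

    stages: dict[str, object] = {}
    pooled = _normalize_and_pool(study, specs)
    feature_cols = [c for c in pooled.columns if c != "experiment_id"]
    stages["pooled_rows"] = int(len(pooled))
    stages["merged_features"] = len(feature_cols)
    logger.info("pooled %d rows, %d merged features", len(pooled), len(feature_cols))
    if len(feature_cols) < min_features:
        raise ConfigurationError(
            f"only {len(feature_cols)} features survive the merge; "
            f"need at least {min_features}"
        )

    sim = tda_mod.spearman_adjacency(pooled[feature_cols])
    k_used = tda_mod.choose_k(sim.n_samples) if k == "auto" else int(k)
    stages["k"] = k_used
    logger.info("mutual kNN with k=%d over %d features", k_used, len(sim.features))

    graph = tda_mod.mutual_knn_graph(sim, k_used, similarity=similarity)
    graph = tda_mod.louvain_partition(graph, seed=seed, resolution=resolution)
    report = tda_mod.prioritize_features(graph, clinical)
    stages["n_clusters"] = int(report.clusters.shape[0])

    result = {
        "pooled": pooled,
        "similarity": sim,
        "graph": graph,
        "report": report,
        "k": k_used,
    }

    if outdir is not None:
        import networkx as nx

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(graph, out / "feature_graph.graphml")
        with open(out / "edges.tsv", "w") as fh:
            fh.write("source\ttarget\n")
            for u, v in sorted(graph.edges):
                fh.write(f"{u}\t{v}\n")
        report.features[["cluster"]].to_csv(out / "clusters.csv")
        report.to_csv(out / "prioritization.csv")
        report.to_json(out / "prioritization.json")
        params = {
            "workflow": "tda", "k": k_used, "similarity": similarity,
            "resolution": resolution, "seed": seed, "clinical": sorted(clinical),
        }
        _manifest(out, params, stages)
    return result


@dataclass
class RunConfig:
    """Declarative run configuration (YAML-loadable).

    Either ``study_dir`` (a directory written by
    :func:`oitnet.synthetic_data.write_study`) or ``simulation`` (a
    generator configuration plus sample sizes) must identify the training
    study; ``transfer`` may identify a second study the same way.
    """

    study_dir: str | None = None
    simulation: dict | None = None
    transfer_study_dir: str | None = None
    transfer_simulation: dict | None = None
    dag_file: str | None = None
    target: str = "mMCP1"
    clinical: list[str] = field(default_factory=list)
    levels: int = 3
    initial_levels: int = 10
    alpha: float = 0.0
    k: int | str = "auto"
    similarity: str = "signed"
    resolution: float = 1.0
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def _load(self, study_dir, simulation) -> StudyCollection | None:
        from oitnet.synthetic_data import (
            build_ground_truth,
            cma_config,
            pna_config,
            read_study,
            simulate_study,
        )

        if study_dir is not None:
            return read_study(study_dir)
        if simulation is None:
            return None
        sim = dict(simulation)
        flavour = sim.pop("model", None)
        if isinstance(flavour, str):
            base = {"cma": cma_config, "pna": pna_config}.get(flavour.lower())
            if base is None:
                raise ConfigurationError(f"unknown builtin model {flavour!r}")
            config = base()
        elif isinstance(flavour, Mapping):
            config = dict(flavour)
        else:
            raise ConfigurationError("simulation requires a 'model' entry")
        truth = build_ground_truth(config)
        return simulate_study(
            truth,
            n_per_arm=int(sim.get("n_per_arm", 6)),
            n_experiments=sim.get("n_experiments"),
            seed=int(sim.get("seed", self.seed)),
        )

    def load_study(self) -> StudyCollection:
        study = self._load(self.study_dir, self.simulation)
        if study is None:
            raise ConfigurationError("config identifies no training study")
        return study

    def load_transfer_study(self) -> StudyCollection | None:
        return self._load(self.transfer_study_dir, self.transfer_simulation)

    def load_dag(self) -> ExpertDAG:
        if self.dag_file is None:
            return default_dag()
        with open(self.dag_file) as fh:
            return ExpertDAG.from_dict(yaml.safe_load(fh))
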