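"""Synthetic oral-immunotherapy study generator with ground-truth oracles.

The generator emulates the statistical structure of murine OIT experiments
in the cow's-milk (CMA) and peanut (PNA) allergy models: five treatment
arms (sham, sensitized, FOS diet, OIT, OIT+FOS), immune markers organized
in correlated latent blocks (clinical, antibody, SCFA, cytokine, cell
phenotype), log-normal positive-skewed assay scales, an absolute-scale body
temperature around 37 deg C with an anaphylaxis-conditional drop,
per-experiment multiplicative batch scaling on relative features, and
partially overlapping feature panels between experiments and models.

Each feature loads on its block's latent factor; blocks are coupled through
a latent covariance matrix, and treatments shift block means additively in
latent units. The CMA-flavoured configuration couples the SCFA block to the
clinical block while the PNA-flavoured one decouples it, mirroring the
qualitative contrast the topological analysis is expected to recover.

Ground-truth oracles (known block membership, effect directions, and the
Monte-Carlo Bayes-optimal multiclass AUC for a target marker) support
validation of the downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from oitnet.bayesnet import DEFAULT_MARKERS, hand_till_auc
from oitnet.errors import ConfigurationError
from oitnet.preprocess import ABSOLUTE, RELATIVE, VariableSpec, level_names

#: the five treatment arms and their (sensitized, diet, oit) flags
DEFAULT_ARMS: dict[str, dict[str, int]] = {
    "sham": {"sensitized": 0, "diet": 0, "oit": 0},
    "sensitized": {"sensitized": 1, "diet": 0, "oit": 0},
    "fos": {"sensitized": 1, "diet": 1, "oit": 0},
    "oit": {"sensitized": 1, "diet": 0, "oit": 1},
    "oit_fos": {"sensitized": 1, "diet": 1, "oit": 1},
}

BLOCK_ORDER = ("clinical", "antibody", "scfa", "cytokine", "cell")

#: clinical readouts every configuration must provide
REQUIRED_CLINICAL = ("ear_swelling", "shock_score_id", "body_temperature", "mMCP1")

_TEMPERATURE_FEATURE = "body_temperature"

# Deterministic loading cycle: features within a block load on the block
# factor with moderate heterogeneity. Together with the residual noise this
# yields within-block Spearman correlations around 0.2-0.4 -- strong enough
# for the feature network to recover blocks, weak enough that treatment
# flags (not sibling markers) carry most of the information about any one
# marker, which is the regime a treatment-rooted expert network assumes.
_LOADING_CYCLE = (0.51, 0.45, 0.57, 0.48, 0.54, 0.60)
_DEFAULT_NOISE = 1.2
_TEMPERATURE_LOADING = -0.4  # deg C per latent unit: allergy drives a drop
_TEMPERATURE_NOISE = 0.75  # deg C between-animal spread
_TEMPERATURE_BASELINE = 37.2  # deg C

# Additive treatment effects on block latent means, in latent units.
# Through the ~0.5 loadings these translate to order-of-magnitude
# fold-changes on the log-normal assay scales (e.g. specific IgE rises
# >20-fold with sensitization) and a ~1.8 deg C anaphylactic temperature
# drop partially rescued by OIT and diet.
_DEFAULT_EFFECTS = {
    "sensitized": {"clinical": 4.5, "antibody": 6.0, "cytokine": 2.4, "cell": 1.5},
    "diet": {"clinical": -2.4, "antibody": -1.5, "cytokine": -0.9, "cell": -0.6},
    "oit": {"clinical": -3.0, "antibody": -1.2, "cytokine": -1.2, "cell": -0.6},
}

# In the CMA flavour the SCFA block rides the same axis as clinical severity
# (latent coupling plus treatment response aligned with the clinical block),
# so SCFA features are topologically near the clinical cluster; in the PNA
# flavour the block receives neither coupling nor treatment effects and
# stays an isolated cluster. The generator emulates this correlational
# contrast, not SCFA metabolism.
_SCFA_EFFECTS_COUPLED = {"sensitized": 2.0, "diet": -1.0, "oit": -1.2}

# SCFA panels (GC-MS on the same cecal samples) co-vary tightly; higher
# loadings keep the block internally coherent whether or not it couples to
# the clinical axis.
_SCFA_LOADING_CYCLE = (0.80, 0.72, 0.88, 0.76, 0.84, 0.92)

_SHARED_COUPLING = [
    ["clinical", "antibody", 0.5],
    ["clinical", "cytokine", 0.3],
    ["clinical", "cell", 0.2],
    ["antibody", "cytokine", 0.2],
    ["antibody", "cell", 0.2],
    ["cytokine", "cell", 0.4],
]


def _block_features_cma() -> dict[str, list[str]]:
    cytokines = [f"{c}_{t}" for c in ("IL4", "IL5", "IL10", "IL13",
                                      "IFNg", "TNFa", "IL6", "IL17")
                 for t in ("MLN", "spleen", "LP")]
    cells = [
        "Treg_spleen", "Treg_MLN", "Th1_spleen", "Th1_MLN", "Th2_spleen",
        "Th2_MLN", "CD19B220_spleen", "CXCR3_spleen", "T1ST2_spleen",
        "CD4_spleen", "CD8_spleen", "DC_CD103_MLN", "DC_CD11b_MLN",
        "B220_MLN", "GATA3_spleen", "Tbet_spleen", "FoxP3_LP", "CD69_spleen",
        "CD25_spleen", "NK_spleen", "CD4_MLN", "CD8_MLN", "Th17_spleen",
        "ILC2_LP",
    ]
    return {
        "clinical": ["ear_swelling", "shock_score_id", "body_temperature",
                     "mMCP1", "shock_score_ip", "temp_drop_ip",
                     "anaphylaxis_score"],
        "antibody": ["sIgE", "sIgG1", "sIgG2a", "total_IgE"],
        "scfa": ["acetate", "propionate", "butyrate", "isobutyrate",
                 "valerate", "isovalerate", "caproate"],
        "cytokine": cytokines,
        "cell": cells,
    }


def _block_features_pna() -> dict[str, list[str]]:
    # 20 features shared with the CMA panel, 13 PNA-specific.
    return {
        "clinical": ["ear_swelling", "shock_score_id", "body_temperature",
                     "mMCP1", "shock_score_ip", "temp_drop_ip",
                     "anaphylaxis_score"],
        "antibody": ["sIgE", "sIgG1", "sIgG2a"],
        "scfa": ["acetate", "propionate", "butyrate", "isobutyrate",
                 "valerate", "isovalerate", "caproate"],
        "cytokine": ["IL4_MLN", "IL5_MLN", "IL10_MLN", "IFNg_spleen",
                     "IL33_spleen", "TSLP_LP", "IFNg_antiCD3CD28_spleen",
                     "IL13_PE_spleen", "IL5_PE_spleen"],
        "cell": ["Th1_CD183_CD69_spleen", "Th2_T1ST2_CD69_spleen",
                 "Treg_PNA_spleen", "Treg_PNA_MLN", "Th2_PNA_MLN",
                 "DC_CD11bneg_CD103_MLN", "Basophil_blood"],
    }


def _panel_config(name: str, blocks: dict[str, list[str]],
                  scfa_clinical_coupling: float,
                  batch_scales: list[float],
                  experiment_excludes: list[list[str]]) -> dict:
    loadings = {}
    for bname, feats in blocks.items():
        cycle = _SCFA_LOADING_CYCLE if bname == "scfa" else _LOADING_CYCLE
        for i, f in enumerate(feats):
            loadings.setdefault(bname, {})[f] = cycle[i % len(cycle)]
    loadings["clinical"][_TEMPERATURE_FEATURE] = _TEMPERATURE_LOADING
    coupling = [list(c) for c in _SHARED_COUPLING]
    coupling.append(["clinical", "scfa", scfa_clinical_coupling])
    if scfa_clinical_coupling > 0:
        coupling.append(["antibody", "scfa", 0.3])
    effects = {fl: dict(eff) for fl, eff in _DEFAULT_EFFECTS.items()}
    if scfa_clinical_coupling > 0:
        for fl, v in _SCFA_EFFECTS_COUPLED.items():
            effects[fl]["scfa"] = v
    return {
        "name": name,
        "arms": {a: dict(fl) for a, fl in DEFAULT_ARMS.items()},
        "blocks": {b: {"features": dict(loadings[b])} for b in blocks},
        "coupling": coupling,
        "effects": effects,
        "noise_sd": {"default": _DEFAULT_NOISE,
                     _TEMPERATURE_FEATURE: _TEMPERATURE_NOISE},
        "temperature": {"feature": _TEMPERATURE_FEATURE,
                        "baseline": _TEMPERATURE_BASELINE},
        "batch_scales": list(batch_scales),
        "experiment_excludes": [list(x) for x in experiment_excludes],
    }


def cma_config() -> dict:
    """CMA-flavoured study configuration: 66 features, 3 experiments,
    SCFA block coupled to the clinical block (coupling 0.8)."""
    return _panel_config(
        "CMA", _block_features_cma(), scfa_clinical_coupling=0.8,
        batch_scales=[1.0, 1.8, 0.6],
        experiment_excludes=[[], ["TNFa_LP", "IL17_LP", "ILC2_LP"], []],
    )


def pna_config() -> dict:
    """PNA-flavoured study configuration: 33 features (20 shared with CMA),
    2 experiments, SCFA block decoupled from the clinical block."""
    return _panel_config(
        "PNA", _block_features_pna(), scfa_clinical_coupling=0.0,
        batch_scales=[1.0, 1.5],
        experiment_excludes=[[], ["IL13_PE_spleen"]],
    )


@dataclass
class GroundTruthModel:
    """Fully resolved generating model for one allergy-model flavour."""

    name: str
    arm_definitions: dict[str, dict[str, int]]
    block_names: tuple[str, ...]
    features: tuple[str, ...]
    feature_block: dict[str, str]
    loadings: dict[str, float]
    noise_sd: dict[str, float]
    coupling: np.ndarray  # latent block covariance, len(block_names)^2
    effects: dict[str, np.ndarray]  # flag -> per-block additive shift
    batch_scales: tuple[float, ...]
    temperature_feature: str
    temperature_baseline: float
    experiment_excludes: tuple[tuple[str, ...], ...]
    variable_specs: dict[str, VariableSpec] = field(default_factory=dict)

    def block_members(self, block: str) -> list[str]:
        return [f for f in self.features if self.feature_block[f] == block]


def build_ground_truth(config: Mapping) -> GroundTruthModel:
    """Resolve a study configuration into a generating model.

    Validates the treatment-arm table (five arms with binary flags), the
    block structure (a clinical block with the four required clinical
    readouts must exist), positivity of noise and batch scales, and
    positive-semidefiniteness of the latent block covariance. Deterministic:
    the model contains no sampled quantities.

    Raises
    ------
    ConfigurationError
        On any structural defect in the configuration.
    """
    blocks = config.get("blocks", {})
    if "clinical" not in blocks:
        raise ConfigurationError("configuration must define a 'clinical' block")
    if len(blocks) < 2:
        raise ConfigurationError("configuration must define at least 2 blocks")
    block_names = tuple(b for b in BLOCK_ORDER if b in blocks) + tuple(
        b for b in blocks if b not in BLOCK_ORDER
    )

    features: list[str] = []
    feature_block: dict[str, str] = {}
    loadings: dict[str, float] = {}
    for bname in block_names:
        feats = blocks[bname].get("features", {})
        if isinstance(feats, (list, tuple)):
            feats = {f: _LOADING_CYCLE[i % len(_LOADING_CYCLE)]
                     for i, f in enumerate(feats)}
        for fname, loading in feats.items():
            if fname in feature_block:
                raise ConfigurationError(
                    f"feature {fname!r} appears in more than one block"
                )
            features.append(fname)
            feature_block[fname] = bname
            loadings[fname] = float(loading)

    missing_clin = [f for f in REQUIRED_CLINICAL
                    if feature_block.get(f) != "clinical"]
    if missing_clin:
        raise ConfigurationError(
            f"clinical block must contain {missing_clin} "
            "(ear swelling, shock score, body temperature, mMCP-1)"
        )

    arms = {a: dict(fl) for a, fl in config.get("arms", DEFAULT_ARMS).items()}
    if len(arms) != 5:
        raise ConfigurationError(f"expected exactly 5 treatment arms, got {len(arms)}")
    for arm, flags in arms.items():
        for flag, v in flags.items():
            if v not in (0, 1):
                raise ConfigurationError(
                    f"arm {arm!r} flag {flag!r} must be 0/1, got {v!r}"
                )

    noise_cfg = dict(config.get("noise_sd", {}))
    default_noise = float(noise_cfg.pop("default", _DEFAULT_NOISE))
    noise_sd = {f: float(noise_cfg.get(f, default_noise)) for f in features}
    if any(s <= 0 for s in noise_sd.values()):
        raise ConfigurationError("noise_sd must be strictly positive")

    batch = tuple(float(b) for b in config.get("batch_scales", [1.0]))
    if any(b <= 0 for b in batch):
        raise ConfigurationError("batch scales must be strictly positive")

    k = len(block_names)
    cov = np.eye(k)
    b_index = {b: i for i, b in enumerate(block_names)}
    for entry in config.get("coupling", []):
        b1, b2, v = entry
        if b1 not in b_index or b2 not in b_index:
            raise ConfigurationError(f"coupling references unknown block(s): {entry}")
        cov[b_index[b1], b_index[b2]] = cov[b_index[b2], b_index[b1]] = float(v)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8:
        raise ConfigurationError(
            f"latent block covariance is not positive semidefinite "
            f"(min eigenvalue {eigvals.min():.4f})"
        )

    effects: dict[str, np.ndarray] = {}
    for flag, per_block in config.get("effects", {}).items():
        vec = np.zeros(k)
        for bname, v in per_block.items():
            if bname not in b_index:
                raise ConfigurationError(
                    f"effect for flag {flag!r} references unknown block {bname!r}"
                )
            vec[b_index[bname]] = float(v)
        effects[flag] = vec

    temp_cfg = config.get("temperature", {})
    temp_feature = temp_cfg.get("feature", _TEMPERATURE_FEATURE)
    temp_baseline = float(temp_cfg.get("baseline", _TEMPERATURE_BASELINE))
    if temp_feature not in feature_block:
        raise ConfigurationError(
            f"temperature feature {temp_feature!r} is not a declared feature"
        )

    specs = {
        f: VariableSpec(
            name=f,
            scale=ABSOLUTE if f == temp_feature else RELATIVE,
            block=feature_block[f],
            clinical=feature_block[f] == "clinical",
        )
        for f in features
    }

    excludes = tuple(
        tuple(x) for x in config.get("experiment_excludes", [[]])
    ) or ((),)

    return GroundTruthModel(
        name=str(config.get("name", "study")),
        arm_definitions=arms,
        block_names=block_names,
        features=tuple(features),
        feature_block=feature_block,
        loadings=loadings,
        noise_sd=noise_sd,
        coupling=cov,
        effects=effects,
        batch_scales=batch,
        temperature_feature=temp_feature,
        temperature_baseline=temp_baseline,
        experiment_excludes=excludes,
        variable_specs=specs,
    )


@dataclass
class Experiment:
    """One experiment's sample x feature table plus per-sample metadata."""

    experiment_id: str
    model_label: str
    data: pd.DataFrame
    meta: pd.DataFrame


@dataclass
class StudyCollection:
    """A set of experiments from one generating model, plus variable specs."""

    experiments: list[Experiment]
    variable_specs: dict[str, VariableSpec]

    def feature_tables(self) -> dict[str, pd.DataFrame]:
        return {e.experiment_id: e.data for e in self.experiments}

    def metadata(self) -> pd.DataFrame:
        return pd.concat([e.meta for e in self.experiments], axis=0)

    def n_samples(self) -> int:
        return sum(len(e.data) for e in self.experiments)


def _draw_samples(
    model: GroundTruthModel,
    n_per_arm: int,
    rng: np.random.Generator,
    batch_scale: float,
    feature_subset: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one experiment's samples (latent blocks -> features)."""
    feats = list(feature_subset) if feature_subset is not None else list(model.features)
    chol = np.linalg.cholesky(
        model.coupling + 1e-10 * np.eye(len(model.block_names))
    )
    b_index = {b: i for i, b in enumerate(model.block_names)}

    arm_rows, flag_rows = [], []
    latents = []
    for arm, flags in model.arm_definitions.items():
        shift = np.zeros(len(model.block_names))
        for flag, vec in model.effects.items():
            shift = shift + flags.get(flag, 0) * vec
        z = rng.standard_normal((n_per_arm, len(model.block_names))) @ chol.T
        latents.append(z + shift)
        arm_rows.extend([arm] * n_per_arm)
        flag_rows.extend([flags] * n_per_arm)
    latent = np.vstack(latents)
    n = latent.shape[0]

    data: dict[str, np.ndarray] = {}
    for f in feats:
        b = model.feature_block[f]
        x = model.loadings[f] * latent[:, b_index[b]] + rng.normal(
            0.0, model.noise_sd[f], size=n
        )
        if f == model.temperature_feature:
            data[f] = model.temperature_baseline + x
        else:
            data[f] = np.exp(x) * batch_scale
    table = pd.DataFrame(data)
    meta = pd.DataFrame(
        {
            "arm": arm_rows,
            "sensitized": [fl["sensitized"] for fl in flag_rows],
            "diet": [fl["diet"] for fl in flag_rows],
            "oit": [fl["oit"] for fl in flag_rows],
        }
    )
    return table, meta


def simulate_study(
    model: GroundTruthModel,
    n_per_arm: int = 6,
    n_experiments: int | None = None,
    seed: int = 0,
) -> StudyCollection:
    """Simulate a multi-experiment study from a ground-truth model.

    Each experiment gets its own RNG stream (split from ``seed``), its own
    multiplicative batch scale on relative features (the absolute
    temperature feature is never batch-scaled), and its configured feature
    panel (some experiments may lack some features, exercising the
    merge-on-intersection rule downstream). Fully reproducible per seed.

    Defaults of 6 animals per arm and the configured number of experiments
    give study sizes close to the real ones (~90 CMA animals over three
    experiments, ~70 PNA animals over two).
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    if n_experiments is None:
        n_experiments = len(model.batch_scales)
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")

    streams = np.random.SeedSequence(seed).spawn(n_experiments)
    experiments: list[Experiment] = []
    for e in range(n_experiments):
        rng = np.random.default_rng(streams[e])
        excludes = model.experiment_excludes[e % len(model.experiment_excludes)]
        feats = [f for f in model.features if f not in excludes]
        batch = model.batch_scales[e % len(model.batch_scales)]
        table, meta = _draw_samples(model, n_per_arm, rng, batch, feats)
        exp_id = f"{model.name}_e{e + 1}"
        ids = [
            f"{exp_id}_{arm}_{i + 1}"
            for arm in model.arm_definitions
            for i in range(n_per_arm)
        ]
        table.index = pd.Index(ids, name="sample_id")
        meta.index = pd.Index(ids, name="sample_id")
        meta.insert(0, "model", model.name)
        meta.insert(0, "experiment_id", exp_id)
        experiments.append(Experiment(exp_id, model.name, table, meta))
    return StudyCollection(experiments=experiments, variable_specs=dict(model.variable_specs))


def _quantile_code(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Nearest-rank quantile codes 0..n_levels-1, ties to the lower level."""
    n = len(values)
    s = np.sort(values)
    cuts = [s[int(np.ceil(j * n / n_levels)) - 1] for j in range(1, n_levels)]
    return np.searchsorted(np.asarray(cuts), values, side="left")


def oracle_bayes_auc(
    model: GroundTruthModel,
    target: str = "mMCP1",
    levels: int = 3,
    n_mc: int = 20000,
    seed: int = 0,
    predictors: Sequence[str] | None = None,
) -> float:
    """Monte-Carlo Bayes-optimal Hand-Till AUC for a discretized target.

    Draws ``n_mc`` samples from the generating model, discretizes the
    target and the predictor markers into ``levels`` quantile levels
    (treatment flags stay binary), estimates the true conditional
    distribution of the target level given the joint predictor
    configuration by empirical frequencies, and scores those posteriors
    with the Hand-Till multiclass AUC. This is the performance ceiling any
    fitted network predicting from the same discretized variables can
    approach.
    """
    if target not in model.features:
        raise ValueError(f"unknown target feature {target!r}")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if predictors is None:
        predictors = [m for m in DEFAULT_MARKERS
                      if m in model.features and m != target]
    else:
        unknown = [p for p in predictors if p not in model.features]
        if unknown:
            raise ValueError(f"unknown predictor feature(s): {unknown}")
        predictors = [p for p in predictors if p != target]

    n_per_arm = max(2, int(np.ceil(n_mc / len(model.arm_definitions))))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    table, meta = _draw_samples(
        model, n_per_arm, rng, batch_scale=1.0,
        feature_subset=[target, *predictors],
    )

    y = _quantile_code(table[target].to_numpy(), levels)
    cols = {fl: meta[fl].to_numpy() for fl in ("sensitized", "diet", "oit")}
    for p in predictors:
        cols[p] = _quantile_code(table[p].to_numpy(), levels)
    combo = pd.DataFrame(cols)
    combo_id = pd.factorize(pd.MultiIndex.from_frame(combo))[0]

    counts = np.zeros((combo_id.max() + 1, levels))
    np.add.at(counts, (combo_id, y), 1.0)
    post = counts / counts.sum(axis=1, keepdims=True)
    labels = level_names(levels)
    posteriors = pd.DataFrame(post[combo_id], columns=labels)
    true = np.asarray(labels, dtype=object)[y]
    return hand_till_auc(true, posteriors)


# -- study I/O ---------------------------------------------------------------

def write_study(study: StudyCollection, outdir) -> None:
    """Write one CSV per experiment, a pooled metadata CSV, and the
    variable-spec YAML."""
    from pathlib import Path

    from oitnet.preprocess import specs_to_yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for exp in study.experiments:
        exp.data.to_csv(out / f"{exp.experiment_id}.features.csv")
    study.metadata().to_csv(out / "metadata.csv")
    specs_to_yaml(study.variable_specs, out / "variables.yaml")


def read_study(indir) -> StudyCollection:
    """Read a study written by :func:`write_study`."""
    from pathlib import Path

    from oitnet.preprocess import specs_from_yaml

    ind = Path(indir)
    meta = pd.read_csv(ind / "metadata.csv", index_col="sample_id")
    specs = specs_from_yaml(ind / "variables.yaml")
    experiments = []
    for path in sorted(ind.glob("*.features.csv")):
        exp_id = path.name.replace(".features.csv", "")
        data = pd.read_csv(path, index_col="sample_id")
        sub_meta = meta.loc[data.index]
        model_label = str(sub_meta["model"].iloc[0])
        experiments.append(Experiment(exp_id, model_label, data, sub_meta))
    return StudyCollection(experiments=experiments, variable_specs=specs)
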