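"""Discrete Bayesian network with expert structure over treatment and marker nodes.

The network encodes the treatment design of an oral-immunotherapy study:
three binary root nodes (sensitized, scFOS/lcFOS diet, OIT) and a set of
discretized marker nodes (allergen-specific IgE and IgG1, ear swelling upon
intradermal challenge, mMCP-1 upon intragastric challenge, body temperature
during anaphylaxis), each a child of all three roots by default. Structure
is never learned from data; conditional probability tables are estimated by
maximum likelihood (optionally Dirichlet-smoothed), and inference is exact
by enumeration over the joint, which is cheap for networks of this size.

Predictive performance is summarized with the Hand-Till multiclass AUC
(the average over unordered class pairs of the two one-vs-one rank AUCs).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from oitnet.errors import ImpossibleEvidenceError

ROOT_LEVELS = ("no", "yes")
MARKER_LEVELS = ("low", "mid", "high")

#: treatment roots shared by every study design
DEFAULT_ROOTS = ("sensitized", "diet", "oit")
#: marker panel used for the default expert network
DEFAULT_MARKERS = ("sIgE", "sIgG1", "ear_swelling", "mMCP1", "body_temperature")


@dataclass(frozen=True)
class ExpertDAG:
    """Directed acyclic graph over named discrete nodes.

    ``levels`` maps each node to its ordered level labels; ``edges`` are
    (parent, child) pairs. The graph must be acyclic and every edge endpoint
    declared.
    """

    levels: Mapping[str, tuple[str, ...]]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "levels", {n: tuple(ls) for n, ls in self.levels.items()}
        )
        object.__setattr__(self, "edges", tuple((p, c) for p, c in self.edges))
        for p, c in self.edges:
            for end in (p, c):
                if end not in self.levels:
                    raise ValueError(f"edge endpoint {end!r} is not a declared node")
        if self._has_cycle():
            raise ValueError("expert structure must be acyclic")

    def _has_cycle(self) -> bool:
        order = self.topological_order(strict=False)
        return order is None

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.levels)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.edges if c == node)

    def topological_order(self, strict: bool = True):
        indeg = {n: 0 for n in self.levels}
        for _, c in self.edges:
            indeg[c] += 1
        queue = [n for n in self.levels if indeg[n] == 0]
        order: list[str] = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for p, c in self.edges:
                if p == n:
                    indeg[c] -= 1
                    if indeg[c] == 0:
                        queue.append(c)
        if len(order) != len(self.levels):
            if strict:
                raise ValueError("graph contains a cycle")
            return None
        return order

    def to_dict(self) -> dict:
        return {
            "levels": {n: list(ls) for n, ls in self.levels.items()},
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ExpertDAG":
        return cls(
            levels={n: tuple(ls) for n, ls in payload["levels"].items()},
            edges=tuple((p, c) for p, c in payload["edges"]),
        )


def default_dag(
    markers: Sequence[str] = DEFAULT_MARKERS,
    roots: Sequence[str] = DEFAULT_ROOTS,
    marker_levels: Sequence[str] = MARKER_LEVELS,
) -> ExpertDAG:
    """Default expert structure: every marker is a child of every treatment root.

    This encodes the design semantics (treatments drive markers) without
    asserting any marker-to-marker biology; the structure is fully
    overridable via configuration.
    """
    levels: dict[str, tuple[str, ...]] = {r: tuple(ROOT_LEVELS) for r in roots}
    for m in markers:
        levels[m] = tuple(marker_levels)
    edges = tuple((r, m) for m in markers for r in roots)
    return ExpertDAG(levels=levels, edges=edges)


@dataclass
class BayesNet:
    """Expert DAG plus one conditional probability table per node.

    ``cpts[node]`` has shape ``(L_parent1, ..., L_parentk, L_node)``; each
    row over the last axis sums to 1. ``counts`` holds the raw fitted counts
    with the same shape, ``alpha`` the Dirichlet smoothing constant used.
    """

    dag: ExpertDAG
    cpts: dict[str, np.ndarray]
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    alpha: float = 0.0
    _joint_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for node {node!r}")
            cpt = np.asarray(self.cpts[node], dtype=float)
            expect = tuple(len(self.dag.levels[p]) for p in self.dag.parents(node))
            expect += (len(self.dag.levels[node]),)
            if cpt.shape != expect:
                raise ValueError(
                    f"CPT for {node!r} has shape {cpt.shape}, expected {expect}"
                )
            rows = cpt.sum(axis=-1)
            if not np.allclose(rows, 1.0, atol=1e-12):
                raise ValueError(f"CPT rows for {node!r} do not sum to 1")
            if (cpt < -1e-15).any() or (cpt > 1 + 1e-15).any():
                raise ValueError(f"CPT entries for {node!r} outside [0, 1]")
            self.cpts[node] = cpt

    # -- joint distribution ------------------------------------------------
    def joint_table(self) -> np.ndarray:
        """Full joint as an ndarray with one axis per node (dag.nodes order)."""
        if self._joint_cache is None:
            nodes = self.dag.nodes
            axis_of = {n: i for i, n in enumerate(nodes)}
            shape = tuple(len(self.dag.levels[n]) for n in nodes)
            joint = np.ones(shape, dtype=float)
            for node in nodes:
                involved = list(self.dag.parents(node)) + [node]
                positions = [axis_of[n] for n in involved]
                perm = np.argsort(positions)
                cpt = np.transpose(self.cpts[node], axes=perm)
                sorted_pos = sorted(positions)
                full_shape = [1] * len(nodes)
                for pos, size in zip(sorted_pos, cpt.shape):
                    full_shape[pos] = size
                joint = joint * cpt.reshape(full_shape)
            self._joint_cache = joint
        return self._joint_cache

    def to_json(self, path) -> None:
        payload = {
            "dag": self.dag.to_dict(),
            "alpha": self.alpha,
            "cpts": {n: self.cpts[n].tolist() for n in self.dag.nodes},
            "counts": {n: self.counts[n].tolist() for n in self.counts},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "BayesNet":
        with open(path) as fh:
            payload = json.load(fh)
        dag = ExpertDAG.from_dict(payload["dag"])
        return cls(
            dag=dag,
            cpts={n: np.asarray(v, dtype=float) for n, v in payload["cpts"].items()},
            counts={n: np.asarray(v, dtype=float) for n, v in payload["counts"].items()},
            alpha=float(payload.get("alpha", 0.0)),
        )


def fit_cpts(dag: ExpertDAG, data: pd.DataFrame, alpha: float = 0.0) -> BayesNet:
    """Estimate every CPT from a discrete data table.

    Entry = (count + alpha) / (row total + alpha * L); with ``alpha = 0``
    this is the maximum-likelihood relative frequency, and parent
    configurations with zero observations fall back to the uniform
    distribution over the node's L levels. Rows with a missing value in any
    network node are dropped (listwise deletion).
    """
    missing = [n for n in dag.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"data lacks network node column(s): {missing}")
    sub = data[list(dag.nodes)].dropna()
    if len(sub) == 0:
        raise ValueError("no complete rows available to fit the network")

    code_of = {
        n: {lvl: i for i, lvl in enumerate(dag.levels[n])} for n in dag.nodes
    }
    codes: dict[str, np.ndarray] = {}
    for n in dag.nodes:
        col = sub[n]
        bad = set(col.unique()) - set(code_of[n])
        if bad:
            raise ValueError(f"column {n!r} contains unknown level(s) {sorted(map(str, bad))}")
        codes[n] = col.map(code_of[n]).to_numpy(dtype=np.intp)

    cpts: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        L = len(dag.levels[node])
        shape = tuple(len(dag.levels[p]) for p in parents) + (L,)
        cnt = np.zeros(shape, dtype=float)
        idx = tuple(codes[p] for p in parents) + (codes[node],)
        np.add.at(cnt, idx, 1.0)
        totals = cnt.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cpt = (cnt + alpha) / (totals + alpha * L)
        unseen = np.broadcast_to(totals == 0, cpt.shape) if alpha == 0 else (
            np.broadcast_to(totals + alpha * L == 0, cpt.shape)
        )
        cpt = np.where(unseen, 1.0 / L, cpt)
        cpts[node] = cpt
        counts[node] = cnt
    return BayesNet(dag=dag, cpts=cpts, counts=counts, alpha=alpha)


def joint_probability(bn: BayesNet, assignment: Mapping[str, str]) -> float:
    """Chain-rule probability of a full state assignment."""
    missing = [n for n in bn.dag.nodes if n not in assignment]
    if missing:
        raise ValueError(f"assignment misses node(s): {missing}")
    p = 1.0
    for node in bn.dag.nodes:
        levels = bn.dag.levels[node]
        if assignment[node] not in levels:
            raise ValueError(
                f"{assignment[node]!r} is not a level of {node!r} {levels}"
            )
        idx = tuple(
            bn.dag.levels[par].index(assignment[par]) for par in bn.dag.parents(node)
        ) + (levels.index(assignment[node]),)
        p *= float(bn.cpts[node][idx])
    return p


def _validate_evidence(bn: BayesNet, evidence: Mapping[str, str]) -> None:
    for node, state in evidence.items():
        if node not in bn.dag.levels:
            raise ValueError(f"evidence node {node!r} is not in the network")
        if state not in bn.dag.levels[node]:
            raise ValueError(
                f"{state!r} is not a level of {node!r} {bn.dag.levels[node]}"
            )


def infer_marginals(
    bn: BayesNet, evidence: Mapping[str, str] | None = None
) -> dict[str, dict[str, float]]:
    """Exact conditional marginal of every node given the evidence.

    Enumerates the full joint (networks here have at most a dozen nodes) and
    conditions by slicing; each returned distribution sums to 1.

    Raises
    ------
    ImpossibleEvidenceError
        If the evidence has probability zero under the fitted network.
    """
    evidence = dict(evidence or {})
    _validate_evidence(bn, evidence)
    nodes = bn.dag.nodes
    joint = bn.joint_table()
    index: list = [slice(None)] * len(nodes)
    for node, state in evidence.items():
        ax = nodes.index(node)
        index[ax] = bn.dag.levels[node].index(state)
    sub = joint[tuple(index)]
    total = float(sub.sum())
    if total <= 0.0:
        raise ImpossibleEvidenceError(f"evidence {evidence!r} has probability zero")

    free = [n for n in nodes if n not in evidence]
    out: dict[str, dict[str, float]] = {}
    for node in nodes:
        if node in evidence:
            out[node] = {
                lvl: 1.0 if lvl == evidence[node] else 0.0
                for lvl in bn.dag.levels[node]
            }
            continue
        ax = free.index(node)
        marg = sub.sum(axis=tuple(i for i in range(sub.ndim) if i != ax)) / total
        out[node] = {lvl: float(p) for lvl, p in zip(bn.dag.levels[node], marg)}
    return out


def predict_posterior(
    bn: BayesNet,
    target: str,
    samples: pd.DataFrame,
    on_impossible: str = "uniform",
) -> pd.DataFrame:
    """Posterior over the target's levels for each sample row.

    Each row's evidence is its observed state on every non-target network
    node; the result row is the exact conditional distribution of the
    target, identical to an :func:`infer_marginals` call with the same
    evidence. Rows whose evidence is impossible under the fitted network
    (zero joint probability, which can happen with unsmoothed CPTs on
    transfer data) receive the uniform distribution when ``on_impossible``
    is ``"uniform"`` (default), or raise when it is ``"raise"``.

    Raises
    ------
    ValueError
        If ``target`` is not a network node, or appears among the sample
        columns (the target must never be part of its own evidence).
    """
    if target not in bn.dag.levels:
        raise ValueError(f"target {target!r} is not a network node")
    if target in samples.columns:
        raise ValueError(
            f"target column {target!r} must not appear in the evidence samples"
        )
    ev_nodes = [n for n in bn.dag.nodes if n != target]
    missing = [n for n in ev_nodes if n not in samples.columns]
    if missing:
        raise ValueError(f"samples lack evidence column(s): {missing}")

    levels = bn.dag.levels[target]
    cache: dict[tuple, np.ndarray] = {}
    rows = np.empty((len(samples), len(levels)), dtype=float)
    ev_frame = samples[ev_nodes]
    for i, (_, row) in enumerate(ev_frame.iterrows()):
        key = tuple(row)
        if key not in cache:
            evidence = dict(zip(ev_nodes, key))
            try:
                marg = infer_marginals(bn, evidence)[target]
                cache[key] = np.array([marg[lvl] for lvl in levels])
            except ImpossibleEvidenceError:
                if on_impossible == "uniform":
                    cache[key] = np.full(len(levels), 1.0 / len(levels))
                else:
                    raise
        rows[i] = cache[key]
    return pd.DataFrame(rows, index=samples.index, columns=list(levels))


def hand_till_auc(
    true_labels,
    posteriors: pd.DataFrame,
    skip_missing: bool = False,
) -> float:
    """Hand-Till multiclass AUC (the M measure).

    For each unordered class pair {i, j}, A_hat(i | j) is the probability
    that a random class-i sample receives a higher class-i score than a
    random class-j sample (ties count one half), computed by ranking the
    class-i posterior column over the samples of the two classes; the pair
    value is the average of A_hat(i | j) and A_hat(j | i), and M is the mean
    over all pairs: M = 2 / (c (c - 1)) * sum_{i<j} A_hat(i, j).

    The measure is insensitive to class imbalance and invariant under any
    strictly increasing transform applied to all score columns.

    Parameters
    ----------
    true_labels:
        Observed class per sample.
    posteriors:
        Sample x class score table; columns are class labels.
    skip_missing:
        If a class column has no member among ``true_labels``, pairs
        involving it are skipped instead of raising (default raises).
    """
    y = pd.Series(list(true_labels))
    if len(y) != len(posteriors):
        raise ValueError("true_labels and posteriors differ in length")
    classes = list(posteriors.columns)
    present = [c for c in classes if (y == c).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 classes present among true labels")
    absent = [c for c in classes if c not in present]
    if absent and not skip_missing:
        raise ValueError(
            f"class(es) {absent} have zero members; pass skip_missing=True to skip"
        )

    def one_vs_one(ci: str, cj: str) -> float:
        # A_hat(ci | cj): rank the ci-scores of the ci+cj samples
        mask = (y == ci) | (y == cj)
        scores = posteriors.loc[mask.to_numpy(), ci].to_numpy(dtype=float)
        is_i = (y[mask.to_numpy()] == ci).to_numpy()
        n_i, n_j = int(is_i.sum()), int((~is_i).sum())
        ranks = rankdata(scores, method="average")
        s_i = ranks[is_i].sum()
        return (s_i - n_i * (n_i + 1) / 2) / (n_i * n_j)

    total, n_pairs = 0.0, 0
    for ci, cj in itertools.combinations(present, 2):
        a_ij = (one_vs_one(ci, cj) + one_vs_one(cj, ci)) / 2.0
        total += a_ij
        n_pairs += 1
    return total / n_pairs


@dataclass
class ScenarioReport:
    """What-if scenario table: per-node level probabilities in percent.

    ``table`` is indexed by (node, level) with one column per scenario, in
    the order the scenarios were supplied; the baseline (empty evidence)
    column reports the prior marginals.
    """

    table: pd.DataFrame
    scenarios: dict[str, dict[str, str]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.6f")

    def to_json(self, path) -> None:
        payload = {
            "scenarios": self.scenarios,
            "probabilities_percent": {
                col: {
                    f"{node}:{level}": round(float(v), 6)
                    for (node, level), v in self.table[col].items()
                }
                for col in self.table.columns
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)
            fh.write("\n")


def default_scenarios() -> dict[str, dict[str, str]]:
    """The standard what-if progression: baseline, sensitization, then OIT
    and/or diet added on top of sensitization."""
    return {
        "baseline": {},
        "sensitized": {"sensitized": "yes"},
        "sensitized+oit": {"sensitized": "yes", "oit": "yes"},
        "sensitized+diet": {"sensitized": "yes", "diet": "yes"},
        "sensitized+diet+oit": {"sensitized": "yes", "diet": "yes", "oit": "yes"},
    }


def scenario_table(
    bn: BayesNet, scenarios: Mapping[str, Mapping[str, str]] | None = None
) -> ScenarioReport:
    """Evaluate an ordered set of what-if scenarios.

    Each scenario asserts evidence (e.g. all animals sensitized and given
    OIT) and reports every node's exact conditional marginal, in percent.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    columns: dict[str, pd.Series] = {}
    for name, evidence in scenarios.items():
        marg = infer_marginals(bn, dict(evidence))
        flat = {
            (node, level): 100.0 * p
            for node in bn.dag.nodes
            for level, p in marg[node].items()
        }
        columns[name] = pd.Series(flat)
    table = pd.DataFrame(columns)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["node", "level"])
    return ScenarioReport(table=table, scenarios={k: dict(v) for k, v in scenarios.items()})


def sample_from(bn: BayesNet, n: int, seed: int) -> pd.DataFrame:
    """Forward-sample ``n`` complete assignments from the network."""
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    out: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for node in order:
        parents = bn.dag.parents(node)
        cpt = bn.cpts[node]
        L = len(bn.dag.levels[node])
        if parents:
            idx = tuple(codes[p] for p in parents)
            probs = cpt[idx]
        else:
            probs = np.broadcast_to(cpt, (n, L))
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        codes[node] = np.minimum((u[:, None] > cum).sum(axis=1), L - 1).astype(np.intp)
        labels = np.asarray(bn.dag.levels[node], dtype=object)
        out[node] = labels[codes[node]]
    return pd.DataFrame({n_: out[n_] for n_ in bn.dag.nodes})
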