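"""Normalization, pooling, merging and discretization of immunology panels.

Multi-experiment animal studies mix assays reported on relative scales
(titers, cytokine ODs, cell percentages) with absolute measurements such as
body temperature. Relative features are min-max rescaled to [0, 1] within
each experiment so that experiments become comparable before pooling;
absolute features pass through unchanged. Pooled experiments are merged on
the intersection of their feature panels, and continuous features are
discretized with a mutual-information-preserving quantile-collapse scheme
(Hartemink's algorithm) so that a discrete Bayesian network can be fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import mutual_info_score

from oitnet.errors import (
    ConstantVariableError,
    EmptyIntersectionError,
    InsufficientSupportError,
)

RELATIVE = "relative"
ABSOLUTE = "absolute"

#: default ordered level labels by level count
_LEVEL_NAMES = {2: ["low", "high"], 3: ["low", "mid", "high"]}


def level_names(n_levels: int) -> list[str]:
    """Ordered label set for an ``n_levels``-state discrete variable."""
    if n_levels in _LEVEL_NAMES:
        return list(_LEVEL_NAMES[n_levels])
    return [f"q{i + 1}" for i in range(n_levels)]


@dataclass(frozen=True)
class VariableSpec:
    """Per-feature measurement metadata.

    Parameters
    ----------
    name:
        Feature identifier (column name).
    scale:
        ``"relative"`` (assay-specific units, min-max normalized per
        experiment) or ``"absolute"`` (physical units, kept unchanged).
    block:
        Assay-block label (clinical, antibody, scfa, cytokine, cell, ...).
    clinical:
        Whether the feature is a clinical outcome readout.
    """

    name: str
    scale: str = RELATIVE
    block: str = ""
    clinical: bool = False

    def __post_init__(self) -> None:
        if self.scale not in (RELATIVE, ABSOLUTE):
            raise ValueError(
                f"scale must be {RELATIVE!r} or {ABSOLUTE!r}, got {self.scale!r}"
            )


def specs_to_yaml(specs: Mapping[str, VariableSpec], path) -> None:
    payload = {
        name: {"scale": s.scale, "block": s.block, "clinical": bool(s.clinical)}
        for name, s in sorted(specs.items())
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def specs_from_yaml(path) -> dict[str, VariableSpec]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {
        name: VariableSpec(name=name, scale=d["scale"], block=d.get("block", ""),
                           clinical=bool(d.get("clinical", False)))
        for name, d in payload.items()
    }


def minmax_normalize(
    dataset: pd.DataFrame, specs: Mapping[str, VariableSpec]
) -> pd.DataFrame:
    """Min-max rescale the relative-scale features of one experiment to [0, 1].

    Applied per experiment, before pooling, so that relative assays from
    different experiments share a common range. Features marked absolute in
    ``specs`` (e.g. body temperature in deg C) are returned unchanged, as are
    columns without a spec (metadata). The observed minimum maps to 0 and the
    maximum to 1; the mapping is affine, hence order-preserving.

    Raises
    ------
    ConstantVariableError
        If a relative feature has zero observed range (or no observed value
        at all): such a feature carries no rank information and would divide
        by zero.
    """
    out = dataset.copy()
    for col in dataset.columns:
        spec = specs.get(col)
        if spec is None or spec.scale == ABSOLUTE:
            continue
        values = pd.to_numeric(out[col], errors="coerce")
        lo, hi = values.min(), values.max()
        if pd.isna(lo):
            raise ConstantVariableError(f"feature {col!r} has no observed values")
        if hi == lo:
            raise ConstantVariableError(
                f"relative feature {col!r} is constant ({lo!r}) in this experiment"
            )
        out[col] = (values - lo) / (hi - lo)
    return out


def pool_and_merge(datasets: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate experiments on the intersection of their feature panels.

    Features present in only a subset of the experiments are discarded:
    keeping them would create mutually exclusive sample sets for which
    pairwise similarity is undefined. Row provenance is retained in an
    ``experiment_id`` column; sample ids (the index) must be globally unique.

    Parameters
    ----------
    datasets:
        Mapping of experiment id to sample x feature table, or a sequence of
        tables (ids then default to ``exp1``, ``exp2``, ...).

    Raises
    ------
    EmptyIntersectionError
        If no feature is shared by all experiments.
    ValueError
        On duplicate sample ids across experiments, or no input.
    """
    if not isinstance(datasets, Mapping):
        datasets = {f"exp{i + 1}": df for i, df in enumerate(datasets)}
    if len(datasets) == 0:
        raise ValueError("pool_and_merge requires at least one dataset")

    tables = list(datasets.values())
    shared = [c for c in tables[0].columns
              if all(c in t.columns for t in tables[1:])]
    if not shared:
        raise EmptyIntersectionError(
            "no feature is present in every experiment; nothing to pool"
        )
    parts = []
    for exp_id, table in datasets.items():
        part = table[shared].copy()
        part.insert(0, "experiment_id", exp_id)
        parts.append(part)
    pooled = pd.concat(parts, axis=0)
    if pooled.index.has_duplicates:
        dups = pooled.index[pooled.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids across experiments: {dups[:5]}")
    return pooled


@dataclass
class DiscretizationMap:
    """Ordered breakpoints and level labels fitted on one pooled dataset.

    The map is the portable part of a trained model: applying it to new data
    (e.g. the second allergy model in a transfer evaluation) reproduces the
    training bins. A value equal to a breakpoint falls in the lower level.
    """

    breakpoints: dict[str, list[float]] = field(default_factory=dict)
    labels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def level_count(self) -> dict[str, int]:
        return {f: len(v) for f, v in self.labels.items()}

    def apply_feature(self, feature: str, values: np.ndarray) -> np.ndarray:
        """Discretize one feature; returns an object array of labels (NaN kept)."""
        bp = np.asarray(self.breakpoints[feature], dtype=float)
        labels = np.asarray(self.labels[feature], dtype=object)
        values = np.asarray(values, dtype=float)
        codes = np.searchsorted(bp, values, side="left")
        out = labels[np.clip(codes, 0, len(labels) - 1)].astype(object)
        out[np.isnan(values)] = np.nan
        return out

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        """Discretize every mapped column of ``table``; other columns pass through."""
        out = table.copy()
        for feature in self.breakpoints:
            if feature in out.columns:
                out[feature] = self.apply_feature(feature, out[feature].to_numpy())
        return out

    def to_yaml(self, path) -> None:
        payload = {
            f: {"breakpoints": [float(b) for b in self.breakpoints[f]],
                "labels": list(self.labels[f])}
            for f in sorted(self.breakpoints)
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DiscretizationMap":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            breakpoints={f: list(map(float, d["breakpoints"])) for f, d in payload.items()},
            labels={f: list(d["labels"]) for f, d in payload.items()},
        )


def _quantile_breakpoints(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior empirical quantiles splitting ``values`` into n_bins bins.

    Duplicate breakpoints (heavy ties) are collapsed, so fewer than
    ``n_bins - 1`` breakpoints may be returned.
    """
    qs = np.arange(1, n_bins) / n_bins
    bp = np.quantile(values, qs)
    return np.unique(bp)


def _codes(values: np.ndarray, bp: np.ndarray) -> np.ndarray:
    """Bin assignment with values equal to a breakpoint going to the lower bin."""
    return np.searchsorted(bp, values, side="left")


def _pairwise_mi(a: np.ndarray, b: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    both = mask_a & mask_b
    if both.sum() < 2:
        return 0.0
    return float(mutual_info_score(a[both], b[both]))


def _exact_search_size(bps, kept, levels) -> float:
    from math import comb

    size = 1.0
    for c in kept:
        size *= comb(len(bps[c]), min(levels - 1, len(bps[c])))
    return size


def _exact_discretize(values, masks, bps, kept, levels) -> None:
    """Exhaustive search over all joint breakpoint subsets (small inputs).

    Maximizes the total pairwise MI over all feature pairs; ties resolve to
    the lexicographically first subset combination, keeping the result
    deterministic. Mutates ``bps`` in place.
    """
    import itertools as _it

    options = []
    for c in kept:
        n_keep = min(levels - 1, len(bps[c]))
        subsets = [
            np.asarray(sub)
            for sub in _it.combinations(bps[c].tolist(), n_keep)
        ]
        options.append([( sub, _codes(values[c], sub)) for sub in subsets])

    best_total, best_combo = -np.inf, None
    for combo in _it.product(*options):
        total = 0.0
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                total += _pairwise_mi(
                    combo[i][1], combo[j][1], masks[kept[i]], masks[kept[j]]
                )
        if total > best_total + 1e-12:
            best_total, best_combo = total, combo
    for c, (sub, _) in zip(kept, best_combo):
        bps[c] = sub


def hartemink_discretize(
    pooled: pd.DataFrame,
    levels: int = 3,
    initial_levels: int = 10,
    on_insufficient: str = "raise",
    columns: Iterable[str] | None = None,
    refine: bool = True,
    exact_limit: int = 2000,
) -> tuple[pd.DataFrame, DiscretizationMap]:
    """Mutual-information-preserving discretization (Hartemink's algorithm).

    Each feature is first quantile-binned into ``initial_levels`` bins; then,
    feature by feature (in column order), adjacent bins are greedily
    collapsed, at every step keeping the merge that maximizes the summed
    pairwise mutual information (nats, empirical joint frequencies) with all
    other features in their current binning, until ``levels`` bins remain.
    With ``refine=True`` (default) a deterministic coordinate-ascent sweep
    follows: each feature in turn is re-assigned the subset of its initial
    quantile breakpoints that maximizes the same objective given the other
    features' current bins, until no feature changes. This repairs the
    myopia of the one-merge-at-a-time collapse at small sample sizes while
    staying inside the family of quantile-subset discretizations. When the
    joint space of breakpoint subsets is small (at most ``exact_limit``
    combinations over all features) the optimum is found by exhaustive
    enumeration instead; greedy search only takes over where enumeration
    is unaffordable.
    The procedure uses only ranks, so it is invariant to strictly monotone
    transforms of any feature. Ties between candidates are broken toward
    the lowest bin index, making the result deterministic.

    A single-feature table has no peer information to preserve and falls
    back to plain ``levels``-quantile binning.

    Parameters
    ----------
    pooled:
        Sample x feature table (metadata columns such as ``experiment_id``
        are ignored automatically when non-numeric; or restrict with
        ``columns``).
    levels:
        Target number of discrete levels per feature (default 3: tertiles).
    initial_levels:
        Number of starting quantile bins (must exceed ``levels``).
    on_insufficient:
        ``"raise"`` (default) raises :class:`InsufficientSupportError` for a
        feature with fewer than ``levels`` achievable bins; ``"exclude"``
        drops it with a warning.

    Returns
    -------
    (discrete table of level labels, DiscretizationMap)
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if initial_levels <= levels:
        raise ValueError("initial_levels must exceed levels")

    if columns is None:
        columns = [c for c in pooled.columns
                   if pd.api.types.is_numeric_dtype(pooled[c])]
    columns = list(columns)
    if not columns:
        raise ValueError("no numeric feature columns to discretize")

    values: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    bps: dict[str, np.ndarray] = {}
    kept: list[str] = []
    for col in columns:
        v = pd.to_numeric(pooled[col], errors="coerce").to_numpy(dtype=float)
        mask = np.isfinite(v)
        n_distinct = np.unique(v[mask]).size
        if n_distinct < levels:
            if on_insufficient == "exclude":
                warnings.warn(
                    f"feature {col!r} has only {n_distinct} distinct values; "
                    f"excluded from {levels}-level discretization",
                    stacklevel=2,
                )
                continue
            raise InsufficientSupportError(
                f"feature {col!r} has {n_distinct} distinct values, "
                f"fewer than levels={levels}"
            )
        bp = _quantile_breakpoints(v[mask], initial_levels)
        if len(bp) + 1 < levels:
            if on_insufficient == "exclude":
                warnings.warn(
                    f"feature {col!r} yields only {len(bp) + 1} quantile bins; excluded",
                    stacklevel=2,
                )
                continue
            raise InsufficientSupportError(
                f"feature {col!r} supports only {len(bp) + 1} quantile bins, "
                f"fewer than levels={levels}"
            )
        values[col] = v
        masks[col] = mask
        bps[col] = bp
        kept.append(col)

    if not kept:
        raise InsufficientSupportError("no feature survived discretization")

    if len(kept) == 1:
        col = kept[0]
        bps[col] = _quantile_breakpoints(values[col][masks[col]], levels)
    elif _exact_search_size(bps, kept, levels) <= exact_limit:
        _exact_discretize(values, masks, bps, kept, levels)
    else:
        initial_bps = {c: bps[c].copy() for c in kept}
        codes = {c: _codes(values[c], bps[c]) for c in kept}

        def objective(col: str, cand: np.ndarray) -> float:
            return sum(
                _pairwise_mi(cand, codes[other], masks[col], masks[other])
                for other in kept
                if other != col
            )

        for col in kept:
            while len(bps[col]) + 1 > levels:
                best_total, best_idx = -np.inf, None
                for i in range(len(bps[col])):
                    cand = _codes(values[col], np.delete(bps[col], i))
                    total = objective(col, cand)
                    if total > best_total + 1e-12:
                        best_total, best_idx = total, i
                bps[col] = np.delete(bps[col], best_idx)
                codes[col] = _codes(values[col], bps[col])

        if refine:
            import itertools as _it

            for _ in range(25):  # sweeps to a coordinate-wise fixed point
                changed = False
                for col in kept:
                    n_keep = len(bps[col])
                    if n_keep >= len(initial_bps[col]):
                        continue
                    best_total = objective(col, codes[col])
                    best_bp = bps[col]
                    for keep in _it.combinations(range(len(initial_bps[col])), n_keep):
                        cand_bp = initial_bps[col][list(keep)]
                        if np.array_equal(cand_bp, bps[col]):
                            continue
                        cand = _codes(values[col], cand_bp)
                        total = objective(col, cand)
                        if total > best_total + 1e-12:
                            best_total, best_bp = total, cand_bp
                    if not np.array_equal(best_bp, bps[col]):
                        bps[col] = best_bp
                        codes[col] = _codes(values[col], bps[col])
                        changed = True
                if not changed:
                    break

    names = level_names(levels)
    dmap = DiscretizationMap(
        breakpoints={c: [float(b) for b in bps[c]] for c in kept},
        labels={c: list(names) for c in kept},
    )
    discrete = pooled.copy()
    discrete = discrete[[c for c in pooled.columns if c in kept or c not in columns]]
    for col in kept:
        discrete[col] = dmap.apply_feature(col, values[col])
    return discrete, dmap


def tertile_labels(values) -> np.ndarray:
    """Empirical tertile labels (low / mid / high) for a numeric vector.

    Uses nearest-rank quantiles: the first breakpoint is the ceil(n/3)-th
    order statistic, the second the ceil(2n/3)-th; values equal to a
    breakpoint are assigned to the lower class, so tied values always share
    a label. With distinct values, class sizes differ by at most one.

    Raises
    ------
    ValueError
        With fewer than 3 finite values.
    """
    v = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    finite = np.isfinite(v)
    n = int(finite.sum())
    if n < 3:
        raise ValueError(f"tertile_labels needs >= 3 finite values, got {n}")
    s = np.sort(v[finite])
    q1 = s[int(np.ceil(n / 3)) - 1]
    q2 = s[int(np.ceil(2 * n / 3)) - 1]
    out = np.empty(v.shape, dtype=object)
    out[:] = np.nan
    out[finite & (v <= q1)] = "low"
    out[finite & (v > q1) & (v <= q2)] = "mid"
    out[finite & (v > q2)] = "high"
    return out
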