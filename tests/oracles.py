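"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: plain Python loops over explicitly
enumerated states, direct pair counting, and Counter-based mutual
information, sharing no code path with the package internals they check.
"""

import itertools
import math
from collections import Counter


def bruteforce_joint(bn):
    """All full assignments and their chain-rule probabilities (dict)."""
    nodes = list(bn.dag.nodes)
    out = {}
    for combo in itertools.product(*(bn.dag.levels[n] for n in nodes)):
        assign = dict(zip(nodes, combo))
        p = 1.0
        for node in nodes:
            idx = tuple(
                bn.dag.levels[par].index(assign[par])
                for par in bn.dag.parents(node)
            ) + (bn.dag.levels[node].index(assign[node]),)
            p *= float(bn.cpts[node][idx])
        out[combo] = p
    return nodes, out


def bruteforce_marginals(bn, evidence):
    """Conditional marginals by filtering the enumerated joint."""
    nodes, joint = bruteforce_joint(bn)
    ev_idx = {nodes.index(k): v for k, v in evidence.items()}
    total = 0.0
    sums = {n: Counter() for n in nodes}
    for combo, p in joint.items():
        if any(combo[i] != v for i, v in ev_idx.items()):
            continue
        total += p
        for i, n in enumerate(nodes):
            sums[n][combo[i]] += p
    if total == 0.0:
        return None
    return {
        n: {lvl: sums[n][lvl] / total for lvl in bn.dag.levels[n]} for n in nodes
    }


def pairwise_rank_auc(true_labels, posteriors):
    """Hand-Till M by direct counting over all between-class sample pairs."""
    labels = list(true_labels)
    classes = sorted({c for c in labels})
    cols = {c: list(posteriors[c]) for c in posteriors.columns}

    def a_given(ci, cj):
        # P(score_ci of a ci-sample > that of a cj-sample), ties 1/2
        wins = ties = n = 0
        for i, yi in enumerate(labels):
            if yi != ci:
                continue
            for j, yj in enumerate(labels):
                if yj != cj:
                    continue
                n += 1
                if cols[ci][i] > cols[ci][j]:
                    wins += 1
                elif cols[ci][i] == cols[ci][j]:
                    ties += 1
        return (wins + 0.5 * ties) / n

    total = 0.0
    pairs = 0
    for a, b in itertools.combinations(classes, 2):
        total += (a_given(a, b) + a_given(b, a)) / 2.0
        pairs += 1
    return total / pairs


def counter_mi(a, b):
    """Mutual information in nats from empirical joint frequencies."""
    n = len(a)
    joint = Counter(zip(a, b))
    pa = Counter(a)
    pb = Counter(b)
    mi = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        mi += pxy * math.log(pxy / ((pa[x] / n) * (pb[y] / n)))
    return mi


def total_pairwise_mi(columns):
    """Sum of MI over all unordered column pairs."""
    total = 0.0
    for i in range(len(columns)):
        for j in range(i + 1, len(columns)):
            total += counter_mi(columns[i], columns[j])
    return total


def exhaustive_hartemink_max(values, initial_breakpoints, levels):
    """Global maximum of total pairwise MI over every way of keeping
    ``levels - 1`` of each feature's initial breakpoints.

    Collapsing adjacent quantile bins always leaves a subset of the initial
    breakpoints, so enumerating subsets covers every collapse sequence.
    """
    import bisect

    def codes(vals, bps):
        return tuple(bisect.bisect_left(bps, v) for v in vals)

    feature_options = []
    for vals, bps in zip(values, initial_breakpoints):
        opts = []
        for keep in itertools.combinations(range(len(bps)), levels - 1):
            kept = [bps[i] for i in keep]
            opts.append(codes(vals, kept))
        feature_options.append(opts)

    best = -math.inf
    for combo in itertools.product(*feature_options):
        best = max(best, total_pairwise_mi(list(combo)))
    return best
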