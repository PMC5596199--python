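"""Independent brute-force oracles used by the acceptance suite."""

import itertools

import numpy as np


def brute_force_complete_linkage(X):
    """O(n^3) agglomeration with inter-cluster distance = max pairwise
    Euclidean distance.  Returns the sequence of merge heights."""
    clusters = [{i} for i in range(len(X))]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if dist < best[0]:
                best = (dist, (a, b))
        dist, (a, b) = best
        heights.append(dist)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


def enumerate_pwm_scores(pwm):
    """Exact log-odds score of every k-mer (4^w values, sorted)."""
    w = pwm.width
    lo = pwm.log_odds
    codes = np.array(list(itertools.product(range(4), repeat=w)))
    return np.sort(lo[np.arange(w), codes].sum(axis=1))


def two_pass_anova_f(values, groups):
    """Plain sums-of-squares one-way ANOVA F statistic."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    grand = values.mean()
    ssb = sum(len(values[groups == g]) * (values[groups == g].mean() - grand) ** 2
              for g in uniq)
    ssw = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
              for g in uniq)
    dfb, dfw = len(uniq) - 1, len(values) - len(uniq)
    return (ssb / dfb) / (ssw / dfw)


def naive_scan_starts(pwm, seq, p_threshold):
    """Per-window rescoring scan: 1-based start positions per strand."""
    out = {"+": set(), "-": set()}
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        for i in range(len(seq) - pwm.width + 1):
            sc = mat.score(seq[i:i + pwm.width])
            if not np.isnan(sc) and mat.score_pvalue(sc) <= p_threshold:
                out[strand].add(i + 1)
    return out
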