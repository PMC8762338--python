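"""Independent brute-force oracles used to validate the implementations.

Everything here is written as directly as possible — explicit loops over
rank positions, full enumeration of group assignments or tables — and never
shares code with the package's own computational paths.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def average_ranks(values) -> list[float]:
    """Ascending average ranks computed by explicit tie-group walking."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # ranks are 1-based
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def ssgsea_oracle(values, genes, set_genes, alpha: float) -> float:
    """Running-sum ssGSEA score for one sample, enumerated position by position.

    Genes are walked in decreasing expression order (ties broken by input
    order); at each position the weighted in-set CDF minus the uniform
    out-of-set CDF is accumulated.
    """
    n = len(genes)
    in_set = [g in set_genes for g in genes]
    ranks = average_ranks(values)
    weights = [(r / n) ** alpha for r in ranks]
    order = sorted(range(n), key=lambda i: (-values[i], i))
    sum_w_in = sum(w for w, m in zip(weights, in_set) if m)
    n_out = n - sum(in_set)
    score = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for pos in order:
        if in_set[pos]:
            cum_in += weights[pos]
        else:
            cum_out += 1.0
        score += cum_in / sum_w_in - cum_out / n_out
    return score


def unweighted_ks_oracle(values, genes, set_genes) -> float:
    """Integrated CDF difference with every in-set gene weighted equally."""
    n = len(genes)
    in_set = [g in set_genes for g in genes]
    order = sorted(range(n), key=lambda i: (-values[i], i))
    n_in = sum(in_set)
    n_out = n - n_in
    score = 0.0
    cum_in = 0
    cum_out = 0
    for pos in order:
        if in_set[pos]:
            cum_in += 1
        else:
            cum_out += 1
        score += cum_in / n_in - cum_out / n_out
    return score


def mwu_enumeration(x, y, alternative: str = "two_sided") -> float:
    """Exact Mann-Whitney p by enumerating every group assignment."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_of(group_a, group_b):
        return sum((a > b) + 0.5 * (a == b) for a in group_a for b in group_b)

    u_obs = u_of(x, y)
    idx = range(len(pooled))
    us = []
    for combo in itertools.combinations(idx, n1):
        chosen = set(combo)
        ga = [pooled[i] for i in chosen]
        gb = [pooled[i] for i in idx if i not in chosen]
        us.append(u_of(ga, gb))
    us = np.asarray(us)
    eps = 1e-9
    p_greater = float((us >= u_obs - eps).mean())
    p_less = float((us <= u_obs + eps).mean())
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def fisher_2x2_enumeration(table) -> float:
    """Two-sided Fisher p for a 2x2 table by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)) / math.comb(n, r1)

    p_obs = pmf(a)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return min(1.0, sum(pmf(k) for k in range(lo, hi + 1)
                        if pmf(k) <= p_obs * (1 + 1e-9)))


def anova_ss_oracle(groups) -> tuple[float, float]:
    """(F, p) from a naive two-pass between/within sum-of-squares split."""
    import scipy.stats as sps

    groups = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, float(sps.f.sf(f, df_b, df_w))


def hypergeom_resampling_oracle(overlap: int, background: int, set_size: int,
                                deg_size: int, draws: int = 100_000,
                                seed: int = 0) -> float:
    """Monte-Carlo upper-tail overlap probability by resampling DEG lists."""
    rng = np.random.default_rng(seed)
    marked = np.zeros(background, dtype=bool)
    marked[:set_size] = True
    hits = 0
    for _ in range(draws):
        picks = rng.choice(background, size=deg_size, replace=False)
        if marked[picks].sum() >= overlap:
            hits += 1
    return hits / draws


def km_product_limit_oracle(times, events):
    """Product-limit estimate walked time point by time point."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=bool)[order]
    s = 1.0
    out = []
    at_risk = len(times)
    i = 0
    while i < len(times):
        t = times[i]
        d = 0
        removed = 0
        while i < len(times) and times[i] == t:
            d += int(events[i])
            removed += 1
            i += 1
        if d > 0:
            s *= 1 - d / at_risk
            out.append((t, s, at_risk))
        at_risk -= removed
    return out


def logrank_oe_oracle(groups):
    """Chi-square statistic from an explicit observed-minus-expected table."""
    # groups: list of (times, events) arrays
    all_times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    all_events = np.concatenate([np.asarray(e, dtype=bool) for _, e in groups])
    gid = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    k = len(groups)
    event_times = np.unique(all_times[all_events])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = all_times >= t
        n = at_risk.sum()
        d = (all_events & (all_times == t)).sum()
        for g in range(k):
            n_g = (at_risk & (gid == g)).sum()
            O[g] += (all_events & (all_times == t) & (gid == g)).sum()
            E[g] += d * n_g / n
            for h in range(k):
                n_h = (at_risk & (gid == h)).sum()
                same = 1.0 if g == h else 0.0
                if n > 1:
                    V[g, h] += d * (n_g / n) * (same - n_h / n) * (n - d) / (n - 1)
    z = (O - E)[:-1]
    stat = float(z @ np.linalg.solve(V[:-1, :-1], z))
    return stat
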