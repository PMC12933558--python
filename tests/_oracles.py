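"""Independent brute-force oracles used by the test suite.

Everything here is deliberately implemented without touching the package
internals it checks: plain loops, enumeration and closed forms.
"""

from __future__ import annotations

import itertools
import math
import random


def reachable_brute_force(edges, members, start):
    """All nodes reachable from ``start`` by enumerating simple paths over
    the member-restricted arc set (directed forward, undirected both ways)."""
    arcs = set()
    for src, dst, directed in edges:
        if src in members and dst in members:
            arcs.add((src, dst))
            if not directed:
                arcs.add((dst, src))
    found = set()

    def walk(path):
        here = path[-1]
        for a, b in arcs:
            if a == here and b not in path:
                found.add(b)
                walk(path + [b])

    if start in members:
        walk([start])
    return found


def wilcoxon_exact_enumeration(a, b):
    """Exact two-sided rank-sum p-value by enumerating every assignment of
    the pooled values to the two groups (tie-free inputs only)."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle assumes tie-free input"
    n = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for x in xs for y in ys if x > y))
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def order_statistic_cdf(x, k, n):
    """P(k-th order statistic of n uniforms <= x): binomial tail, the
    closed form of the Beta(k, n-k+1) CDF."""
    return sum(math.comb(n, j) * x**j * (1 - x) ** (n - j) for j in range(k, n + 1))


def rank_statistic_oracle(pvals):
    p = sorted(pvals)
    n = len(p)
    return min(order_statistic_cdf(p[k - 1], k, n) for k in range(1, n + 1))


def rank_statistic_pvalue_oracle(pvals, n_mc, seed):
    """Pure-python Monte-Carlo calibration with its own RNG."""
    rng = random.Random(seed)
    t_obs = rank_statistic_oracle(pvals)
    n = len(pvals)
    hits = 0
    for _ in range(n_mc):
        t = rank_statistic_oracle([rng.random() for _ in range(n)])
        if t <= t_obs:
            hits += 1
    return (1 + hits) / (n_mc + 1)


def bh_oracle(pvals):
    """Textbook step-up BH with an explicit loop."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        value = min(1.0, pvals[i] * n / rank)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def ptm_reference_oracle(reactions, max_complex_size):
    """Independent reimplementation of the builder: returns the set of
    (protein, residue, position, ptm_type, direction, enzyme, pathway)
    tuples expected from a list of plain-dict reactions."""
    out = set()
    for rxn in reactions:
        if rxn["is_candidate"]:
            continue
        side = {}
        for tag in ("inputs", "outputs"):
            acc = {}
            for ent in rxn[tag]:
                if ent.get("complex_size") is not None and ent["complex_size"] > max_complex_size:
                    continue
                acc.setdefault(ent["protein"], set()).update(
                    (m["residue"], m["position"], m["ptm_type"]) for m in ent.get("mods", [])
                )
            side[tag] = acc
        proteins = set(side["inputs"]) | set(side["outputs"])
        for protein in proteins:
            before = side["inputs"].get(protein, set())
            after = side["outputs"].get(protein, set())
            diffs = [(s, "added") for s in after - before] + [(s, "removed") for s in before - after]
            for (residue, position, ptm_type), direction in diffs:
                for enzyme in rxn["catalysts"] or [""]:
                    for pathway in rxn["pathway_ids"] or ["UNASSIGNED"]:
                        out.add((protein, residue, position, ptm_type, direction, enzyme, pathway))
    return out
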