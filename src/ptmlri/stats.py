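"""Two-cluster differential statistics.

Implements the statistical core of the differential analysis mode:
score-quantile cluster assignment, the two-sided Wilcoxon rank-sum test
(exact for small tie-free samples, tie-corrected normal approximation
otherwise), per-row differential tables, parent-protein normalization of
PTM matrices, the order-statistic rank statistic used for pathway
p-values with Monte-Carlo calibration, p-value combination by product,
and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .sitekey import SiteKeyError, parse_site_key

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterDesign",
    "assign_clusters_by_score",
    "wilcoxon_two_sided",
    "differential_table",
    "normalize_ptm",
    "rank_statistic",
    "rank_statistic_pvalue",
    "combine_lri_pvalue",
    "bh_adjust",
    "derive_seed",
]

#: per-side sample-size limit below which the exact rank-sum null is used
EXACT_THRESHOLD = 25


@dataclass
class ClusterDesign:
    """Assignment of samples to the two compared clusters A and B."""

    sample_ids: list
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [s for s, lab in self.labels.items() if lab not in ("A", "B", "unused")]
        if bad:
            raise ValueError(f"labels must be A/B/unused; offending samples: {bad}")
        if len(self.a_samples) < 2 or len(self.b_samples) < 2:
            raise ValueError("each cluster needs at least 2 samples")

    @property
    def a_samples(self) -> list:
        return [s for s in self.sample_ids if self.labels.get(s) == "A"]

    @property
    def b_samples(self) -> list:
        return [s for s in self.sample_ids if self.labels.get(s) == "B"]

    @property
    def used_samples(self) -> list:
        return [s for s in self.sample_ids if self.labels.get(s) in ("A", "B")]


def assign_clusters_by_score(
    scores: Mapping[str, float], low_q: float = 0.2, high_q: float = 0.2
) -> ClusterDesign:
    """Quantile-based clustering on a per-sample score.

    Samples at or below the ``low_q`` quantile go to cluster A, samples at
    or above the ``1 - high_q`` quantile go to B, the rest are unused.
    Degenerate scores (a sample qualifying for both sides) or fewer than
    2 samples per side are fatal.
    """
    if not (0 < low_q and 0 < high_q and low_q + high_q <= 1):
        raise ValueError("need 0 < low_q, high_q and low_q + high_q <= 1")
    samples = list(scores)
    values = np.asarray([scores[s] for s in samples], dtype=float)
    lo = np.quantile(values, low_q)
    hi = np.quantile(values, 1.0 - high_q)
    labels = {}
    for s, v in zip(samples, values):
        in_a, in_b = v <= lo, v >= hi
        if in_a and in_b:
            raise ValueError("degenerate score distribution: sample qualifies for both clusters")
        labels[s] = "A" if in_a else ("B" if in_b else "unused")
    n_a = sum(1 for v in labels.values() if v == "A")
    n_b = sum(1 for v in labels.values() if v == "B")
    if n_a < 2 or n_b < 2:
        raise ValueError(f"fewer than 2 samples per side (A={n_a}, B={n_b})")
    return ClusterDesign(sample_ids=samples, labels=labels)


def wilcoxon_two_sided(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both sides have at most
    ``EXACT_THRESHOLD`` observations and the pooled values carry no ties;
    tie-corrected normal approximation with continuity correction
    otherwise.  Returns NaN when a side is empty after removing missing
    values; a pooled sample with zero spread gives p = 1.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size <= EXACT_THRESHOLD and y.size <= EXACT_THRESHOLD:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def differential_table(
    matrix: pd.DataFrame,
    design: ClusterDesign,
    test: Callable[[Sequence[float], Sequence[float]], float] = wilcoxon_two_sided,
) -> pd.DataFrame:
    """Per-row two-cluster comparison.

    Returns a frame indexed like ``matrix`` with columns ``delta``
    (median of cluster B minus median of cluster A) and ``p_value`` from
    the pluggable two-sample test.  Rows with no observed value on either
    side are excluded (logged).  Raises if the matrix does not carry every
    sample the design uses.
    """
    missing_cols = [s for s in design.used_samples if s not in matrix.columns]
    if len(missing_cols) == len(design.used_samples):
        raise ValueError("matrix columns share no samples with the cluster design")
    if missing_cols:
        raise ValueError(f"matrix is missing design samples: {missing_cols}")
    a_mat = matrix[design.a_samples].to_numpy(dtype=float)
    b_mat = matrix[design.b_samples].to_numpy(dtype=float)
    rows, deltas, pvals = [], [], []
    n_excluded = 0
    for key, a_row, b_row in zip(matrix.index, a_mat, b_mat):
        a_obs = a_row[~np.isnan(a_row)]
        b_obs = b_row[~np.isnan(b_row)]
        if a_obs.size == 0 or b_obs.size == 0:
            n_excluded += 1
            continue
        rows.append(key)
        deltas.append(float(np.median(b_obs) - np.median(a_obs)))
        pvals.append(test(a_obs, b_obs))
    if n_excluded:
        logger.info("differential_table: excluded %d row(s) empty on one side", n_excluded)
    return pd.DataFrame({"delta": deltas, "p_value": pvals}, index=pd.Index(rows, name="row_key"))


def normalize_ptm(
    ptm_matrix: pd.DataFrame, expr_matrix: pd.DataFrame, mode: str = "ratio"
) -> pd.DataFrame:
    """Normalize site-level PTM intensities by the parent protein.

    ``ratio`` divides each site row by the protein row sample-wise
    (non-positive protein values give missing cells); ``difference``
    subtracts, which is the natural choice for log-scale data.  Sites
    whose parent protein is absent from the expression matrix are
    dropped, as are rows with malformed site keys (both logged).
    """
    if mode not in ("ratio", "difference"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    shared = [c for c in ptm_matrix.columns if c in set(expr_matrix.columns)]
    if not shared:
        raise ValueError("PTM and expression matrices share no sample columns")
    keep_rows, parents = [], []
    n_orphan = n_malformed = 0
    expr_rows = set(expr_matrix.index)
    for key in ptm_matrix.index:
        try:
            sk = parse_site_key(str(key))
        except SiteKeyError:
            n_malformed += 1
            continue
        if sk.protein not in expr_rows:
            n_orphan += 1
            continue
        keep_rows.append(key)
        parents.append(sk.protein)
    if n_malformed:
        logger.warning("normalize_ptm: skipped %d malformed site key(s)", n_malformed)
    if n_orphan:
        logger.info("normalize_ptm: dropped %d site(s) with undetected parent protein", n_orphan)
    site = ptm_matrix.loc[keep_rows, shared].to_numpy(dtype=float)
    prot = expr_matrix.loc[parents, shared].to_numpy(dtype=float)
    if mode == "ratio":
        bad = ~np.isnan(prot) & (prot <= 0.0)
        if bad.any():
            logger.warning("normalize_ptm: %d cell(s) with non-positive protein value set missing", int(bad.sum()))
        prot = prot.copy()
        prot[bad] = np.nan
        out = site / prot
    else:
        out = site - prot
    return pd.DataFrame(out, index=pd.Index(keep_rows, name=ptm_matrix.index.name), columns=shared)


# ---------------------------------------------------------------------------
# pathway rank statistic


def rank_statistic(pvals: Sequence[float]) -> float:
    """Order-statistic rank statistic of sorted p-values.

    For sorted values p_(1) <= ... <= p_(n), the statistic is the minimum
    over k of the Beta(k, n-k+1) CDF at p_(k), i.e. the most surprising
    order statistic relative to n independent uniforms.  Small values
    indicate that some prefix of the targets is jointly more significant
    than expected under the null.
    """
    p = np.sort(np.asarray(list(pvals), dtype=float))
    if p.size == 0:
        raise ValueError("rank_statistic requires at least one p-value")
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    k = np.arange(1, n + 1)
    return float(sps.beta.cdf(p, k, n - k + 1).min())


def rank_statistic_pvalue(pvals: Sequence[float], n_mc: int = 10000, seed: int = 0) -> float:
    """Monte-Carlo calibrated p-value for :func:`rank_statistic`.

    Draws ``n_mc`` null pathways of n independent uniforms with a fixed
    seed and returns ``(1 + #{T_null <= T_obs}) / (n_mc + 1)`` (add-one
    continuity, never exactly zero).
    """
    t_obs = rank_statistic(pvals)
    n = len(list(pvals))
    rng = np.random.default_rng(seed)
    u = np.sort(rng.random((int(n_mc), n)), axis=1)
    k = np.arange(1, n + 1)
    t_null = sps.beta.cdf(u, k, n - k + 1).min(axis=1)
    return float((1 + int((t_null <= t_obs).sum())) / (int(n_mc) + 1))


def combine_lri_pvalue(p_ligand: float, p_receptor: float, p_pathway: float) -> float:
    """Product of the three component p-values (missing propagates)."""
    vals = [p_ligand, p_receptor, p_pathway]
    out = 1.0
    for v in vals:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return float("nan")
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"p-value out of range: {v}")
        out *= v
    return out


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Missing values are passed through as NaN and do not count toward the
    family size.
    """
    p = np.asarray(list(pvals), dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def derive_seed(base_seed: int, *tokens) -> int:
    """Deterministic, platform-stable child seed for one MC calibration."""
    msg = ":".join([str(base_seed), *map(str, tokens)]).encode()
    return int.from_bytes(hashlib.blake2b(msg, digest_size=8).digest(), "big")
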