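"""Differential-mode ligand-receptor inference with PTM refinement.

Pipeline: enumerate candidate (ligand, receptor, pathway) triples from
the reference bundle, score them on expression statistics under sign
constraints (no significance threshold at this stage), refine each
triple with site-level PTM evidence matched against the PTM reference
(direction-aware concordance), compute a pathway-level PTM p-value by
the same rank statistic, correct both p-value families with BH, and
apply the final dual-threshold (or product) selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import PTMRefRecord, ReferenceBundle, filter_pathways, receptor_targets
from .sitekey import SiteKeyError, parse_site_key
from .stats import (
    ClusterDesign,
    bh_adjust,
    combine_lri_pvalue,
    derive_seed,
    differential_table,
    normalize_ptm,
    rank_statistic_pvalue,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "CandidateTriple",
    "LRITriple",
    "PTMEvent",
    "LRIResult",
    "enumerate_candidate_triples",
    "score_triples_expression",
    "concordance_flag",
    "attach_ptm_events",
    "pathway_ptm_pvalue",
    "select_lris",
    "collapse_to_protein_mode",
    "run_differential_pipeline",
]


def _isnan(x: float) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class InferenceConfig:
    """Tuning knobs of the differential pipeline (defaults documented in
    the CLI help)."""

    receptor_sign: str = "positive"          # positive | negative
    target_sign: str = "any"                 # any | positive
    alpha_expr: float = 0.05                 # expression-only selection threshold
    alpha_expr_relaxed: float = 0.25         # expression threshold when PTM evidence present
    alpha_ptm: float = 0.05                  # PTM pathway p threshold
    selection_mode: str = "dual_threshold"   # dual_threshold | product
    min_targets: int = 5
    max_members: int = 400
    n_mc: int = 10000
    seed: int = 0
    ptm_position_mode: str = "site"          # site | protein
    ptm_norm_mode: str = "ratio"             # ratio | difference | none

    def __post_init__(self) -> None:
        for name in ("alpha_expr", "alpha_expr_relaxed", "alpha_ptm"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.receptor_sign not in ("positive", "negative"):
            raise ValueError("receptor_sign must be positive or negative")
        if self.target_sign not in ("any", "positive"):
            raise ValueError("target_sign must be any or positive")
        if self.selection_mode not in ("dual_threshold", "product"):
            raise ValueError("selection_mode must be dual_threshold or product")
        if self.ptm_position_mode not in ("site", "protein"):
            raise ValueError("ptm_position_mode must be site or protein")
        if self.ptm_norm_mode not in ("ratio", "difference", "none"):
            raise ValueError("ptm_norm_mode must be ratio, difference or none")
        if self.n_mc < 1000:
            raise ValueError("n_mc must be >= 1000")


@dataclass(frozen=True)
class CandidateTriple:
    ligand: str
    receptor: str
    pathway_id: str
    targets: frozenset


@dataclass
class LRITriple:
    ligand: str
    receptor: str
    pathway_id: str
    pathway_name: str
    targets: frozenset
    p_ligand: float
    p_receptor: float
    p_pathway: float
    p_overall: float
    ligand_delta: float
    receptor_delta: float
    q_value: float = float("nan")


@dataclass
class PTMEvent:
    """An observed site-level modification matched to a reference record."""

    record: PTMRefRecord
    delta: float
    p_value: float
    enzyme_detected: bool
    substrate_detected: bool
    concordant: str  # concordant | discordant | indeterminate


@dataclass
class LRIResult:
    triple: LRITriple
    events: list = field(default_factory=list)
    p_ptm_pathway: float = float("nan")
    q_ptm: float = float("nan")
    selected: bool = False
    selection_reason: str = "rejected"  # expression_only | ptm_confirmed | ptm_rescued | rejected


# ---------------------------------------------------------------------------


def enumerate_candidate_triples(
    bundle: ReferenceBundle,
    expr_rows: set,
    min_targets: int = 5,
    max_members: int = 400,
) -> list:
    """One candidate per LR pair and per pathway containing the receptor.

    The ligand and receptor must both be detected (present as expression
    rows); targets are the receptor's pathway-restricted reachable set
    intersected with the detected rows, and pathway-size filters are
    applied after that intersection.
    """
    candidates: list = []
    by_receptor: dict = {}
    for pw in bundle.pathways:
        for pair in bundle.lr_pairs:
            if pair.receptor in pw.members:
                by_receptor.setdefault(pw.pathway_id, []).append(pair)
    for pw in bundle.pathways:
        pairs = by_receptor.get(pw.pathway_id, [])
        targets_cache: dict = {}
        for pair in pairs:
            if pair.ligand not in expr_rows or pair.receptor not in expr_rows:
                continue
            if pair.receptor not in targets_cache:
                targets_cache[pair.receptor] = (
                    receptor_targets(bundle.network, pw, pair.receptor) & expr_rows
                )
            targets = targets_cache[pair.receptor]
            kept = filter_pathways([pw], {pw.pathway_id: targets}, min_targets, max_members)
            if not kept:
                continue
            candidates.append(
                CandidateTriple(pair.ligand, pair.receptor, pw.pathway_id, frozenset(targets))
            )
    return candidates


def score_triples_expression(
    candidates: Iterable[CandidateTriple],
    diff: pd.DataFrame,
    config: InferenceConfig,
    pathway_names: dict | None = None,
) -> list:
    """Expression-based scoring of candidate triples; no significance
    threshold is applied here.

    Sign constraints: the ligand must be up-regulated (delta > 0); the
    receptor must follow ``config.receptor_sign``.  When
    ``config.target_sign`` is ``positive``, wrong-signed targets keep a
    p-value of 1 in the rank statistic.  ``q_value`` is BH over the
    retained triples' overall p-values.
    """
    pathway_names = pathway_names or {}
    triples: list = []
    n_dropped_missing = n_dropped_sign = n_dropped_targets = 0
    for cand in sorted(candidates, key=lambda c: (c.ligand, c.receptor, c.pathway_id)):
        if cand.ligand not in diff.index or cand.receptor not in diff.index:
            n_dropped_missing += 1
            continue
        lig = diff.loc[cand.ligand]
        rec = diff.loc[cand.receptor]
        if _isnan(lig["p_value"]) or _isnan(rec["p_value"]):
            n_dropped_missing += 1
            continue
        if lig["delta"] <= 0:
            n_dropped_sign += 1
            continue
        if config.receptor_sign == "positive" and rec["delta"] <= 0:
            n_dropped_sign += 1
            continue
        if config.receptor_sign == "negative" and rec["delta"] >= 0:
            n_dropped_sign += 1
            continue
        target_ps = []
        for t in sorted(cand.targets):
            if t not in diff.index:
                continue
            row = diff.loc[t]
            p = row["p_value"]
            if _isnan(p):
                continue
            if config.target_sign == "positive" and row["delta"] <= 0:
                p = 1.0
            target_ps.append(float(p))
        if not target_ps:
            n_dropped_targets += 1
            continue
        p_pathway = rank_statistic_pvalue(
            target_ps,
            n_mc=config.n_mc,
            seed=derive_seed(config.seed, "pathway", cand.ligand, cand.receptor, cand.pathway_id),
        )
        p_ligand = float(lig["p_value"])
        p_receptor = float(rec["p_value"])
        triples.append(
            LRITriple(
                ligand=cand.ligand,
                receptor=cand.receptor,
                pathway_id=cand.pathway_id,
                pathway_name=pathway_names.get(cand.pathway_id, ""),
                targets=cand.targets,
                p_ligand=p_ligand,
                p_receptor=p_receptor,
                p_pathway=p_pathway,
                p_overall=combine_lri_pvalue(p_ligand, p_receptor, p_pathway),
                ligand_delta=float(lig["delta"]),
                receptor_delta=float(rec["delta"]),
            )
        )
    if n_dropped_missing or n_dropped_sign or n_dropped_targets:
        logger.info(
            "score_triples_expression: dropped %d without ligand/receptor statistics, "
            "%d by sign constraints, %d without measured targets",
            n_dropped_missing, n_dropped_sign, n_dropped_targets,
        )
    qs = bh_adjust([t.p_overall for t in triples])
    for t, q in zip(triples, qs):
        t.q_value = float(q)
    return triples


def concordance_flag(direction: str, delta: float) -> str:
    """Direction-aware agreement between an observed site change and the
    reference: an ``added`` site should increase (delta > 0), a
    ``removed`` site should decrease.  Zero or missing delta is
    indeterminate."""
    if direction not in ("added", "removed"):
        raise ValueError(f"direction must be added or removed, got {direction!r}")
    if _isnan(delta) or delta == 0:
        return "indeterminate"
    if (direction == "added") == (delta > 0):
        return "concordant"
    return "discordant"


def attach_ptm_events(
    triple: LRITriple,
    ptm_records: Sequence[PTMRefRecord],
    ptm_diff: pd.DataFrame,
    expr_rows: set,
) -> list:
    """Match the pathway's reference records to observed PTM statistics.

    An event is created only when the substrate protein is detected in
    the expression data, the annotated enzyme (when any) is detected too,
    and the site itself carries a differential result.  Discordant events
    are retained.
    """
    events: list = []
    for rec in ptm_records:
        if rec.pathway_id != triple.pathway_id:
            continue
        if rec.protein not in expr_rows:
            continue
        enzyme_detected = bool(rec.enzyme) and rec.enzyme in expr_rows
        if rec.enzyme and not enzyme_detected:
            continue
        key = rec.site_key
        if key not in ptm_diff.index:
            continue
        row = ptm_diff.loc[key]
        if _isnan(row["p_value"]):
            continue
        delta = float(row["delta"])
        events.append(
            PTMEvent(
                record=rec,
                delta=delta,
                p_value=float(row["p_value"]),
                enzyme_detected=enzyme_detected,
                substrate_detected=True,
                concordant=concordance_flag(rec.direction, delta),
            )
        )
    return events


def pathway_ptm_pvalue(events: Sequence[PTMEvent], n_mc: int = 10000, seed: int = 0) -> float:
    """Rank-statistic p-value over the events' p-values; NaN when there
    are no events."""
    ps = [e.p_value for e in events if not _isnan(e.p_value)]
    if not ps:
        return float("nan")
    return rank_statistic_pvalue(ps, n_mc=n_mc, seed=seed)


def select_lris(results: Sequence[LRIResult], config: InferenceConfig) -> list:
    """Apply the final selection rule in place and return the list.

    ``dual_threshold``: keep triples with overall expression p at or
    below ``alpha_expr`` (reason ``expression_only``, upgraded to
    ``ptm_confirmed`` when the PTM pathway p also passes ``alpha_ptm``),
    or rescue sub-threshold triples (overall p <= ``alpha_expr_relaxed``)
    whose PTM pathway p passes ``alpha_ptm`` (reason ``ptm_rescued``).
    ``product``: keep triples whose product of overall and PTM p-values
    is at or below ``alpha_expr``.
    """
    for r in results:
        p = r.triple.p_overall
        p_ptm = r.p_ptm_pathway
        ptm_ok = not _isnan(p_ptm) and p_ptm <= config.alpha_ptm
        if config.selection_mode == "dual_threshold":
            if not _isnan(p) and p <= config.alpha_expr:
                r.selected = True
                r.selection_reason = "ptm_confirmed" if ptm_ok else "expression_only"
            elif not _isnan(p) and p <= config.alpha_expr_relaxed and ptm_ok:
                r.selected = True
                r.selection_reason = "ptm_rescued"
            else:
                r.selected = False
                r.selection_reason = "rejected"
        else:  # product
            combined = p * (1.0 if _isnan(p_ptm) else p_ptm)
            if not _isnan(combined) and combined <= config.alpha_expr:
                r.selected = True
                r.selection_reason = "ptm_confirmed" if not _isnan(p_ptm) else "expression_only"
            else:
                r.selected = False
                r.selection_reason = "rejected"
    return list(results)


def collapse_to_protein_mode(ptm_diff: pd.DataFrame) -> pd.DataFrame:
    """Global protein mode: within each (protein, ptm_type), broadcast the
    most extreme site's regulation (smallest p; ties broken by larger
    |delta|, then lexicographically smallest site key) to every site row.
    Idempotent.  Rows with malformed keys are left untouched.
    """
    deltas = ptm_diff["delta"].to_dict()
    pvals = ptm_diff["p_value"].to_dict()
    groups: dict = {}
    for key in ptm_diff.index:
        try:
            sk = parse_site_key(str(key))
        except SiteKeyError:
            continue
        groups.setdefault((sk.protein, sk.ptm_type), []).append(key)
    out = ptm_diff.copy()
    for keys in groups.values():
        scored = [k for k in keys if not _isnan(pvals[k])]
        if not scored:
            continue
        best = min(scored, key=lambda k: (pvals[k], -abs(deltas[k]), str(k)))
        out.loc[keys, "delta"] = deltas[best]
        out.loc[keys, "p_value"] = pvals[best]
    return out


# ---------------------------------------------------------------------------


def run_differential_pipeline(
    expr_matrix: pd.DataFrame,
    ptm_matrix: pd.DataFrame | None,
    design: ClusterDesign,
    bundle: ReferenceBundle,
    config: InferenceConfig | None = None,
) -> list:
    """End-to-end differential analysis; deterministic given the config seed.

    Returns a list of :class:`LRIResult`, sorted by overall p-value.  The
    PTM matrix is optional: without it the run is expression-only and all
    PTM columns stay missing.
    """
    config = config or InferenceConfig()
    used = set(design.used_samples)
    if ptm_matrix is not None and not (used & set(ptm_matrix.columns)):
        raise ValueError("PTM matrix shares no samples with the cluster design")

    expr_diff = differential_table(expr_matrix, design)
    logger.info("expression differential table: %d row(s)", len(expr_diff))

    ptm_diff = None
    if ptm_matrix is not None:
        if config.ptm_norm_mode != "none":
            ptm_matrix = normalize_ptm(ptm_matrix, expr_matrix, mode=config.ptm_norm_mode)
        ptm_diff = differential_table(ptm_matrix, design)
        if config.ptm_position_mode == "protein":
            ptm_diff = collapse_to_protein_mode(ptm_diff)
        logger.info("PTM differential table: %d site(s)", len(ptm_diff))

    expr_rows = set(map(str, expr_matrix.index))
    candidates = enumerate_candidate_triples(
        bundle, expr_rows, min_targets=config.min_targets, max_members=config.max_members
    )
    logger.info("candidate triples: %d", len(candidates))
    names = {p.pathway_id: p.name for p in bundle.pathways}
    triples = score_triples_expression(candidates, expr_diff, config, pathway_names=names)
    logger.info("scored triples: %d", len(triples))

    results: list = []
    for t in triples:
        events: list = []
        if ptm_diff is not None and bundle.ptm_records:
            events = attach_ptm_events(t, bundle.ptm_records, ptm_diff, expr_rows)
        p_ptm = pathway_ptm_pvalue(
            events,
            n_mc=config.n_mc,
            seed=derive_seed(config.seed, "ptm", t.ligand, t.receptor, t.pathway_id),
        )
        results.append(LRIResult(triple=t, events=events, p_ptm_pathway=p_ptm))

    q_ptm = bh_adjust([r.p_ptm_pathway for r in results])
    for r, q in zip(results, q_ptm):
        r.q_ptm = float(q)

    select_lris(results, config)
    results.sort(key=lambda r: (r.triple.p_overall, r.triple.ligand, r.triple.receptor, r.triple.pathway_id))
    logger.info("selected %d / %d triple(s)", sum(r.selected for r in results), len(results))
    return results
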