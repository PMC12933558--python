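"""Synthetic two-cluster proteomics data with planted signal.

Generates a reference bundle (LR pairs, pathways with directed target
chains, PTM reference records), log-scale Gaussian expression and PTM
matrices with planted cluster-B shifts on ligand/receptor/targets of the
planted triples, and site-level PTM deltas whose sign agrees (or
deliberately disagrees) with the reference direction.  Everything is
deterministic per seed, and a truth table supports recovery scoring.

PTM site rows are the parent protein row plus an independent site term,
so difference-mode normalization isolates the planted site effect
exactly; ratio mode is exercised by exponentiating the matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import (
    Edge,
    IntracellularNetwork,
    LRPair,
    PathwayDef,
    PTMRefRecord,
    ReferenceBundle,
)
from .sitekey import format_site_key
from .stats import ClusterDesign

__all__ = ["SimConfig", "TruthTable", "simulate_bundle", "simulate_matrices", "score_recovery"]


@dataclass
class SimConfig:
    n_samples_a: int = 20
    n_samples_b: int = 20
    n_ligands: int = 10
    n_receptors: int = 10
    n_pathways: int = 10
    targets_per_pathway: int = 8
    baseline_mean: float = 20.0
    baseline_sd: float = 1.0
    effect_size: float = 3.0          # planted B-A shift, in SD units
    ptm_sites_per_pathway: int = 3
    frac_concordant: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    n_planted: int | None = None      # None plants every LR-pathway pair

    def __post_init__(self) -> None:
        if self.n_samples_a < 3 or self.n_samples_b < 3:
            raise ValueError("need at least 3 samples per cluster")
        for name in ("frac_concordant", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_ligands, self.n_receptors, self.n_pathways) < 1:
            raise ValueError("need at least one ligand, receptor and pathway")


@dataclass
class TruthTable:
    planted_triples: list = field(default_factory=list)   # (ligand, receptor, pathway_id)
    planted_events: list = field(default_factory=list)    # (site_key, direction, intended concordance)


def _receptor(i: int, config: SimConfig) -> str:
    return f"REC{i % config.n_receptors}"


def simulate_bundle(config: SimConfig) -> tuple:
    """Deterministic bundle: LR pair i pairs ligand LIGi with receptor
    REC(i mod n_receptors); pathway j contains that receptor plus a
    directed chain of ``targets_per_pathway`` targets; PTM reference
    records sit on the pathway's targets with the pathway's receptor as
    enzyme.  The first ``n_planted`` pairs (all by default) are listed in
    the truth table along with their pathway's PTM events.
    """
    pairs = [LRPair(f"LIG{i}", _receptor(i, config), source="sim") for i in range(config.n_ligands)]

    pathways, edges, records = [], [], []
    for j in range(config.n_pathways):
        receptor = _receptor(j, config)
        targets = [f"T{j}_{k}" for k in range(config.targets_per_pathway)]
        members = frozenset([receptor, *targets])
        pathways.append(PathwayDef(f"PW{j}", f"simulated pathway {j}", "user", members))
        chain = [receptor, *targets]
        edges.extend(Edge(a, b, directed=True) for a, b in zip(chain[:-1], chain[1:]))
        for s in range(config.ptm_sites_per_pathway):
            records.append(
                PTMRefRecord(
                    protein=targets[s % max(1, config.targets_per_pathway)],
                    residue="S",
                    position=100 + s,
                    ptm_type="phosphorylation",
                    direction="added" if s % 2 == 0 else "removed",
                    enzyme=receptor,
                    pathway_id=f"PW{j}",
                )
            )
    bundle = ReferenceBundle(
        lr_pairs=pairs,
        pathways=pathways,
        network=IntracellularNetwork(edges),
        ptm_records=records,
    )

    n_planted = config.n_ligands if config.n_planted is None else min(config.n_planted, config.n_ligands)
    truth = TruthTable()
    planted_pathways = set()
    for i in range(n_planted):
        pid = f"PW{i % config.n_pathways}"
        truth.planted_triples.append((f"LIG{i}", _receptor(i, config), pid))
        planted_pathways.add(pid)
    for rec in records:
        if rec.pathway_id in planted_pathways:
            site_idx = rec.position - 100
            n_conc = math.ceil(config.frac_concordant * config.ptm_sites_per_pathway)
            intended = "concordant" if site_idx < n_conc else "discordant"
            truth.planted_events.append((rec.site_key, rec.direction, intended))
    return bundle, truth


def simulate_matrices(bundle: ReferenceBundle, truth: TruthTable, config: SimConfig) -> tuple:
    """Log-scale Gaussian matrices with the planted shifts of ``truth``.

    Returns ``(expr_matrix, ptm_matrix, design)``.  Cluster B columns of
    planted ligands, receptors and pathway targets are shifted by
    ``effect_size * baseline_sd``; planted PTM sites receive an
    independent site-level shift whose sign matches the reference
    direction for intended-concordant events and opposes it otherwise.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"A{i}" for i in range(config.n_samples_a)] + [
        f"B{i}" for i in range(config.n_samples_b)
    ]
    design = ClusterDesign(
        sample_ids=samples,
        labels={s: ("A" if s.startswith("A") else "B") for s in samples},
    )
    b_cols = np.array([s.startswith("B") for s in samples])

    proteins = sorted(
        {p.ligand for p in bundle.lr_pairs}
        | {p.receptor for p in bundle.lr_pairs}
        | set(bundle.network.nodes)
        | {m for pw in bundle.pathways for m in pw.members}
    )
    expr = pd.DataFrame(
        config.baseline_mean + config.baseline_sd * rng.standard_normal((len(proteins), len(samples))),
        index=pd.Index(proteins, name="protein"),
        columns=samples,
    )

    shift = config.effect_size * config.baseline_sd
    shifted_rows: set = set()
    for ligand, receptor, pathway_id in truth.planted_triples:
        pw = bundle.pathway_by_id(pathway_id)
        shifted_rows |= {ligand, receptor}
        shifted_rows |= set(pw.members) - {receptor}
    for row in shifted_rows:
        expr.loc[row, b_cols] += shift

    intended_by_key = {key: intended for key, _, intended in truth.planted_events}
    site_keys = sorted({rec.site_key for rec in bundle.ptm_records})
    ptm = pd.DataFrame(
        index=pd.Index(site_keys, name="site_key"), columns=samples, dtype=float
    )
    direction_by_key = {rec.site_key: rec.direction for rec in bundle.ptm_records}
    protein_by_key = {rec.site_key: rec.protein for rec in bundle.ptm_records}
    for key in site_keys:
        base = expr.loc[protein_by_key[key]].to_numpy(dtype=float)
        values = base + config.baseline_sd * rng.standard_normal(len(samples))
        if key in intended_by_key:
            sign = 1.0 if direction_by_key[key] == "added" else -1.0
            if intended_by_key[key] == "discordant":
                sign = -sign
            values = values + sign * shift * b_cols
        ptm.loc[key] = values

    if config.missing_rate > 0:
        expr[rng.random(expr.shape) < config.missing_rate] = np.nan
        ptm[rng.random(ptm.shape) < config.missing_rate] = np.nan
    return expr, ptm, design


def score_recovery(results: Sequence, truth: TruthTable) -> tuple:
    """(sensitivity, false-discovery fraction) of selected triples against
    the planted truth; the FDR fraction is 0 when nothing is selected."""
    planted = set(truth.planted_triples)
    selected = {
        (r.triple.ligand, r.triple.receptor, r.triple.pathway_id) for r in results if r.selected
    }
    sensitivity = len(selected & planted) / len(planted) if planted else 0.0
    fdr = len(selected - planted) / len(selected) if selected else 0.0
    return sensitivity, fdr
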