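"""Readers, writers and exporters.

Everything is plain text: TSV for tables and matrices, SIF for the
network export, YAML for config echoes, JSON for run metadata.  Every
writer here has a matching reader and the pair is a fixpoint (tested).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .infer import LRIResult, LRITriple, PTMEvent
from .reference import PTMRefRecord, ReferenceBundle
from .sitekey import parse_site_key
from .stats import ClusterDesign

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "write_bundle",
    "write_ptm_reference",
    "results_to_frame",
    "events_to_frame",
    "write_results_dir",
    "load_results_dir",
    "export_cytoscape",
    "export_significance_comparison",
]

RESULT_COLUMNS = [
    "ligand", "receptor", "pathway_id", "pathway_name", "n_targets",
    "p_ligand", "p_receptor", "p_pathway", "p_overall", "q_value",
    "n_ptm_events", "n_concordant", "n_discordant",
    "p_ptm_pathway", "q_ptm", "selected", "selection_reason",
]

EVENT_COLUMNS = [
    "ligand", "receptor", "pathway_id", "protein", "residue", "position",
    "ptm_type", "direction", "enzyme", "delta", "p_value", "concordance",
]


def read_matrix(path: Path) -> pd.DataFrame:
    """TSV matrix: first column is the row key, other columns are samples.
    Empty cells and ``NA`` are missing."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path: Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_design(path: Path) -> ClusterDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "label"} <= set(df.columns):
        raise ValueError(f"{path}: design table needs 'sample' and 'label' columns")
    return ClusterDesign(
        sample_ids=list(df["sample"]),
        labels=dict(zip(df["sample"], df["label"])),
    )


def write_design(design: ClusterDesign, path: Path) -> None:
    pd.DataFrame(
        {"sample": design.sample_ids, "label": [design.labels.get(s, "unused") for s in design.sample_ids]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference bundle


def write_bundle(bundle: ReferenceBundle, directory: Path) -> None:
    """Write the four bundle tables in the schema the loader expects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(p.ligand, p.receptor, p.source) for p in bundle.lr_pairs],
        columns=["ligand", "receptor", "source"],
    ).to_csv(directory / "lr_pairs.tsv", sep="\t", index=False)
    rows = [
        (pw.pathway_id, pw.name, pw.source, m)
        for pw in bundle.pathways
        for m in sorted(pw.members)
    ]
    pd.DataFrame(rows, columns=["pathway_id", "name", "source", "member"]).to_csv(
        directory / "pathways.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(e.source, e.target, int(e.directed)) for e in bundle.network.edges],
        columns=["source", "target", "directed"],
    ).to_csv(directory / "network.tsv", sep="\t", index=False)
    write_ptm_reference(bundle.ptm_records, directory / "ptm_reference.tsv")


def write_ptm_reference(records: Sequence[PTMRefRecord], path: Path) -> None:
    pd.DataFrame(
        [
            (r.protein, r.residue, r.position, r.ptm_type, r.direction, r.enzyme, r.pathway_id)
            for r in records
        ],
        columns=["protein", "residue", "position", "ptm_type", "direction", "enzyme", "pathway_id"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables


def results_to_frame(results: Sequence[LRIResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.triple
        conc = [e.concordant for e in r.events]
        rows.append(
            {
                "ligand": t.ligand,
                "receptor": t.receptor,
                "pathway_id": t.pathway_id,
                "pathway_name": t.pathway_name,
                "n_targets": len(t.targets),
                "p_ligand": t.p_ligand,
                "p_receptor": t.p_receptor,
                "p_pathway": t.p_pathway,
                "p_overall": t.p_overall,
                "q_value": t.q_value,
                "n_ptm_events": len(r.events),
                "n_concordant": conc.count("concordant"),
                "n_discordant": conc.count("discordant"),
                "p_ptm_pathway": r.p_ptm_pathway,
                "q_ptm": r.q_ptm,
                "selected": r.selected,
                "selection_reason": r.selection_reason,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def events_to_frame(results: Sequence[LRIResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.triple
        for e in r.events:
            rows.append(
                {
                    "ligand": t.ligand,
                    "receptor": t.receptor,
                    "pathway_id": t.pathway_id,
                    "protein": e.record.protein,
                    "residue": e.record.residue,
                    "position": e.record.position,
                    "ptm_type": e.record.ptm_type,
                    "direction": e.record.direction,
                    "enzyme": e.record.enzyme,
                    "delta": e.delta,
                    "p_value": e.p_value,
                    "concordance": e.concordant,
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_results_dir(results: Sequence[LRIResult], directory: Path, metadata: dict | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    results_to_frame(results).to_csv(directory / "results.tsv", sep="\t", index=False, na_rep="NA")
    events_to_frame(results).to_csv(directory / "events.tsv", sep="\t", index=False, na_rep="NA")
    if metadata is not None:
        (directory / "run_meta.json").write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")


def load_results_dir(directory: Path) -> list:
    """Rebuild LRIResult objects from a written results directory.

    Target sets are not serialized; reconstructed triples carry an empty
    target set and the recorded ``n_targets`` is only present in the TSV.
    Sufficient for crosstalk, annotation and the exporters.
    """
    directory = Path(directory)
    res_df = pd.read_csv(
        directory / "results.tsv", sep="\t", na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    ev_df = pd.read_csv(
        directory / "events.tsv", sep="\t", na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    events_by_triple: dict = {}
    for row in ev_df.itertuples(index=False):
        rec = PTMRefRecord(
            protein=row.protein,
            residue=row.residue,
            position=int(row.position),
            ptm_type=row.ptm_type,
            direction=row.direction,
            enzyme="" if (isinstance(row.enzyme, float) and math.isnan(row.enzyme)) else str(row.enzyme),
            pathway_id=row.pathway_id,
        )
        ev = PTMEvent(
            record=rec,
            delta=float(row.delta),
            p_value=float(row.p_value),
            enzyme_detected=bool(rec.enzyme),
            substrate_detected=True,
            concordant=row.concordance,
        )
        events_by_triple.setdefault((row.ligand, row.receptor, row.pathway_id), []).append(ev)
    results = []
    for row in res_df.itertuples(index=False):
        triple = LRITriple(
            ligand=row.ligand,
            receptor=row.receptor,
            pathway_id=row.pathway_id,
            pathway_name="" if (isinstance(row.pathway_name, float) and math.isnan(row.pathway_name)) else str(row.pathway_name),
            targets=frozenset(),
            p_ligand=float(row.p_ligand),
            p_receptor=float(row.p_receptor),
            p_pathway=float(row.p_pathway),
            p_overall=float(row.p_overall),
            ligand_delta=float("nan"),
            receptor_delta=float("nan"),
            q_value=float(row.q_value),
        )
        results.append(
            LRIResult(
                triple=triple,
                events=events_by_triple.get((row.ligand, row.receptor, row.pathway_id), []),
                p_ptm_pathway=float(row.p_ptm_pathway),
                q_ptm=float(row.q_ptm),
                selected=bool(row.selected),
                selection_reason=row.selection_reason,
            )
        )
    return results


# ---------------------------------------------------------------------------
# exporters


def export_cytoscape(results: Sequence[LRIResult], out_prefix: Path) -> dict:
    """SIF + node/edge attribute tables for network editing tools.

    Edges: ligand->receptor typed ``LR``, receptor->target typed ``RT``;
    duplicates collapse.  Returns the written paths.  Empty results give
    header-only files and a warning.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if not results:
        logger.warning("export_cytoscape: empty result list")
    edges: dict = {}
    node_roles: dict = {}
    node_delta: dict = {}
    for r in results:
        t = r.triple
        conc = [e.concordant for e in r.events]
        key = (t.ligand, "LR", t.receptor)
        edges.setdefault(key, {"p_overall": t.p_overall,
                               "n_concordant": conc.count("concordant"),
                               "n_discordant": conc.count("discordant")})
        node_roles.setdefault(t.ligand, "ligand")
        node_roles.setdefault(t.receptor, "receptor")
        node_delta.setdefault(t.ligand, t.ligand_delta)
        node_delta.setdefault(t.receptor, t.receptor_delta)
        for target in sorted(t.targets):
            edges.setdefault((t.receptor, "RT", target),
                             {"p_overall": t.p_overall, "n_concordant": 0, "n_discordant": 0})
            node_roles.setdefault(target, "target")
            node_delta.setdefault(target, float("nan"))
    sif_path = out_prefix.with_suffix(".sif")
    with open(sif_path, "w") as fh:
        for src, kind, dst in edges:
            fh.write(f"{src}\t{kind}\t{dst}\n")
    nodes_path = Path(str(out_prefix) + "_nodes.tsv")
    pd.DataFrame(
        [(n, node_roles[n], node_delta[n]) for n in node_roles],
        columns=["node", "role", "delta"],
    ).to_csv(nodes_path, sep="\t", index=False, na_rep="NA")
    edges_path = Path(str(out_prefix) + "_edges.tsv")
    pd.DataFrame(
        [
            (src, kind, dst, attrs["p_overall"], attrs["n_concordant"], attrs["n_discordant"])
            for (src, kind, dst), attrs in edges.items()
        ],
        columns=["source", "interaction", "target", "p_overall", "n_concordant", "n_discordant"],
    ).to_csv(edges_path, sep="\t", index=False, na_rep="NA")
    return {"sif": sif_path, "nodes": nodes_path, "edges": edges_path}


def export_significance_comparison(results: Sequence[LRIResult]) -> pd.DataFrame:
    """Per-pathway expression-vs-PTM significance table.

    Triples sharing a pathway are merged: mean -log10 of the expression
    pathway p, mean -log10 of the PTM pathway p (missing when no triple
    of the pathway has events), total event count, and the majority
    concordance call (``mixed`` on ties).
    """
    by_pathway: dict = {}
    for r in results:
        by_pathway.setdefault((r.triple.pathway_id, r.triple.pathway_name), []).append(r)
    rows = []
    for (pid, name), group in sorted(by_pathway.items()):
        expr_logs = [-math.log10(r.triple.p_pathway) for r in group if r.triple.p_pathway > 0]
        ptm_logs = [
            -math.log10(r.p_ptm_pathway)
            for r in group
            if not math.isnan(r.p_ptm_pathway) and r.p_ptm_pathway > 0
        ]
        events = [e for r in group for e in r.events]
        n_conc = sum(e.concordant == "concordant" for e in events)
        n_disc = sum(e.concordant == "discordant" for e in events)
        if not events:
            flag = "none"
        elif n_conc > n_disc:
            flag = "concordant"
        elif n_disc > n_conc:
            flag = "discordant"
        else:
            flag = "mixed"
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": name,
                "n_triples": len(group),
                "mean_minus_log10_p_expr": float(np.mean(expr_logs)) if expr_logs else float("nan"),
                "mean_minus_log10_p_ptm": float(np.mean(ptm_logs)) if ptm_logs else float("nan"),
                "n_ptm_events": len(events),
                "concordance": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "pathway_name", "n_triples",
            "mean_minus_log10_p_expr", "mean_minus_log10_p_ptm",
            "n_ptm_events", "concordance",
        ],
    )


# ---------------------------------------------------------------------------
# config echo


def write_config_echo(config_obj, path: Path) -> None:
    from dataclasses import asdict, is_dataclass

    data = asdict(config_obj) if is_dataclass(config_obj) else dict(config_obj)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_config_echo(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
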