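"""Dedicated PTM analyses: cross-PTM-type crosstalk and PhosphoSitePlus
annotation.

Crosstalk integrates two completed runs performed with different PTM
types and reports the pathways, LRIs and substrate proteins carrying
events in both.  The PhosphoSitePlus (PSP) parser understands the
vendor's flat-file dialect (three preamble lines before the header,
optionally gzip-compressed, ``MOD_RSD`` tokens like ``Y187-p``); the
annotation join is a left join on (gene symbol, residue+position) that
never drops or reorders events.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CrosstalkReport",
    "crosstalk",
    "PSPAnnotation",
    "parse_psp_file",
    "annotate_events_psp",
]

# MOD_RSD suffix -> modification type
_PSP_TYPE = {
    "p": "phosphorylation",
    "ub": "ubiquitination",
    "ac": "acetylation",
    "me": "methylation",
    "m1": "methylation",
    "m2": "methylation",
    "m3": "methylation",
    "sm": "sumoylation",
    "gl": "glycosylation",
    "ga": "glycosylation",
    "gc": "glycosylation",
}

_KIND_KEY_COLUMNS = {
    "regulatory": "MOD_RSD",
    "kinase_substrate": "SUB_MOD_RSD",
    "disease": "MOD_RSD",
}


@dataclass
class CrosstalkReport:
    shared_pathways: list = field(default_factory=list)
    shared_lris: list = field(default_factory=list)          # (ligand, receptor)
    dual_modified_proteins: list = field(default_factory=list)


def _event_sets(results: Sequence, selected_only: bool) -> tuple:
    pathways, lris, proteins, types = set(), set(), set(), set()
    for r in results:
        if selected_only and not r.selected:
            continue
        if not r.events:
            continue
        t = r.triple
        pathways.add(t.pathway_id)
        lris.add((t.ligand, t.receptor))
        for e in r.events:
            proteins.add(e.record.protein)
            types.add(e.record.ptm_type)
    return pathways, lris, proteins, types


def crosstalk(results_a: Sequence, results_b: Sequence, selected_only: bool = True) -> CrosstalkReport:
    """Intersect two runs' event-bearing pathways, LRIs and substrates.

    The two runs are expected to come from references of different PTM
    types; overlapping types only produce a warning.
    """
    pw_a, lri_a, prot_a, types_a = _event_sets(results_a, selected_only)
    pw_b, lri_b, prot_b, types_b = _event_sets(results_b, selected_only)
    if types_a & types_b:
        logger.warning("crosstalk: both runs carry events of type(s) %s", sorted(types_a & types_b))
    return CrosstalkReport(
        shared_pathways=sorted(pw_a & pw_b),
        shared_lris=sorted(lri_a & lri_b),
        dual_modified_proteins=sorted(prot_a & prot_b),
    )


# ---------------------------------------------------------------------------
# PhosphoSitePlus


@dataclass
class PSPAnnotation:
    site_group_id: str = ""
    kinase: str = ""
    domain: str = ""
    functions: str = ""
    processes: str = ""
    diseases: str = ""
    alteration: str = ""
    notes: str = ""

    def empty(self) -> bool:
        return not any(
            (self.site_group_id, self.kinase, self.domain, self.functions,
             self.processes, self.diseases, self.alteration, self.notes)
        )


def _open_text(path: Path):
    raw = open(path, "rb").read(2)
    if raw == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _split_mod_rsd(token: str) -> tuple:
    """``Y187-p`` -> (``Y187``, ``phosphorylation``); unknown suffixes are
    kept verbatim, a missing suffix gives an empty type."""
    token = str(token).strip()
    if "-" in token:
        site, suffix = token.rsplit("-", 1)
        return site.upper(), _PSP_TYPE.get(suffix.lower(), suffix.lower())
    return token.upper(), ""


def parse_psp_file(path: Path, kind: str) -> list:
    """Parse a PhosphoSitePlus flat file into keyed records.

    ``kind`` is one of ``regulatory``, ``kinase_substrate`` or
    ``disease``.  The preamble (3 lines in the vendor files) is skipped
    by locating the header row within the first 10 lines; non-human rows
    are excluded.  Each record carries ``gene``, ``site`` (e.g. Y187),
    ``ptm_type`` and kind-specific payload fields.
    """
    if kind not in _KIND_KEY_COLUMNS:
        raise ValueError(f"kind must be one of {sorted(_KIND_KEY_COLUMNS)}, got {kind!r}")
    key_col = _KIND_KEY_COLUMNS[kind]
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines[:10]):
        if key_col in line.split("\t"):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(
            f"{path}: header row with column {key_col!r} not found within the first 10 lines; "
            "expected the PhosphoSitePlus flat-file dialect (preamble lines, then a tab-separated header)"
        )
    df = pd.read_csv(
        _io.StringIO("\n".join(lines[header_idx:])), sep="\t", dtype=str, keep_default_na=False
    )

    def human(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
        for c in cols:
            if c in df.columns:
                df = df[df[c].str.strip().str.lower() == "human"]
        return df

    records: list = []
    if kind == "kinase_substrate":
        df = human(df, ["KIN_ORGANISM", "SUB_ORGANISM"])
        for row in df.itertuples(index=False):
            d = row._asdict()
            site, ptm_type = _split_mod_rsd(d.get("SUB_MOD_RSD", ""))
            records.append(
                {
                    "gene": str(d.get("SUB_GENE", "")).upper(),
                    "site": site,
                    "ptm_type": ptm_type or "phosphorylation",
                    "site_group_id": d.get("SITE_GRP_ID", ""),
                    "kinase": d.get("KINASE", ""),
                    "domain": d.get("DOMAIN", ""),
                }
            )
    else:
        df = human(df, ["ORGANISM"])
        for row in df.itertuples(index=False):
            d = row._asdict()
            site, ptm_type = _split_mod_rsd(d.get("MOD_RSD", ""))
            rec = {
                "gene": str(d.get("GENE", "")).upper(),
                "site": site,
                "ptm_type": ptm_type,
                "site_group_id": d.get("SITE_GRP_ID", ""),
            }
            if kind == "regulatory":
                rec.update(
                    {
                        "domain": d.get("DOMAIN", ""),
                        "functions": d.get("ON_FUNCTION", ""),
                        "processes": d.get("ON_PROCESS", ""),
                        "notes": d.get("NOTES", ""),
                    }
                )
            else:  # disease
                rec.update(
                    {
                        "diseases": d.get("DISEASE", ""),
                        "alteration": d.get("ALTERATION", ""),
                        "notes": d.get("NOTES", ""),
                    }
                )
            records.append(rec)
    return records


def annotate_events_psp(events: Sequence, psp: Mapping[str, Sequence[dict]]) -> list:
    """Left-join PSP records onto events by (protein, residue+position).

    ``psp`` maps parser kinds to their record lists.  Returns
    ``[(event, PSPAnnotation | None), ...]`` preserving order and length;
    events without any PSP match get ``None``.
    """
    index: dict = {}
    for kind in ("regulatory", "kinase_substrate", "disease"):
        for rec in psp.get(kind, []):
            key = (rec["gene"], rec["site"])
            ann = index.setdefault(key, PSPAnnotation())
            if not ann.site_group_id:
                ann.site_group_id = rec.get("site_group_id", "")
            if kind == "kinase_substrate":
                ann.kinase = ann.kinase or rec.get("kinase", "")
                ann.domain = ann.domain or rec.get("domain", "")
            elif kind == "regulatory":
                ann.domain = ann.domain or rec.get("domain", "")
                ann.functions = ann.functions or rec.get("functions", "")
                ann.processes = ann.processes or rec.get("processes", "")
                ann.notes = ann.notes or rec.get("notes", "")
            else:
                ann.diseases = ann.diseases or rec.get("diseases", "")
                ann.alteration = ann.alteration or rec.get("alteration", "")
                ann.notes = ann.notes or rec.get("notes", "")
    out = []
    for e in events:
        key = (e.record.protein, f"{e.record.residue}{e.record.position}")
        ann = index.get(key)
        out.append((e, None if ann is None or ann.empty() else ann))
    return out
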