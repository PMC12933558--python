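"""Reference data model: ligand-receptor pairs, pathways, the partially
directed intracellular network, and site-level PTM reference records.

The receptor-target relation is derived here by pathway-restricted
traversal: targets of a receptor within a pathway are the proteins
reachable from the receptor in the subnetwork induced by edges whose
both endpoints belong to the pathway, following directed edges forward
and undirected edges both ways.  The receptor itself is never its own
target.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sitekey import format_site_key

logger = logging.getLogger(__name__)

__all__ = [
    "LRPair",
    "PathwayDef",
    "Edge",
    "IntracellularNetwork",
    "PTMRefRecord",
    "ReferenceBundle",
    "load_reference_bundle",
    "load_bundle_dir",
    "pathway_subnetwork",
    "receptor_targets",
    "filter_pathways",
]

DIRECTIONS = ("added", "removed")


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor must be non-empty")


@dataclass(frozen=True)
class PathwayDef:
    pathway_id: str
    name: str
    source: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id}: empty member set")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    directed: bool = True


@dataclass
class IntracellularNetwork:
    """Partially directed protein interaction network.

    Self-loops are dropped and an undirected edge is stored once with
    canonically ordered endpoints.
    """

    edges: list = field(default_factory=list)

    def __post_init__(self) -> None:
        canonical: dict = {}
        dropped_loops = 0
        for e in self.edges:
            if e.source == e.target:
                dropped_loops += 1
                continue
            if e.directed:
                key = (e.source, e.target, True)
                edge = e
            else:
                a, b = sorted((e.source, e.target))
                key = (a, b, False)
                edge = Edge(a, b, False)
            canonical[key] = edge
        if dropped_loops:
            logger.warning("dropped %d self-loop edge(s)", dropped_loops)
        self.edges = list(canonical.values())

    @property
    def nodes(self) -> frozenset:
        out = set()
        for e in self.edges:
            out.add(e.source)
            out.add(e.target)
        return frozenset(out)

    def successors(self) -> dict:
        """Forward adjacency: directed edges forward, undirected both ways."""
        adj: dict = {}
        for e in self.edges:
            adj.setdefault(e.source, set()).add(e.target)
            if not e.directed:
                adj.setdefault(e.target, set()).add(e.source)
        return adj


@dataclass(frozen=True)
class PTMRefRecord:
    """One expected modification event: a site on a substrate protein,
    a direction (added/removed), the catalyzing enzyme (may be empty),
    and the pathway the underlying reaction belongs to."""

    protein: str
    residue: str
    position: int
    ptm_type: str
    direction: str
    enzyme: str = ""
    pathway_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")

    @property
    def site_key(self) -> str:
        return format_site_key(self.protein, self.residue, self.position, self.ptm_type)


@dataclass
class ReferenceBundle:
    lr_pairs: list
    pathways: list
    network: IntracellularNetwork
    ptm_records: list = field(default_factory=list)

    def pathway_by_id(self, pathway_id: str) -> PathwayDef:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


# ---------------------------------------------------------------------------
# loading


def _read_tsv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def load_reference_bundle(paths: Mapping[str, Path]) -> ReferenceBundle:
    """Load and validate a reference bundle from TSV tables.

    ``paths`` maps table names (``lr_pairs``, ``pathways``, ``network``,
    optionally ``ptm_reference``) to file paths.  Protein symbols are
    upper-cased on load.  Duplicate rows are dropped with a logged count;
    PTM records pointing at unknown pathways are dropped with a warning.
    """
    for key in ("lr_pairs", "pathways", "network"):
        if key not in paths:
            raise FileNotFoundError(f"reference bundle is missing the {key!r} table")

    lr_df = _read_tsv(paths["lr_pairs"], ["ligand", "receptor", "source"])
    pairs: list = []
    seen = set()
    for row in lr_df.itertuples(index=False):
        key = (row.ligand.upper(), row.receptor.upper())
        if key in seen:
            continue
        seen.add(key)
        pairs.append(LRPair(key[0], key[1], row.source))
    if len(pairs) < len(lr_df):
        logger.info("dropped %d duplicate LR pair row(s)", len(lr_df) - len(pairs))

    pw_df = _read_tsv(paths["pathways"], ["pathway_id", "name", "source", "member"])
    pathways: list = []
    for pid, grp in pw_df.groupby("pathway_id", sort=False):
        names = grp["name"].unique()
        sources = grp["source"].unique()
        pathways.append(
            PathwayDef(
                pathway_id=pid,
                name=names[0],
                source=sources[0],
                members=frozenset(m.upper() for m in grp["member"] if m),
            )
        )

    net_df = _read_tsv(paths["network"], ["source", "target", "directed"])
    edges = [
        Edge(row.source.upper(), row.target.upper(), directed=row.directed.strip() in ("1", "true", "True"))
        for row in net_df.itertuples(index=False)
    ]
    network = IntracellularNetwork(edges)

    ptm_records: list = []
    if "ptm_reference" in paths:
        ptm_df = _read_tsv(
            paths["ptm_reference"],
            ["protein", "residue", "position", "ptm_type", "direction", "enzyme", "pathway_id"],
        )
        known = {p.pathway_id for p in pathways}
        seen_rec = set()
        n_unknown = 0
        for row in ptm_df.itertuples(index=False):
            if row.pathway_id not in known:
                n_unknown += 1
                continue
            rec = PTMRefRecord(
                protein=row.protein.upper(),
                residue=row.residue.upper(),
                position=int(row.position),
                ptm_type=row.ptm_type.lower(),
                direction=row.direction,
                enzyme=row.enzyme.upper(),
                pathway_id=row.pathway_id,
            )
            if rec in seen_rec:
                continue
            seen_rec.add(rec)
            ptm_records.append(rec)
        if n_unknown:
            logger.warning("dropped %d PTM record(s) referencing unknown pathways", n_unknown)
        n_dup = len(ptm_df) - n_unknown - len(ptm_records)
        if n_dup:
            logger.info("dropped %d duplicate PTM record row(s)", n_dup)

    return ReferenceBundle(lr_pairs=pairs, pathways=pathways, network=network, ptm_records=ptm_records)


def load_bundle_dir(directory: Path) -> ReferenceBundle:
    """Load a bundle from a directory of conventionally named tables."""
    directory = Path(directory)
    paths = {
        "lr_pairs": directory / "lr_pairs.tsv",
        "pathways": directory / "pathways.tsv",
        "network": directory / "network.tsv",
    }
    ptm = directory / "ptm_reference.tsv"
    if ptm.exists():
        paths["ptm_reference"] = ptm
    return load_reference_bundle(paths)


# ---------------------------------------------------------------------------
# traversal


def pathway_subnetwork(network: IntracellularNetwork, pathway: PathwayDef) -> IntracellularNetwork:
    """Edge-induced subnetwork keeping edges with both endpoints in the pathway."""
    members = pathway.members
    kept = [e for e in network.edges if e.source in members and e.target in members]
    return IntracellularNetwork(kept)


def receptor_targets(network: IntracellularNetwork, pathway: PathwayDef, receptor: str) -> set:
    """Proteins reachable from ``receptor`` within the pathway-restricted
    network (directed edges forward, undirected both ways), excluding the
    receptor itself.  Empty set when the receptor is not a pathway member.
    """
    if receptor not in pathway.members:
        return set()
    adj = pathway_subnetwork(network, pathway).successors()
    seen = {receptor}
    queue = deque([receptor])
    while queue:
        node = queue.popleft()
        for nxt in adj.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    seen.discard(receptor)
    return seen


def filter_pathways(
    pathways: Iterable[PathwayDef],
    target_sets: Mapping[str, set],
    min_targets: int = 5,
    max_members: int = 400,
) -> list:
    """Keep pathways with at least ``min_targets`` derived targets and at
    most ``max_members`` members.  ``target_sets`` maps pathway_id to the
    target set the caller derived (possibly intersected with detected rows).
    """
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    if max_members < min_targets:
        raise ValueError("max_members must be >= min_targets")
    kept = []
    for p in pathways:
        targets = target_sets.get(p.pathway_id, set())
        if len(targets) >= min_targets and len(p.members) <= max_members:
            kept.append(p)
    return kept
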