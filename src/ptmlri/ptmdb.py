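"""Build the PTM-pathway reference from a reaction-graph export.

Reactions come from a neutral JSON export of a biochemical reaction
graph (one object per reaction, with input/output entities carrying
annotated modification sites).  For every retained reaction, the
modification sites of each protein are diffed between the reactant and
product states: a site present only on the output side was *added* by
the reaction, one present only on the input side was *removed*.  Each
diffed site is expanded over the reaction's catalysts and pathways into
:class:`~ptmlri.reference.PTMRefRecord` rows.

Converter note: to produce ``reactions.json`` from a live graph
database, export one object per reaction with fields ``reaction_id``,
``is_candidate``, ``pathway_ids``, ``catalysts`` and ``inputs`` /
``outputs`` lists of ``{protein, complex_id, complex_size, mods:
[{residue, position, ptm_type}]}``.  This module never talks to a
database server.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .reference import PTMRefRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ModSite",
    "ReactionEntity",
    "Reaction",
    "BuilderConfig",
    "load_reactions_json",
    "filter_reactions",
    "diff_ptm_positions",
    "build_ptm_reference",
]

UNASSIGNED_PATHWAY = "UNASSIGNED"


@dataclass(frozen=True)
class ModSite:
    residue: str
    position: int
    ptm_type: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass
class ReactionEntity:
    protein: str
    mods: frozenset = frozenset()
    complex_id: str | None = None
    complex_size: int | None = None

    def __post_init__(self) -> None:
        self.mods = frozenset(self.mods)
        if self.complex_size is not None and self.complex_size < 1:
            raise ValueError("complex_size must be >= 1 when present")


@dataclass
class Reaction:
    reaction_id: str
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    catalysts: list = field(default_factory=list)
    pathway_ids: list = field(default_factory=list)
    is_candidate: bool = False


@dataclass
class BuilderConfig:
    max_complex_size: int = 10

    def __post_init__(self) -> None:
        if self.max_complex_size < 1:
            raise ValueError("max_complex_size must be >= 1")


def load_reactions_json(path: Path) -> list:
    """Read the neutral reaction export (schema in the module docstring)."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: top-level JSON value must be a list of reactions")
    reactions = []
    for i, obj in enumerate(raw):
        try:
            reactions.append(
                Reaction(
                    reaction_id=str(obj["reaction_id"]),
                    is_candidate=bool(obj.get("is_candidate", False)),
                    pathway_ids=[str(p) for p in obj.get("pathway_ids", [])],
                    catalysts=[str(c).upper() for c in obj.get("catalysts", [])],
                    inputs=[_entity(e) for e in obj.get("inputs", [])],
                    outputs=[_entity(e) for e in obj.get("outputs", [])],
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: reaction #{i}: {exc}") from exc
    return reactions


def _entity(obj: dict) -> ReactionEntity:
    return ReactionEntity(
        protein=str(obj["protein"]).upper(),
        mods=frozenset(
            ModSite(str(m["residue"]).upper(), int(m["position"]), str(m["ptm_type"]).lower())
            for m in obj.get("mods", [])
        ),
        complex_id=obj.get("complex_id"),
        complex_size=obj.get("complex_size"),
    )


def filter_reactions(reactions: Iterable[Reaction], config: BuilderConfig | None = None) -> list:
    """Drop candidate reactions; within retained ones, drop entities in
    complexes strictly larger than ``max_complex_size`` (a complex of
    exactly the threshold size is retained)."""
    config = config or BuilderConfig()
    out = []
    for rxn in reactions:
        if rxn.is_candidate:
            continue
        keep = lambda e: e.complex_size is None or e.complex_size <= config.max_complex_size
        out.append(
            Reaction(
                reaction_id=rxn.reaction_id,
                inputs=[e for e in rxn.inputs if keep(e)],
                outputs=[e for e in rxn.outputs if keep(e)],
                catalysts=list(rxn.catalysts),
                pathway_ids=list(rxn.pathway_ids),
                is_candidate=False,
            )
        )
    return out


def diff_ptm_positions(input_entity: ReactionEntity, output_entity: ReactionEntity) -> list:
    """Diff modification sites between reactant and product states of one
    protein.  Returns ``[(ModSite, direction), ...]`` where direction is
    ``added`` for output-only sites and ``removed`` for input-only sites.
    """
    if input_entity.protein != output_entity.protein:
        raise ValueError(
            f"entity pairing bug: {input_entity.protein!r} vs {output_entity.protein!r}"
        )
    added = sorted(output_entity.mods - input_entity.mods, key=_site_order)
    removed = sorted(input_entity.mods - output_entity.mods, key=_site_order)
    return [(s, "added") for s in added] + [(s, "removed") for s in removed]


def _site_order(site: ModSite) -> tuple:
    return (site.position, site.residue, site.ptm_type)


def _mods_by_protein(entities: Sequence[ReactionEntity]) -> dict:
    # a protein occurring several times on one side gets its mods unioned
    out: dict = {}
    for e in entities:
        out[e.protein] = out.get(e.protein, frozenset()) | e.mods
    return out


def build_ptm_reference(reactions: Iterable[Reaction], config: BuilderConfig | None = None) -> list:
    """Emit deduplicated PTMRefRecords for every retained reaction, diffed
    site, catalyst and pathway.

    Reactions without a catalyst emit records with an empty enzyme field;
    reactions without pathways are emitted under the ``UNASSIGNED``
    pathway (dropped later at bundle load).  Proteins appearing on only
    one side of a reaction are treated as fully added (output only) or
    fully removed (input only) and logged.
    """
    config = config or BuilderConfig()
    records: list = []
    seen: set = set()
    n_unpaired = 0
    for rxn in filter_reactions(reactions, config):
        in_mods = _mods_by_protein(rxn.inputs)
        out_mods = _mods_by_protein(rxn.outputs)
        diffs: list = []
        for protein in sorted(set(in_mods) | set(out_mods)):
            if protein not in in_mods or protein not in out_mods:
                n_unpaired += 1
            a = ReactionEntity(protein, in_mods.get(protein, frozenset()))
            b = ReactionEntity(protein, out_mods.get(protein, frozenset()))
            diffs.extend((protein, site, direction) for site, direction in diff_ptm_positions(a, b))
        if not diffs:
            continue
        enzymes = rxn.catalysts or [""]
        pathways = rxn.pathway_ids or [UNASSIGNED_PATHWAY]
        for protein, site, direction in diffs:
            for enzyme in enzymes:
                for pathway_id in pathways:
                    rec = PTMRefRecord(
                        protein=protein,
                        residue=site.residue,
                        position=site.position,
                        ptm_type=site.ptm_type,
                        direction=direction,
                        enzyme=enzyme,
                        pathway_id=pathway_id,
                    )
                    if rec not in seen:
                        seen.add(rec)
                        records.append(rec)
    if n_unpaired:
        logger.info("%d entity(ies) appeared on a single reaction side; treated as fully added/removed", n_unpaired)
    return records
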