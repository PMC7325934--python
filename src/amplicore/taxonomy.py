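"""Rank-aware taxonomy assignment with identity gates.

Feature representatives are searched against a lineage-annotated reference
(QIIME-style 7-rank headers) with a 90% identity floor.  The assignment
walks ranks top-down, stops before the first unnamed rank (a reference
annotated "...; f__Ruminococcaceae; g__; s__" supports kingdom-family
only), and additionally withholds genus below 97% identity and species
below 99%.  Ties among equal-identity best hits resolve to the lowest
common named lineage of the tied references.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .subotu import ClusterConfig, FeatureTable, identity_at_least, pairwise_identity
from .synthetic_data import RANKS, ReferenceDB

__all__ = [
    "RANKS",
    "Hit",
    "TaxonomyAssignment",
    "search_reference",
    "assign_lineage",
    "classify_features",
    "collapse_at_rank",
    "annotation_rate",
]

MIN_IDENTITY_FLOOR = 0.90
GENUS_GATE = 0.97
SPECIES_GATE = 0.99
_GENUS_INDEX = RANKS.index("genus")
_SPECIES_INDEX = RANKS.index("species")
_FAMILY_INDEX = RANKS.index("family")


@dataclass(frozen=True)
class Hit:
    ref_id: str
    identity: float
    lineage: tuple[str, ...]


@dataclass
class TaxonomyAssignment:
    """Assigned (possibly truncated) lineage for one feature."""

    feature_id: str
    lineage: tuple[str, ...]  # named ranks only, length == depth+1 (empty if unassigned)
    identity: float | None
    depth: int | None  # rank index of deepest assigned rank, None if unassigned

    def __post_init__(self) -> None:
        if self.depth is not None:
            if self.identity is None or self.identity < MIN_IDENTITY_FLOOR:
                raise ValueError("assigned features require identity >= 0.90")
            if self.depth >= _GENUS_INDEX and self.identity < GENUS_GATE:
                raise ValueError("genus-depth assignment requires identity >= 0.97")
            if self.depth >= _SPECIES_INDEX and self.identity < SPECIES_GATE:
                raise ValueError("species-depth assignment requires identity >= 0.99")
            if len(self.lineage) != self.depth + 1:
                raise ValueError("lineage length inconsistent with depth")

    @property
    def assigned(self) -> bool:
        return self.depth is not None

    def name_at(self, rank_index: int) -> str | None:
        if self.depth is None or rank_index > self.depth:
            return None
        return self.lineage[rank_index]


def search_reference(
    query: str,
    reference: ReferenceDB,
    min_identity: float = MIN_IDENTITY_FLOOR,
    config: ClusterConfig = ClusterConfig(),
) -> list[Hit]:
    """Identity-ranked reference hits at or above the floor.

    Uses the same global-alignment identity as sub-OTU clustering, with the
    exact edit-distance prefilter; results sorted by identity then ref_id.
    """
    if not query:
        raise ValueError("empty query")
    if len(reference) == 0:
        raise ValueError("empty reference database")
    hits = []
    for taxon in reference:
        if config.use_prefilter and not identity_at_least(
            query, taxon.sequence, min_identity
        ):
            continue
        ident = pairwise_identity(query, taxon.sequence, config)
        if ident >= min_identity:
            hits.append(Hit(taxon.ref_id, ident, taxon.lineage))
    hits.sort(key=lambda h: (-h.identity, h.ref_id))
    return hits


def _named_prefix(lineage: tuple[str, ...]) -> tuple[str, ...]:
    named = []
    for name in lineage:
        if name == "":
            break
        named.append(name)
    return tuple(named)


def assign_lineage(feature_id: str, hits: list[Hit]) -> TaxonomyAssignment:
    """Resolve ranked hits into a gated, possibly truncated assignment."""
    if not hits:
        return TaxonomyAssignment(feature_id, (), None, None)
    best = hits[0].identity
    tied = [h for h in hits if abs(h.identity - best) <= 1e-12]
    lineage = _named_prefix(tied[0].lineage)
    for h in tied[1:]:
        other = _named_prefix(h.lineage)
        common = 0
        for a, b in zip(lineage, other):
            if a != b:
                break
            common += 1
        lineage = lineage[:common]
    # identity gates: withhold genus below 0.97, species below 0.99
    max_depth = _SPECIES_INDEX
    if best < SPECIES_GATE:
        max_depth = _GENUS_INDEX
    if best < GENUS_GATE:
        max_depth = _FAMILY_INDEX
    lineage = lineage[: max_depth + 1]
    if not lineage:
        return TaxonomyAssignment(feature_id, (), None, None)
    return TaxonomyAssignment(feature_id, lineage, best, len(lineage) - 1)


def classify_features(
    features: FeatureTable,
    reference: ReferenceDB,
    min_identity: float = MIN_IDENTITY_FLOOR,
    config: ClusterConfig = ClusterConfig(),
) -> dict[str, TaxonomyAssignment]:
    return {
        fid: assign_lineage(
            fid, search_reference(features.representatives[fid], reference, min_identity, config)
        )
        for fid in features.feature_ids
    }


def collapse_at_rank(
    features: FeatureTable,
    assignments: dict[str, TaxonomyAssignment],
    rank: str,
) -> pd.DataFrame:
    """Sum feature counts per named taxon at a rank.

    Features without a name at that rank (unassigned, or truncated above
    it) pool into "unclassified".  Column sums are preserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    idx = RANKS.index(rank)
    groups: dict[str, list[str]] = {}
    for fid in features.feature_ids:
        name = assignments[fid].name_at(idx) if fid in assignments else None
        if fid not in assignments:
            raise ValueError(f"feature {fid} lacks an assignment record")
        groups.setdefault(name if name is not None else "unclassified", []).append(fid)
    rows = {
        taxon: features.counts.loc[fids].sum(axis=0) for taxon, fids in groups.items()
    }
    collapsed = pd.DataFrame(rows).T
    named = sorted(t for t in collapsed.index if t != "unclassified")
    if "unclassified" in collapsed.index:
        named.append("unclassified")
    return collapsed.loc[named]


def annotation_rate(
    features: FeatureTable,
    assignments: dict[str, TaxonomyAssignment],
    domain_rank: str = "kingdom",
) -> pd.Series:
    """Percent of reads per sample in features assigned at the domain rank."""
    idx = RANKS.index(domain_rank)
    assigned = [
        fid
        for fid in features.feature_ids
        if assignments[fid].depth is not None and assignments[fid].depth >= idx
    ]
    totals = features.counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero total reads in sample(s) {bad}: rate undefined")
    hit = features.counts.loc[assigned].sum(axis=0)
    return 100.0 * hit / totals
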