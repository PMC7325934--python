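"""Sub-OTU feature construction from dereplicated amplicon reads.

The sub-OTU approach sits between exact-sequence variants and classic 97%
OTUs: dereplicated sequences with total abundance at or above a seed
threshold (default 10) become *seed* features, and every remaining low-count
sequence is either merged into its nearest seed (global-alignment identity
>= 98%) or retained as an *independent* feature.  Counts are conserved
exactly, so the resulting feature table has the same grand total as the
dereplicated pool.

Identity between two sequences is defined on a global, end-gap-penalized
alignment as (matching columns) / (alignment columns).  The default scores
are match +1, mismatch -1, gap -2.  An exact edit-distance prefilter
(``identity <= L_min / (L_min + d)`` for edit distance ``d``) is used to
skip alignments that provably cannot reach a threshold; it never changes
the result relative to exhaustive all-pairs alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "ClusterConfig",
    "DereplicatedSequence",
    "FeatureTable",
    "pairwise_identity",
    "identity_at_least",
    "dereplicate",
    "designate_seeds",
    "cluster_to_features",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of seed designation and nearest-seed merging."""

    min_seed_count: int = 10
    min_identity: float = 0.98
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0
    per_sample_seeds: bool = False  # seed threshold applied per sample instead of pooled
    use_prefilter: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_seed_count < 1:
            raise ValueError("min_seed_count must be >= 1")


@dataclass
class DereplicatedSequence:
    """A unique sequence with its per-sample occurrence counts."""

    sequence: str
    counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class FeatureTable:
    """Integer feature-by-sample count table with representative sequences.

    ``provenance`` records whether each feature was an abundance-designated
    seed or an unmerged independent sequence.  ``members`` maps each feature
    to the dereplicated sequences whose counts it absorbed (itself included),
    which downstream truth-tracking uses.
    """

    counts: pd.DataFrame  # features x samples, int
    representatives: dict[str, str]
    provenance: dict[str, str]  # feature id -> "seed" | "independent"
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def _make_aligner(config: ClusterConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match_score
    aligner.mismatch_score = config.mismatch_score
    aligner.open_gap_score = config.gap_score
    aligner.extend_gap_score = config.gap_score
    return aligner


_DEFAULT_CONFIG = ClusterConfig()


def pairwise_identity(
    seq_a: str, seq_b: str, config: ClusterConfig = _DEFAULT_CONFIG
) -> float:
    """Global-alignment identity between two DNA sequences.

    Identity is the number of identical aligned columns divided by the total
    number of alignment columns (mismatches and gap columns both count in
    the denominator), computed on a score-optimal global alignment with the
    configured scores.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    aligner = _make_aligner(config)
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns


def identity_at_least(seq_a: str, seq_b: str, threshold: float) -> bool:
    """Exact prefilter: can the alignment identity possibly reach *threshold*?

    Any alignment has matches <= min(|a|, |b|) and (mismatch + gap) columns
    >= the unit-cost edit distance d, so identity <= L_min / (L_min + d).
    Returns False only when the bound already rules the pair out, hence the
    screen never discards a true hit.
    """
    la, lb = len(seq_a), len(seq_b)
    lmin = min(la, lb)
    d = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    return lmin / (lmin + d) >= threshold


def dereplicate(reads_per_sample: dict[str, list[str]]) -> list[DereplicatedSequence]:
    """Collapse exact duplicate reads into unique sequences with counts.

    Sequences are uppercase-normalized, tallied per sample, and returned in
    deterministic order: decreasing total count, ties broken lexicographically
    by sequence.
    """
    pool: dict[str, dict[str, int]] = {}
    for sample, reads in reads_per_sample.items():
        for read in reads:
            seq = read.upper()
            per_sample = pool.setdefault(seq, {})
            per_sample[sample] = per_sample.get(sample, 0) + 1
    records = [DereplicatedSequence(seq, counts) for seq, counts in pool.items()]
    records.sort(key=lambda r: (-r.total_count, r.sequence))
    return records


def designate_seeds(
    pool: list[DereplicatedSequence], config: ClusterConfig = _DEFAULT_CONFIG
) -> list[DereplicatedSequence]:
    """Select seed sequences: total count >= ``min_seed_count``, in pool order.

    With ``per_sample_seeds`` the threshold must instead be met within at
    least one single sample.
    """
    if config.per_sample_seeds:
        return [
            r
            for r in pool
            if any(c >= config.min_seed_count for c in r.counts.values())
        ]
    return [r for r in pool if r.total_count >= config.min_seed_count]


def cluster_to_features(
    pool: list[DereplicatedSequence],
    seeds: list[DereplicatedSequence],
    config: ClusterConfig = _DEFAULT_CONFIG,
    sample_ids: list[str] | None = None,
) -> FeatureTable:
    """Merge non-seed counts into nearest seeds; build the feature table.

    Every non-seed is compared against all seeds.  If its best identity is
    >= ``min_identity`` its counts are merged into that seed; identity ties
    go to the higher-abundance seed, then to the lexicographically smaller
    sequence.  Non-seeds matching no seed become independent features.
    Counts are conserved exactly.
    """
    seed_seqs = {s.sequence for s in seeds}
    for s in seeds:
        if s.sequence not in {r.sequence for r in pool}:
            raise ValueError("seeds must be a subset of the pool")

    if sample_ids is None:
        seen: list[str] = []
        for rec in pool:
            for sample in rec.counts:
                if sample not in seen:
                    seen.append(sample)
        sample_ids = sorted(seen)

    # feature id per seed, in seed (pool) order
    feature_of_seed: dict[str, str] = {}
    order: list[str] = []
    reps: dict[str, str] = {}
    provenance: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    merged_counts: dict[str, dict[str, int]] = {}

    def _new_feature(rec: DereplicatedSequence, kind: str) -> str:
        fid = f"sotu_{len(order) + 1:05d}"
        order.append(fid)
        reps[fid] = rec.sequence
        provenance[fid] = kind
        members[fid] = [rec.sequence]
        merged_counts[fid] = dict(rec.counts)
        return fid

    for s in seeds:
        feature_of_seed[s.sequence] = _new_feature(s, "seed")

    seed_totals = {s.sequence: s.total_count for s in seeds}
    for rec in pool:
        if rec.sequence in seed_seqs:
            continue
        best: tuple[float, int, str] | None = None  # (identity, count, seq)
        for s in seeds:
            if config.use_prefilter and not identity_at_least(
                rec.sequence, s.sequence, config.min_identity
            ):
                continue
            ident = pairwise_identity(rec.sequence, s.sequence, config)
            if ident < config.min_identity:
                continue
            key = (ident, seed_totals[s.sequence], s.sequence)
            if best is None or (key[0], key[1], _lex_rank(key[2])) > (
                best[0],
                best[1],
                _lex_rank(best[2]),
            ):
                best = key
        if best is None:
            _new_feature(rec, "independent")
        else:
            fid = feature_of_seed[best[2]]
            members[fid].append(rec.sequence)
            for sample, n in rec.counts.items():
                merged_counts[fid][sample] = merged_counts[fid].get(sample, 0) + n

    table = pd.DataFrame(0, index=order, columns=sample_ids, dtype=np.int64)
    for fid, counts in merged_counts.items():
        for sample, n in counts.items():
            table.loc[fid, sample] = n
    return FeatureTable(table, reps, provenance, members)


class _lex_rank(str):
    """Reverse lexicographic comparison so that max() prefers the smaller string."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__gt__(self, str(other))

    def __gt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__lt__(self, str(other))
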