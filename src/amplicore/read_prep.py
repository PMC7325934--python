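"""Read-level quality control for merged amplicon reads.

Rules applied, in order: locate and strip the forward primer (IUPAC-aware,
up to a configured number of mismatches; reads without it are discarded),
strip the reverse primer if present, trim leading/trailing N runs, reject
reads with internal ambiguous bases, reject on mean per-base error
probability (from FASTQ qualities) above threshold, and reject trimmed
reads shorter than the minimum length.  A separate pass flags two-parent
crossover chimeras among dereplicated sequences before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import IUPAC_SETS, iupac_mismatches, revcomp
from .subotu import ClusterConfig, DereplicatedSequence, pairwise_identity

__all__ = [
    "PrepConfig",
    "PrepResult",
    "PrepReport",
    "prepare_read",
    "prepare_sample",
    "detect_chimeras",
    "prep_stats",
]

REASONS = ("alphabet", "primer", "ambiguous", "quality", "length")


@dataclass(frozen=True)
class PrepConfig:
    forward_primer: str = "GTGYCAGCMGCCGCGGTAA"
    reverse_primer: str = "CCGYCAATTYMTTTRAGTTT"
    max_primer_mismatches: int = 2
    min_length: int = 150
    per_base_error_threshold: float = 0.01
    chimera_abundance_skew: float = 2.0
    chimera_segment_identity: float = 0.99
    chimera_parent_identity_ceiling: float = 0.95
    require_forward_primer: bool = True

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not (0.0 < self.per_base_error_threshold < 1.0):
            raise ValueError("per_base_error_threshold must be in (0, 1)")


@dataclass
class PrepResult:
    retained: bool
    sequence: str | None = None
    reason: str | None = None


def _find_primer(read: str, primer: str, max_mm: int) -> tuple[int, int] | None:
    """Best (start, end) of an IUPAC primer occurrence within mismatches, or None."""
    plen = len(primer)
    best: tuple[int, int, int] | None = None  # (mismatches, start, end)
    for start in range(0, len(read) - plen + 1):
        mm = iupac_mismatches(primer, read[start : start + plen])
        if mm <= max_mm and (best is None or mm < best[0]):
            best = (mm, start, start + plen)
            if mm == 0:
                break
    return None if best is None else (best[1], best[2])


def prepare_read(
    read: str,
    config: PrepConfig,
    quality: str | None = None,
) -> PrepResult:
    """Apply primer stripping and quality rules to one merged read.

    Returns the retained trimmed sequence or a rejection with one of the
    reasons "alphabet", "primer", "ambiguous", "quality", "length".
    ``quality`` is a FASTQ (phred+33) string; FASTA inputs skip the
    mean-error check.
    """
    seq = read.upper()
    if any(b not in IUPAC_SETS for b in seq):
        return PrepResult(False, reason="alphabet")

    if quality is not None:
        errs = [10 ** (-(ord(ch) - 33) / 10) for ch in quality]
        if errs and sum(errs) / len(errs) > config.per_base_error_threshold:
            return PrepResult(False, reason="quality")

    if config.require_forward_primer:
        hit = _find_primer(seq, config.forward_primer.upper(), config.max_primer_mismatches)
        if hit is None:
            return PrepResult(False, reason="primer")
        seq = seq[hit[1] :]

    # reverse primer appears reverse-complemented at the 3' end of merged
    # reads; strip when found, keep the read when absent
    rc = revcomp(config.reverse_primer)
    hit = _find_primer(seq, rc, config.max_primer_mismatches)
    if hit is not None:
        seq = seq[: hit[0]]

    seq = seq.strip("N")
    if "N" in seq:
        return PrepResult(False, reason="ambiguous")
    if len(seq) < config.min_length:
        return PrepResult(False, reason="length")
    return PrepResult(True, sequence=seq)


def prepare_sample(
    reads: list[tuple[str, str, str]],
    config: PrepConfig,
) -> tuple[list[str], dict[str, int]]:
    """Prepare a sample's reads; returns retained sequences and rejection tally."""
    kept: list[str] = []
    tally = {r: 0 for r in REASONS}
    tally["input"] = len(reads)
    for _, seq, qual in reads:
        res = prepare_read(seq, config, quality=qual or None)
        if res.retained:
            kept.append(res.sequence)  # type: ignore[arg-type]
        else:
            tally[res.reason] += 1  # type: ignore[index]
    tally["retained"] = len(kept)
    return kept, tally


def _mismatch_profiles(seq: str, parent: str) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative positional mismatches from the left and from the right.

    ``left[p]`` counts mismatches between ``seq[:p]`` and ``parent[:p]``;
    ``right[p]`` between ``seq[p:]`` and the parent's right-aligned tail.
    Positional comparison assumes substitution-style divergence (merged
    amplicons share coordinates), which is what a single-breakpoint
    crossover of two same-locus parents produces.
    """
    n = len(seq)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    left = np.zeros(n + 1, dtype=np.int64)
    right = np.zeros(n + 1, dtype=np.int64)

    m = min(n, len(parent))
    b = np.frombuffer(parent.encode(), dtype=np.uint8)
    diff = a[:m] != b[:m]
    left[1 : m + 1] = np.cumsum(diff)
    left[m + 1 :] = left[m] + np.arange(1, n - m + 1)

    diff_r = a[n - m :] != b[len(parent) - m :]
    tail_mm = np.cumsum(diff_r[::-1])[::-1]
    right[n - m : n] = tail_mm
    if n > m:
        right[: n - m] = tail_mm[0] + np.arange(n - m, 0, -1)
    return left, right


def detect_chimeras(
    pool: list[DereplicatedSequence],
    config: PrepConfig,
    max_parents: int = 30,
    min_segment: int = 20,
) -> list[bool]:
    """Flag two-parent single-breakpoint chimeras in a dereplicated pool.

    A sequence is chimeric when two candidate parents, each at least
    ``chimera_abundance_skew`` times more abundant, admit a breakpoint
    where the left segment matches parent A and the right segment parent B
    at >= ``chimera_segment_identity``, while no single parent explains the
    whole sequence at > ``chimera_parent_identity_ceiling``.  The pool must
    be sorted by decreasing count (dereplicate() order).  Every breakpoint
    with both segments >= ``min_segment`` long is examined.
    """
    flags = [False] * len(pool)
    align_cfg = ClusterConfig()
    for i, rec in enumerate(pool):
        parents = [
            p
            for j, p in enumerate(pool[:i])
            if p.total_count >= config.chimera_abundance_skew * rec.total_count
            and not flags[j]
        ][:max_parents]
        if len(parents) < 2:
            continue
        best_whole = max(
            pairwise_identity(rec.sequence, p.sequence, align_cfg) for p in parents
        )
        if best_whole > config.chimera_parent_identity_ceiling:
            continue
        seq = rec.sequence
        n = len(seq)
        if n < 2 * min_segment:
            continue
        profiles = [_mismatch_profiles(seq, p.sequence) for p in parents]
        bps = np.arange(min_segment, n - min_segment + 1)
        lens_l = bps.astype(float)
        lens_r = (n - bps).astype(float)
        max_mm = 1.0 - config.chimera_segment_identity
        found = False
        for ai in range(len(parents)):
            left_ok = profiles[ai][0][bps] / lens_l <= max_mm
            if not left_ok.any():
                continue
            for bi in range(len(parents)):
                if ai == bi:
                    continue
                right_ok = profiles[bi][1][bps] / lens_r <= max_mm
                if (left_ok & right_ok).any():
                    found = True
                    break
            if found:
                break
        flags[i] = found
    return flags


@dataclass
class PrepReport:
    """Per-sample QC accounting; rejection categories partition the input."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        parts = t[list(REASONS) + ["chimera_rejected", "retained"]].sum(axis=1)
        if not (parts == t["input"]).all():
            raise ValueError("rejection categories must partition the input count")


def prep_stats(per_sample_tallies: dict[str, dict[str, int]]) -> PrepReport:
    """Assemble per-sample QC tallies into a report with retained fractions."""
    rows = {}
    for sample, tally in per_sample_tallies.items():
        row = {k: tally.get(k, 0) for k in ("input", *REASONS, "retained")}
        row["chimera_rejected"] = tally.get("chimera_rejected", 0)
        rows[sample] = row
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    frac = table["retained"] / table["input"].where(table["input"] > 0)
    table = table.assign(retained_pct=100.0 * frac)
    return PrepReport(table)
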