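"""Synthetic amplicon communities and the packaged soil-geochemistry table.

This module generates everything the downstream pipeline needs for testing
without any sequence download: a toy lineage-annotated reference database,
a multi-factor community design (contamination level x chamber generation x
chamber type), error-bearing amplicon reads with read-level ground truth,
and the five-site soil geochemistry table used by :mod:`amplicore.geochem`.

The community design emulates an in-situ cultivation study on mercury-
contaminated soils: samples are laid out over contamination levels
(reference/low/medium/high), successive 20-day chamber generations (G1-G3)
and two chamber types (diffusion chamber DC, microbial trap MT).  Taxa can
be flagged as metal-enriched through per-taxon log-fold effects keyed by
level and/or generation; per-sample relative abundances are drawn from a
Dirichlet whose log-means include those effects.

Reads are merged single-end amplicons: forward primer + a fixed per-taxon
amplicon region + reverse-complemented reverse primer, with i.i.d.
substitution errors and optional two-parent single-breakpoint chimeras.
Identical configurations (including the seed) give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import instantiate_iupac, revcomp

__all__ = [
    "PRIMER_PRESETS",
    "ReferenceTaxon",
    "ReferenceDB",
    "SimulationConfig",
    "GroundTruth",
    "build_reference",
    "simulate_design",
    "generate_reads",
    "geochem_fixture",
    "write_fasta",
    "write_fastq",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Commonly used amplicon primer pairs (16S V4-V5 and fungal ITS1).
PRIMER_PRESETS: dict[str, tuple[str, str]] = {
    "515F/926R": ("GTGYCAGCMGCCGCGGTAA", "CCGYCAATTYMTTTRAGTTT"),
    "ITS1F/ITS2R": ("CTTGGTCATTTAGAGGAAGTAA", "GCTGCGTTCTTCATCGATGC"),
}

LEVELS = ("reference", "low", "medium", "high")
GENERATIONS = ("G1", "G2", "G3")
CHAMBERS = ("DC", "MT")


@dataclass(frozen=True)
class ReferenceTaxon:
    """One reference record: id, 7-rank lineage (possibly truncated), sequence."""

    ref_id: str
    lineage: tuple[str, ...]  # 7 names, "" for unnamed ranks
    sequence: str

    def __post_init__(self) -> None:
        if len(self.lineage) != 7:
            raise ValueError("lineage must have exactly 7 ranks")
        empty_seen = False
        for name in self.lineage:
            if name == "":
                empty_seen = True
            elif empty_seen:
                raise ValueError("named rank below an empty rank")
        if len(self.sequence) < 200:
            raise ValueError("reference sequences must be >= 200 bp")

    def lineage_string(self) -> str:
        return ";".join(p + n for p, n in zip(RANK_PREFIXES, self.lineage))


class ReferenceDB:
    """Ordered collection of :class:`ReferenceTaxon` with FASTA round-trip."""

    def __init__(self, taxa: list[ReferenceTaxon]):
        self.taxa = list(taxa)
        self._by_id = {t.ref_id: t for t in self.taxa}
        if len(self._by_id) != len(self.taxa):
            raise ValueError("duplicate ref_id in reference")

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self):
        return iter(self.taxa)

    def __getitem__(self, ref_id: str) -> ReferenceTaxon:
        return self._by_id[ref_id]

    def ids(self) -> list[str]:
        return [t.ref_id for t in self.taxa]

    def to_fasta(self) -> str:
        lines = []
        for t in self.taxa:
            lines.append(f">{t.ref_id} {t.lineage_string()}")
            lines.append(t.sequence)
        return "\n".join(lines) + "\n"

    @classmethod
    def from_fasta(cls, text: str) -> "ReferenceDB":
        taxa = []
        header: str | None = None
        chunks: list[str] = []
        for line in text.splitlines():
            if line.startswith(">"):
                if header is not None:
                    taxa.append(_parse_record(header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line.strip():
                chunks.append(line.strip())
        if header is not None:
            taxa.append(_parse_record(header, "".join(chunks)))
        return cls(taxa)


def _parse_record(header: str, seq: str) -> ReferenceTaxon:
    ref_id, _, lineage_str = header.partition(" ")
    names = []
    for part in lineage_str.split(";"):
        part = part.strip()
        names.append(part[3:] if len(part) >= 3 else "")
    while len(names) < 7:
        names.append("")
    return ReferenceTaxon(ref_id, tuple(names[:7]), seq.upper())


def build_reference(
    n_taxa: int,
    seed: int,
    length: int = 250,
    unnamed_fraction: float = 0.2,
) -> ReferenceDB:
    """Generate a toy reference database of well-separated sequences.

    Sequences are i.i.d. uniform DNA, which makes all pairwise identities
    fall far below the 0.95 separability bound with overwhelming
    probability.  A ``unnamed_fraction`` of taxa get an empty genus or
    species name to exercise rank-truncation rules downstream.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng([int(seed), 101])
    bases = np.array(list("ACGT"))
    n_unnamed = math.ceil(unnamed_fraction * n_taxa) if unnamed_fraction > 0 else 0
    unnamed = set(rng.choice(n_taxa, size=n_unnamed, replace=False).tolist())
    taxa = []
    for i in range(n_taxa):
        seq = "".join(rng.choice(bases, size=length))
        lineage = [
            "Bacteria",
            f"Phylum{i % 6 + 1:02d}",
            f"Class{i:03d}",
            f"Order{i:03d}",
            f"Family{i:03d}",
            f"Genus{i:03d}",
            f"species{i:03d}",
        ]
        if i in unnamed:
            # alternate between missing species only and missing genus+species
            lineage[6] = ""
            if i % 2 == 0:
                lineage[5] = ""
        taxa.append(ReferenceTaxon(f"ref_{i + 1:04d}", tuple(lineage), seq))
    return ReferenceDB(taxa)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated study.

    ``enrichment_effects`` maps taxon id to a dict of additive natural-log
    abundance effects keyed by contamination level and/or generation name;
    a sample receives the sum of the entries matching its design cell.
    """

    samples_per_cell: int = 1
    levels: tuple[str, ...] = LEVELS
    generations: tuple[str, ...] = GENERATIONS
    chambers: tuple[str, ...] = CHAMBERS
    reads_per_sample: int = 500
    amplicon_length: int = 250
    amplicon_offset: int = 0
    substitution_error_rate: float = 0.005
    chimera_rate: float = 0.0
    dirichlet_concentration: float = 50.0
    primer_pair: str = "515F/926R"
    enrichment_effects: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.substitution_error_rate, self.chimera_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")

    @property
    def primers(self) -> tuple[str, str]:
        return PRIMER_PRESETS[self.primer_pair]


@dataclass
class GroundTruth:
    """True community composition behind a simulated design."""

    metadata: pd.DataFrame  # sample x (level, generation, chamber, replicate)
    abundances: pd.DataFrame  # taxa x samples, columns sum to 1

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata.index)


def simulate_design(reference: ReferenceDB, config: SimulationConfig) -> GroundTruth:
    """Draw per-sample true relative abundances for the full factorial design.

    Base log-abundances per taxon are normal(0, 1); the configured
    enrichment effects shift the log-mean of their taxon in the matching
    design cells; Dirichlet sampling around the softmax of the log-means
    adds between-sample variability.
    """
    if len(reference) == 0:
        raise ValueError("reference must be nonempty")
    taxon_ids = reference.ids()
    known = set(taxon_ids)
    for tid in config.enrichment_effects:
        if tid not in known:
            raise ValueError(f"enrichment effect for unknown taxon {tid!r}")
    valid_keys = set(config.levels) | set(config.generations)
    for tid, effects in config.enrichment_effects.items():
        for key in effects:
            if key not in valid_keys:
                raise ValueError(f"effect key {key!r} is neither a level nor a generation")

    rng = np.random.default_rng([int(config.rng_seed), 202])
    base_log = rng.normal(0.0, 1.0, size=len(taxon_ids))

    rows = []
    columns = {}
    for level in config.levels:
        for gen in config.generations:
            for chamber in config.chambers:
                for rep in range(1, config.samples_per_cell + 1):
                    sample_id = f"{level}-{chamber}-{gen}-r{rep}"
                    rows.append((sample_id, level, gen, chamber, rep))
                    log_mean = base_log.copy()
                    for j, tid in enumerate(taxon_ids):
                        eff = config.enrichment_effects.get(tid, {})
                        log_mean[j] += eff.get(level, 0.0) + eff.get(gen, 0.0)
                    weights = np.exp(log_mean - log_mean.max())
                    weights /= weights.sum()
                    alpha = config.dirichlet_concentration * weights
                    columns[sample_id] = rng.dirichlet(alpha)

    metadata = pd.DataFrame(
        [r[1:] for r in rows],
        index=[r[0] for r in rows],
        columns=["level", "generation", "chamber", "replicate"],
    )
    abundances = pd.DataFrame(columns, index=taxon_ids)
    return GroundTruth(metadata, abundances)


def generate_reads(
    reference: ReferenceDB,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Simulate per-sample reads and their read-level truth table.

    Returns ``(reads, read_truth)`` where ``reads[sample]`` is a list of
    ``(read_id, sequence, quality)`` tuples and ``read_truth`` has one row
    per read: sample, source taxon (chimeras record both parents), and the
    chimera flag.  Each read is the forward primer, the fixed per-taxon
    amplicon window with i.i.d. substitutions, and the reverse complement
    of the reverse primer.  Chimeric reads cross two same-sample parents at
    a single interior breakpoint.
    """
    taxon_ids = truth.abundances.index.to_list()
    missing = [t for t in taxon_ids if t not in set(reference.ids())]
    if missing:
        raise ValueError(f"truth references unknown taxa: {missing[:3]}")

    fwd = instantiate_iupac(config.primers[0])
    rev_rc = revcomp(instantiate_iupac(config.primers[1]))
    amplicons = {
        t.ref_id: t.sequence[
            config.amplicon_offset : config.amplicon_offset + config.amplicon_length
        ]
        for t in reference
    }
    bases = np.array(list("ACGT"))
    base_index = {b: i for i, b in enumerate("ACGT")}

    reads: dict[str, list[tuple[str, str, str]]] = {}
    truth_rows = []
    for s_idx, sample in enumerate(truth.sample_ids):
        rng = np.random.default_rng([int(config.rng_seed), 303, s_idx])
        probs = truth.abundances[sample].to_numpy()
        source_idx = rng.choice(len(taxon_ids), size=config.reads_per_sample, p=probs)
        chimera_flags = rng.random(config.reads_per_sample) < config.chimera_rate
        sample_reads = []
        for r_idx in range(config.reads_per_sample):
            read_id = f"{sample}_read{r_idx + 1:06d}"
            src = taxon_ids[int(source_idx[r_idx])]
            parent_b = ""
            if chimera_flags[r_idx] and len(taxon_ids) > 1:
                other = int(rng.choice(len(taxon_ids), p=probs))
                while other == int(source_idx[r_idx]):
                    other = int(rng.choice(len(taxon_ids), p=probs))
                parent_b = taxon_ids[other]
                amp_a, amp_b = amplicons[src], amplicons[parent_b]
                min_len = min(len(amp_a), len(amp_b))
                bp = int(rng.integers(min_len // 4, 3 * min_len // 4 + 1))
                insert = amp_a[:bp] + amp_b[bp:]
            else:
                chimera_flags[r_idx] = False
                insert = amplicons[src]
            seq = fwd + insert + rev_rc
            if config.substitution_error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
                hits = np.flatnonzero(
                    rng.random(len(seq)) < config.substitution_error_rate
                )
                for pos in hits:
                    orig = base_index.get(arr[pos], 0)
                    arr[pos] = bases[(orig + int(rng.integers(1, 4))) % 4]
                seq = "".join(arr)
            sample_reads.append((read_id, seq, "I" * len(seq)))
            truth_rows.append(
                (read_id, sample, src, bool(chimera_flags[r_idx]), parent_b)
            )
        reads[sample] = sample_reads

    read_truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "source_taxon", "is_chimera", "chimera_parent_b"],
    ).set_index("read_id")
    return reads, read_truth


def write_fasta(reads: list[tuple[str, str, str]]) -> str:
    return "".join(f">{rid}\n{seq}\n" for rid, seq, _ in reads)


def write_fastq(reads: list[tuple[str, str, str]]) -> str:
    return "".join(f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in reads)


def geochem_fixture():
    """The packaged five-site soil geochemistry table.

    Moisture and loss-on-ignition in wt.%, TC/TN in g/kg, TP and
    extractable NH4/NO3/PO4 in mg/kg, THg and MeHg in ng/g dry weight.
    Below-detection measurements are carried as an explicit mask, never as
    zeros.  Returns an :class:`amplicore.geochem.GeochemTable`.
    """
    from .geochem import GeochemTable

    return GeochemTable.fixture()
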