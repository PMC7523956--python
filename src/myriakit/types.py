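"""Core domain types.

All genomic and hairpin-local coordinates are 0-based, half-open.
Conversion to and from the 1-based inclusive conventions of GFF3 and
RepeatMasker ``.out`` happens only at the I/O boundary (:mod:`myriakit.io`).
Hairpin-local coordinates always run 5'->3' along the hairpin RNA,
independent of which genomic strand the locus sits on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: (start, end) pair, 0-based half-open.
Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def interval_len(iv: Interval) -> int:
    return iv[1] - iv[0]


@dataclass
class GenomeSequence:
    """A named DNA sequence (scaffold, pseudomolecule, or hairpin)."""

    seq_id: str
    residues: str
    species_id: str = ""

    def __post_init__(self):
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValidationError(f"sequence {self.seq_id!r} is empty")
        if set(self.residues) - set("ACGTN"):
            bad = sorted(set(self.residues) - set("ACGTN"))
            raise ValidationError(
                f"sequence {self.seq_id!r} contains non-ACGTN residues {bad}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HairpinAnnotation:
    """A miRNA locus: precursor hairpin plus its 5p/3p mature arms.

    ``arm5p`` / ``arm3p`` are hairpin-local intervals over ``hairpin_seq``;
    the 5p arm always precedes the 3p arm with at least one loop base
    between them.  ``copy_ids`` links loci of the same family whose mature
    sequences are identical (reads cannot be attributed between them).
    """

    mirna_id: str
    family_id: str
    species_id: str
    seq_id: str
    strand: str
    hairpin_interval: Interval
    hairpin_seq: str | None
    arm5p: Interval
    arm3p: Interval
    copy_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.mirna_id}: strand must be + or -")
        for name, (s, e) in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if not (0 <= s < e):
                raise ValidationError(f"{self.mirna_id}: {name} interval empty or negative")
            if self.hairpin_seq is not None and e > len(self.hairpin_seq):
                raise ValidationError(
                    f"{self.mirna_id}: {name} extends past hairpin end "
                    f"({e} > {len(self.hairpin_seq)})"
                )
            if not (18 <= e - s <= 27):
                raise ValidationError(
                    f"{self.mirna_id}: {name} length {e - s} outside [18, 27]"
                )
        if self.arm5p[1] >= self.arm3p[0]:
            raise ValidationError(
                f"{self.mirna_id}: arms overlap or lack a loop between them"
            )

    @property
    def mature5p(self) -> str | None:
        if self.hairpin_seq is None:
            return None
        return self.hairpin_seq[self.arm5p[0]:self.arm5p[1]]

    @property
    def mature3p(self) -> str | None:
        if self.hairpin_seq is None:
            return None
        return self.hairpin_seq[self.arm3p[0]:self.arm3p[1]]

    @property
    def loop(self) -> Interval:
        return (self.arm5p[1], self.arm3p[0])


@dataclass
class SmallRnaSample:
    """One small-RNA library: reads as (sequence, Phred+33 quality) pairs.

    Qualities are stored as Phred+33 strings (or ``None`` when absent) to
    keep multi-million-read samples compact.
    """

    sample_id: str
    species_id: str
    stage_label: str
    reads: list[tuple[str, str | None]]
    stats: dict = field(default_factory=dict)

    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class RepeatFeature:
    """A RepeatMasker hit: genomic interval, class/family, divergence."""

    seq_id: str
    interval: Interval
    repeat_class: str
    family: str = ""
    divergence_pct: float | None = None
    transitions: int | None = None
    transversions: int | None = None
    aligned_bp: int | None = None

    def __post_init__(self):
        if self.interval[1] <= self.interval[0]:
            raise ValidationError(f"repeat on {self.seq_id}: empty interval {self.interval}")
        if self.divergence_pct is not None and self.divergence_pct < 0:
            raise ValidationError("divergence_pct must be >= 0")
        if self.aligned_bp is None:
            self.aligned_bp = interval_len(self.interval)


@dataclass
class GeneFeature:
    """A gene model: gene span plus its exon intervals."""

    gene_id: str
    seq_id: str
    strand: str
    gene_interval: Interval
    exon_intervals: list[Interval]

    def validate(self) -> None:
        gs, ge = self.gene_interval
        exons = sorted(self.exon_intervals)
        for s, e in exons:
            if not (gs <= s < e <= ge):
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside gene [{gs},{ge})"
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
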