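"""Synthetic data with known ground truth.

Three generators cover everything the analysis stages consume:

* :func:`make_hairpin_set` — random miRNA hairpins (arm lengths 20–24 nt,
  loops 8–15 nt), optionally with duplicated loci whose mature sequences
  are identical, emulating multi-copy miRNA families.
* :func:`simulate_sample` — a small-RNA library over those hairpins with a
  known per-family 5p fraction (the arm-selection value the pipeline is
  meant to recover), 18–27 nt reads with positional jitter, substitution
  errors, loop-derived degradation reads, and two-level Phred qualities.
* :func:`make_genome_fixture` — scaffolds with genes, introns, repeats at
  controlled distances from genes, divergence values from a stated young/old
  mixture, and telomeric arrays, together with an exact composition ledger.

Randomness: every public generator takes one integer seed; per-(sample,
miRNA) streams are split off it by name, so adding samples or miRNAs never
perturbs the reads of earlier ones.
"""

from __future__ import annotations

import math
import os
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from . import io as mio
from .types import (
    GeneFeature,
    GenomeSequence,
    HairpinAnnotation,
    RepeatFeature,
    SmallRnaSample,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: Phred+33 characters for the two synthetic quality levels.
_Q40 = ord("I")  # Phred 40
_Q15 = ord("0")  # Phred 15


def _named_rng(seed: int, *names: str) -> np.random.Generator:
    """Deterministic child generator for a named stream under one seed."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(n.encode()) & 0x7FFFFFFF for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class SyntheticTruth:
    """Ground truth for arm-usage simulations.

    ``true_omega`` maps (family_id, species_id) to the true 5p fraction;
    ``planted_switch`` lists families whose dominant arm differs between
    the first two species; ``dup_copies`` counts loci per family.
    """

    true_omega: dict[tuple[str, str], float]
    planted_switch: set[str]
    dup_copies: dict[str, int]
    seed: int

    def __post_init__(self):
        for key, w in self.true_omega.items():
            if not (0.0 <= w <= 1.0):
                raise ParameterError(f"true_omega{key} = {w} outside [0, 1]")


@dataclass
class ReadNoiseConfig:
    """Noise model for simulated small-RNA reads."""

    depth_mean: float = 2000.0
    length_range: tuple[int, int] = (18, 27)
    end_jitter_sd: float = 1.0
    subst_error_rate: float = 0.01
    loop_read_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if not (18 <= lo <= hi <= 27):
            raise ParameterError("length_range must lie within [18, 27]")
        for name in ("subst_error_rate", "loop_read_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} = {v} outside [0, 1]")


@dataclass
class GenomeFixtureTruth:
    """Exact composition ledger for a generated genome fixture."""

    genome_bp: int
    repeat_bp_by_class: dict[str, int]
    genic_repeat_bp_by_class: dict[str, int]
    intergenic_repeat_bp_by_class: dict[str, int]
    exon_bp: int
    intron_bp: int
    telomere_ends: list[tuple[str, str, int]]
    divergences: list[float] = field(default_factory=list)

    @property
    def repeat_bp_total(self) -> int:
        return sum(self.repeat_bp_by_class.values())

    @property
    def genic_repeat_bp(self) -> int:
        return sum(self.genic_repeat_bp_by_class.values())

    @property
    def intergenic_repeat_bp(self) -> int:
        return sum(self.intergenic_repeat_bp_by_class.values())


# ---------------------------------------------------------------------------
# hairpins


def make_hairpin_set(
    n_mirnas: int,
    dup_fraction: float = 0.0,
    seed: int = 0,
    species_id: str = "synA",
) -> tuple[list[HairpinAnnotation], list[GenomeSequence]]:
    """Random hairpin loci plus their FASTA records.

    ``ceil(dup_fraction * n_mirnas)`` families are emitted as two loci with
    identical hairpin (hence mature) sequences; their ``copy_ids`` are
    cross-linked.  Deterministic under ``seed``.
    """
    if n_mirnas < 1:
        raise ParameterError("n_mirnas must be >= 1")
    if not (0.0 <= dup_fraction <= 1.0):
        raise ParameterError("dup_fraction must be in [0, 1]")
    rng = _named_rng(seed, "hairpins", species_id)
    n_dup = math.ceil(dup_fraction * n_mirnas)
    dup_families = set(rng.choice(n_mirnas, size=n_dup, replace=False).tolist())

    annotations: list[HairpinAnnotation] = []
    fasta: list[GenomeSequence] = []
    seq_id = f"{species_id}_mirscaf1"
    cursor = 1000
    for i in range(n_mirnas):
        family = f"mir-n{i + 1:03d}"
        arm5_len = int(rng.integers(20, 25))
        loop_len = int(rng.integers(8, 16))
        arm5 = _random_seq(rng, arm5_len)
        loop = _random_seq(rng, loop_len)
        arm3 = list(revcomp(arm5))
        # imperfect stem: a few substitutions so the two arms stay distinct
        for pos in rng.choice(len(arm3), size=3, replace=False):
            arm3[pos] = "ACGT"[(_CODE[ord(arm3[pos])] + int(rng.integers(1, 4))) % 4]
        arm3 = "".join(arm3)
        hp_seq = arm5 + loop + arm3
        n_copies = 2 if i in dup_families else 1
        for copy in range(1, n_copies + 1):
            mirna_id = family if n_copies == 1 else f"{family}-{copy}"
            start = cursor
            ann = HairpinAnnotation(
                mirna_id=mirna_id,
                family_id=family,
                species_id=species_id,
                seq_id=seq_id,
                strand="+",
                hairpin_interval=(start, start + len(hp_seq)),
                hairpin_seq=hp_seq,
                arm5p=(0, arm5_len),
                arm3p=(arm5_len + loop_len, len(hp_seq)),
            )
            ann.validate()
            annotations.append(ann)
            fasta.append(GenomeSequence(mirna_id, hp_seq, species_id))
            cursor += len(hp_seq) + int(rng.integers(2000, 20000))
    mio.link_copies(annotations)
    return annotations, fasta


def make_arm_truth(
    hairpins: list[HairpinAnnotation],
    species_ids: list[str],
    switch_fraction: float = 0.1,
    seed: int = 0,
) -> SyntheticTruth:
    """Assign true 5p fractions per (family, species), planting switches.

    Non-switch families share one fraction across species, drawn 40% from
    U(0.85, 0.98) (5p-dominant), 40% from U(0.02, 0.15) (3p-dominant) and
    20% from U(0.35, 0.65) (no dominant arm).  Planted-switch families are
    strongly 5p-dominant in one of the first two species and strongly
    3p-dominant in the other (separation >= 0.7).
    """
    if len(species_ids) < 1:
        raise ParameterError("at least one species required")
    rng = _named_rng(seed, "truth")
    families = sorted({h.family_id for h in hairpins})
    n_switch = math.ceil(switch_fraction * len(families)) if len(species_ids) >= 2 else 0
    switch_idx = set(rng.choice(len(families), size=n_switch, replace=False).tolist())

    true_omega: dict[tuple[str, str], float] = {}
    planted: set[str] = set()
    for i, fam in enumerate(families):
        if i in switch_idx:
            planted.add(fam)
            hi = float(rng.uniform(0.85, 0.98))
            lo = float(rng.uniform(0.02, 0.15))
            if rng.random() < 0.5:
                hi, lo = lo, hi
            for j, sp in enumerate(species_ids):
                true_omega[(fam, sp)] = lo if j == 1 else hi
        else:
            u = rng.random()
            if u < 0.4:
                w = float(rng.uniform(0.85, 0.98))
            elif u < 0.8:
                w = float(rng.uniform(0.02, 0.15))
            else:
                w = float(rng.uniform(0.35, 0.65))
            for sp in species_ids:
                true_omega[(fam, sp)] = w
    dup_copies: dict[str, int] = {}
    for h in hairpins:
        dup_copies[h.family_id] = dup_copies.get(h.family_id, 0) + 1
    return SyntheticTruth(true_omega, planted, dup_copies, seed)


# ---------------------------------------------------------------------------
# reads


def _locus_reads(
    hp: HairpinAnnotation,
    omega: float,
    noise: ReadNoiseConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    n = int(rng.poisson(noise.depth_mean))
    if n == 0:
        return []
    hp_arr = np.frombuffer(hp.hairpin_seq.encode(), dtype=np.uint8)
    L = len(hp_arr)
    lo, hi = noise.length_range

    is_loop = rng.random(n) < noise.loop_read_rate
    is_5p = rng.random(n) < omega
    starts = np.zeros(n, dtype=np.int64)
    ends = np.zeros(n, dtype=np.int64)
    for arm, mask in ((hp.arm5p, ~is_loop & is_5p), (hp.arm3p, ~is_loop & ~is_5p)):
        k = int(mask.sum())
        if k == 0:
            continue
        js = np.rint(rng.normal(0.0, noise.end_jitter_sd, k)).astype(np.int64)
        je = np.rint(rng.normal(0.0, noise.end_jitter_sd, k)).astype(np.int64)
        starts[mask] = arm[0] + js
        ends[mask] = arm[1] + je
    k = int(is_loop.sum())
    if k:
        ls, le = hp.loop
        length = rng.integers(lo, hi + 1, k)
        centre = rng.integers(ls, le, k)
        starts[is_loop] = centre - length // 2
        ends[is_loop] = starts[is_loop] + length
    # clamp to the hairpin and to the admissible length window
    starts = np.clip(starts, 0, L - lo)
    ends = np.clip(ends, starts + lo, np.minimum(starts + hi, L))

    maxlen = int((ends - starts).max())
    idx = starts[:, None] + np.arange(maxlen)
    valid = idx < ends[:, None]
    mat = hp_arr[np.minimum(idx, L - 1)]
    err = (rng.random((n, maxlen)) < noise.subst_error_rate) & valid
    codes = _CODE[mat]
    n_err = int(err.sum())
    if n_err:
        codes[err] = (codes[err] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4
    mat = _BASES[codes]
    qual = np.where(err, np.uint8(_Q15), np.uint8(_Q40))

    reads = []
    lens = (ends - starts).tolist()
    for i, ln in enumerate(lens):
        reads.append((mat[i, :ln].tobytes().decode(), qual[i, :ln].tobytes().decode()))
    return reads


def simulate_sample(
    hairpins: list[HairpinAnnotation],
    truth: SyntheticTruth,
    noise: ReadNoiseConfig,
    sample_id: str,
    species_id: str,
    seed: int | None = None,
    stage_label: str = "",
) -> SmallRnaSample:
    """One small-RNA library over the hairpin set.

    Per miRNA locus the read count is Poisson(depth_mean); each read comes
    from the 5p arm with probability ``true_omega`` (loop with probability
    ``loop_read_rate``), with jittered ends, i.i.d. substitution errors and
    Q40/Q15 qualities.  The random stream is split per (sample, miRNA).
    """
    if seed is None:
        seed = noise.seed
    reads: list[tuple[str, str]] = []
    for hp in sorted(hairpins, key=lambda h: h.mirna_id):
        key = (hp.family_id, species_id)
        if key not in truth.true_omega:
            raise ParameterError(f"family {hp.family_id!r} absent from truth for {species_id!r}")
        rng = _named_rng(seed, "sample", sample_id, hp.mirna_id)
        reads.extend(_locus_reads(hp, truth.true_omega[key], noise, rng))
    return SmallRnaSample(sample_id, species_id, stage_label, reads)


#: developmental stages the study design samples per species.
DEFAULT_STAGES = ("egg", "juvenile", "adult")


# ---------------------------------------------------------------------------
# genome fixture


@dataclass
class GenomeFixtureConfig:
    """Sizes and counts for the synthetic genome fixture.

    Genic repeats sit ``genic_repeat_distance`` (<= 2 kb) downstream of a
    gene; intergenic repeats are placed > 2 kb from every gene.  Divergence
    values come from a young/old Gaussian mixture, rounded to 0.1% as the
    RepeatMasker table prints them.
    """

    n_scaffolds: int = 3
    genes_per_scaffold: int = 4
    exons_per_gene: int = 3
    exon_bp: int = 300
    intron_bp: int = 400
    genic_repeat_bp: int = 800
    genic_repeat_distance: int = 1000
    intergenic_repeats_per_scaffold: int = 4
    intergenic_repeat_bp: int = 1200
    intergenic_gap: int = 2500
    repeat_classes: tuple[str, ...] = ("LINE", "DNA", "LTR", "SINE", "Unknown")
    telomere_motif: str = "TTAGG"
    telomere_ends: tuple[tuple[int, str, int], ...] = ((0, "3p", 100), (1, "5p", 60))
    end_pad: int = 1500
    young_divergence: tuple[float, float] = (3.0, 1.5)
    old_divergence: tuple[float, float] = (25.0, 5.0)
    young_fraction: float = 0.5
    scaffold_bp: int | None = None


def make_genome_fixture(
    cfg: GenomeFixtureConfig | None = None, seed: int = 0
) -> tuple[list[GenomeSequence], list[GeneFeature], list[RepeatFeature], GenomeFixtureTruth]:
    """Build scaffolds with known gene/repeat/telomere composition.

    Features never overlap, so per-class sums equal interval unions and the
    returned :class:`GenomeFixtureTruth` is exact by construction.
    """
    cfg = cfg or GenomeFixtureConfig()
    rng = _named_rng(seed, "genome")
    records: list[GenomeSequence] = []
    genes: list[GeneFeature] = []
    repeats: list[RepeatFeature] = []
    telomeres_by_scaffold: dict[int, dict[str, int]] = {}
    for idx, end, copies in cfg.telomere_ends:
        telomeres_by_scaffold.setdefault(idx, {})[end] = copies

    repeat_bp: dict[str, int] = {}
    genic_bp: dict[str, int] = {}
    intergenic_bp: dict[str, int] = {}
    exon_bp = 0
    intron_bp = 0
    divergences: list[float] = []
    telomere_truth: list[tuple[str, str, int]] = []
    class_cycle = 0

    def draw_divergence() -> float:
        if rng.random() < cfg.young_fraction:
            mu, sd = cfg.young_divergence
        else:
            mu, sd = cfg.old_divergence
        return round(float(np.clip(rng.normal(mu, sd), 0.1, 49.0)), 1)

    gene_counter = 0
    for s in range(cfg.n_scaffolds):
        seq_id = f"scaf{s + 1}"
        parts: list[str] = []
        pos = 0
        tel = telomeres_by_scaffold.get(s, {})
        if "5p" in tel:
            arr = revcomp(cfg.telomere_motif) * tel["5p"]
            parts.append(arr)
            pos += len(arr)
            telomere_truth.append((seq_id, "5p", tel["5p"]))
        parts.append(_random_seq(rng, cfg.end_pad))
        pos += cfg.end_pad

        def place_repeat(length: int, genic: bool):
            nonlocal pos, class_cycle
            rclass = cfg.repeat_classes[class_cycle % len(cfg.repeat_classes)]
            class_cycle += 1
            div = draw_divergence()
            repeats.append(
                RepeatFeature(
                    seq_id=seq_id,
                    interval=(pos, pos + length),
                    repeat_class=rclass,
                    family=f"fam{class_cycle}",
                    divergence_pct=div,
                )
            )
            divergences.append(div)
            repeat_bp[rclass] = repeat_bp.get(rclass, 0) + length
            bucket = genic_bp if genic else intergenic_bp
            bucket[rclass] = bucket.get(rclass, 0) + length
            parts.append(_random_seq(rng, length))
            pos += length

        for _g in range(cfg.genes_per_scaffold):
            gene_counter += 1
            gene_start = pos
            exons = []
            for e in range(cfg.exons_per_gene):
                if e > 0:
                    parts.append(_random_seq(rng, cfg.intron_bp))
                    pos += cfg.intron_bp
                    intron_bp += cfg.intron_bp
                exons.append((pos, pos + cfg.exon_bp))
                parts.append(_random_seq(rng, cfg.exon_bp))
                pos += cfg.exon_bp
                exon_bp += cfg.exon_bp
            genes.append(
                GeneFeature(
                    gene_id=f"gene{gene_counter}",
                    seq_id=seq_id,
                    strand="+",
                    gene_interval=(gene_start, pos),
                    exon_intervals=exons,
                )
            )
            parts.append(_random_seq(rng, cfg.genic_repeat_distance))
            pos += cfg.genic_repeat_distance
            place_repeat(cfg.genic_repeat_bp, genic=True)
            parts.append(_random_seq(rng, cfg.intergenic_gap))
            pos += cfg.intergenic_gap

        for _r in range(cfg.intergenic_repeats_per_scaffold):
            place_repeat(cfg.intergenic_repeat_bp, genic=False)
            parts.append(_random_seq(rng, 600))
            pos += 600

        parts.append(_random_seq(rng, cfg.end_pad))
        pos += cfg.end_pad
        if "3p" in tel:
            arr = cfg.telomere_motif * tel["3p"]
            parts.append(arr)
            pos += len(arr)
            telomere_truth.append((seq_id, "3p", tel["3p"]))
        if cfg.scaffold_bp is not None:
            if pos > cfg.scaffold_bp:
                raise ParameterError(
                    f"scaffold {seq_id}: content ({pos} bp) exceeds scaffold_bp "
                    f"({cfg.scaffold_bp} bp)"
                )
            parts.append(_random_seq(rng, cfg.scaffold_bp - pos))
            pos = cfg.scaffold_bp
        records.append(GenomeSequence(seq_id, "".join(parts)))

    truth = GenomeFixtureTruth(
        genome_bp=sum(len(r) for r in records),
        repeat_bp_by_class=repeat_bp,
        genic_repeat_bp_by_class=genic_bp,
        intergenic_repeat_bp_by_class=intergenic_bp,
        exon_bp=exon_bp,
        intron_bp=intron_bp,
        telomere_ends=telomere_truth,
        divergences=divergences,
    )
    return records, genes, repeats, truth


def write_genome_fixture(outdir: str, cfg: GenomeFixtureConfig | None = None, seed: int = 0):
    """Emit the fixture in the exact formats the readers accept."""
    os.makedirs(outdir, exist_ok=True)
    records, genes, repeats, truth = make_genome_fixture(cfg, seed)
    mio.write_fasta(records, os.path.join(outdir, "genome.fa"))
    mio.write_gene_gff(genes, os.path.join(outdir, "genes.gff3"))
    mio.write_repeatmasker_out(repeats, os.path.join(outdir, "repeats.out"))
    return records, genes, repeats, truth
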