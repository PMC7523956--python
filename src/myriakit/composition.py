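"""Genome-composition accounting.

The ledger answers, in exact integer bp: how much of a genome is repeat
(by class), how much of the repeat content sits within 2 kb of an
annotated gene versus beyond it, what remains after removing all repeats,
and how much of the gene space is exon versus intron.  Alongside it sit
the repeat-landscape histogram (genome fraction per repeat class binned by
Kimura divergence from the repeat consensus — a proxy for element activity
through time) and a telomeric-repeat scan of scaffold ends.

Repeat spans within one class are union-merged (a bp covered twice counts
once); the cross-class union gives the total.  Raw (unmerged) sums are
reported as well, since upstream annotations may legitimately overlap.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import KimuraDomainError, ParameterError, ValidationError
from .intervals import expand, merge, union_length
from .types import GeneFeature, GenomeSequence, RepeatFeature, revcomp


@dataclass
class CompositionConfig:
    genic_window: int = 2_000
    landscape_bin_width: float = 1.0
    landscape_max: float = 50.0
    telomere_motif: str = "TTAGG"
    telomere_min_copies: int = 25
    telomere_end_window: int = 10_000

    def __post_init__(self):
        for name in (
            "genic_window", "landscape_bin_width", "landscape_max",
            "telomere_min_copies", "telomere_end_window",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if set(self.telomere_motif.upper()) - set("ACGT"):
            raise ParameterError("telomere_motif must be ACGT only")


@dataclass
class CompositionSummary:
    """Genome-wide ledger; all spans in exact integer bp."""

    species_id: str
    genome_bp: int
    repeat_bp_by_class: dict[str, int]
    repeat_bp_total: int
    repeat_pct: float
    genic_repeat_bp_by_class: dict[str, int] = field(default_factory=dict)
    intergenic_repeat_bp_by_class: dict[str, int] = field(default_factory=dict)
    non_repeat_bp: int = 0
    exon_bp: int = 0
    intron_bp: int = 0
    repeat_bp_raw_sum: int = 0


@dataclass
class TelomereReport:
    seq_id: str
    end: str  # 5p / 3p
    motif: str
    copies: int
    present: bool


def mb_display(bp: int) -> int:
    """bp -> Mb, rounding half away from zero (display convention)."""
    sign = -1 if bp < 0 else 1
    return sign * int(abs(bp) / 1e6 + 0.5)


# ---------------------------------------------------------------------------
# repeat spans


def summarize_repeats(
    features: list[RepeatFeature], genome_bp: int, species_id: str = ""
) -> CompositionSummary:
    """Per-class and total repeat spans as interval unions.

    Per-class bp merges overlaps within the class; the total merges across
    all classes, so per-class values can sum to more than the total when
    classes overlap.  ``repeat_pct`` is 100 * total / genome_bp.
    """
    if genome_bp <= 0:
        raise ParameterError("genome_bp must be > 0")
    by_class: dict[str, dict[str, list]] = {}
    all_by_seq: dict[str, list] = {}
    raw_sum = 0
    for f in features:
        by_class.setdefault(f.repeat_class, {}).setdefault(f.seq_id, []).append(f.interval)
        all_by_seq.setdefault(f.seq_id, []).append(f.interval)
        raw_sum += f.interval[1] - f.interval[0]
    repeat_bp_by_class = {
        cls: sum(union_length(ivs) for ivs in seqs.values())
        for cls, seqs in by_class.items()
    }
    total = sum(union_length(ivs) for ivs in all_by_seq.values())
    return CompositionSummary(
        species_id=species_id,
        genome_bp=genome_bp,
        repeat_bp_by_class=repeat_bp_by_class,
        repeat_bp_total=total,
        repeat_pct=100.0 * total / genome_bp,
        non_repeat_bp=genome_bp - total,
        repeat_bp_raw_sum=raw_sum,
    )


def partition_genic(
    features: list[RepeatFeature],
    genes: list[GeneFeature],
    cfg: CompositionConfig | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Split repeat bp by class into genic vs intergenic.

    A repeat is genic iff its gap to some gene is at most ``genic_window``
    bp — equivalently, it overlaps or touches the gene interval expanded
    by the window on both sides (clamped at zero), so a repeat starting
    exactly 2 kb downstream still counts as genic.  The whole feature goes
    to exactly one category.  Returns (genic, intergenic) per-class bp sums.
    """
    cfg = cfg or CompositionConfig()
    windows: dict[str, list] = {}
    for g in genes:
        windows.setdefault(g.seq_id, []).append(expand(g.gene_interval, cfg.genic_window))
    windows = {sid: merge(ivs) for sid, ivs in windows.items()}

    import bisect

    window_starts = {sid: [iv[0] for iv in ivs] for sid, ivs in windows.items()}
    genic: dict[str, int] = {}
    intergenic: dict[str, int] = {}
    for f in features:
        ivs = windows.get(f.seq_id, [])
        s, e = f.interval
        # merged windows are disjoint and sorted: only the last window
        # starting at or before the feature end can touch it
        i = bisect.bisect_right(window_starts.get(f.seq_id, []), e) - 1
        hit = i >= 0 and ivs[i][1] >= s
        bucket = genic if hit else intergenic
        bucket[f.repeat_class] = bucket.get(f.repeat_class, 0) + (e - s)
    return genic, intergenic


def decompose_genome(summary: CompositionSummary) -> pd.DataFrame:
    """The printed size decomposition: genome, repeat, non-repeat (genome
    minus repeat), exon and intron spans, each with percent of genome at
    full precision and rounded to the integer percent the reports use,
    plus Mb display values (rounded half away from zero)."""
    if summary.repeat_bp_total > summary.genome_bp:
        raise ValidationError(
            f"repeat_bp_total ({summary.repeat_bp_total}) exceeds genome_bp "
            f"({summary.genome_bp})"
        )
    non_repeat = summary.genome_bp - summary.repeat_bp_total
    rows = [
        ("genome", summary.genome_bp),
        ("repeat", summary.repeat_bp_total),
        ("non_repeat", non_repeat),
        ("exon", summary.exon_bp),
        ("intron", summary.intron_bp),
    ]
    out = []
    for name, bp in rows:
        pct = 100.0 * bp / summary.genome_bp
        out.append(
            {
                "component": name,
                "bp": bp,
                "mb": mb_display(bp),
                "pct_of_genome": pct,
                "pct_rounded": int(pct + 0.5),
            }
        )
    return pd.DataFrame(out)


def nonrepeat_ratio_pcts(non_repeat_a: int, non_repeat_b: int) -> tuple[float, float]:
    """Both directional percent differences between two non-repeat spans:
    (a over b, b over a) as 100 * (x - y) / y.  Reported without taking a
    position on which direction a comparison intends."""
    return (
        100.0 * (non_repeat_a - non_repeat_b) / non_repeat_b,
        100.0 * (non_repeat_b - non_repeat_a) / non_repeat_a,
    )


# ---------------------------------------------------------------------------
# gene spans


def gene_span_stats(genes: list[GeneFeature]) -> tuple[int, int, dict[str, list[int]]]:
    """Exon and intron union bp across genes, plus per-gene intron lengths.

    Introns are the gaps between consecutive sorted exons within a gene;
    overlapping spans across genes count once (union semantics).
    """
    exon_ivs: dict[str, list] = {}
    intron_ivs: dict[str, list] = {}
    per_gene: dict[str, list[int]] = {}
    for g in genes:
        exons = sorted(g.exon_intervals)
        lengths = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            intron_ivs.setdefault(g.seq_id, []).append((e1, s2))
            lengths.append(s2 - e1)
        per_gene[g.gene_id] = lengths
        exon_ivs.setdefault(g.seq_id, []).extend(exons)
    exon_bp = sum(union_length(ivs) for ivs in exon_ivs.values())
    intron_bp = sum(union_length(ivs) for ivs in intron_ivs.values())
    return exon_bp, intron_bp, per_gene


# ---------------------------------------------------------------------------
# Kimura divergence and the repeat landscape


def kimura_distance(P: float, Q: float) -> float:
    """Two-parameter distance d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).

    P and Q are the transition and transversion proportions; raises
    :class:`KimuraDomainError` when the log argument saturates
    (1 - 2P - Q <= 0 or 1 - 2Q <= 0).
    """
    if P < 0 or Q < 0:
        raise ParameterError("P and Q must be >= 0")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        raise KimuraDomainError(f"distance undefined for P={P}, Q={Q}")
    return -0.5 * math.log(a * math.sqrt(b))


def build_landscape(
    features: list[RepeatFeature],
    genome_bp: int,
    cfg: CompositionConfig | None = None,
) -> pd.DataFrame:
    """Genome percentage per (repeat class, divergence bin).

    ``divergence_pct`` is taken as the (CpG-adjusted) Kimura substitution
    level in percent, as annotated upstream; bins are
    ``landscape_bin_width`` percentage points wide up to ``landscape_max``,
    with older copies pooled into a final overflow bin.
    """
    cfg = cfg or CompositionConfig()
    if genome_bp <= 0:
        raise ParameterError("genome_bp must be > 0")
    width = cfg.landscape_bin_width
    n_bins = int(math.ceil(cfg.landscape_max / width))
    mass: dict[tuple[str, int], int] = {}
    for f in features:
        if f.divergence_pct is None:
            continue
        b = int(f.divergence_pct // width)
        b = min(b, n_bins)  # overflow bin
        key = (f.repeat_class, b)
        mass[key] = mass.get(key, 0) + (f.aligned_bp or 0)
    rows = []
    for (cls, b), bp in sorted(mass.items()):
        lo = b * width
        hi = math.inf if b == n_bins else (b + 1) * width
        rows.append(
            {
                "repeat_class": cls,
                "bin_lo": lo,
                "bin_hi": hi,
                "aligned_bp": bp,
                "genome_pct": 100.0 * bp / genome_bp,
            }
        )
    return pd.DataFrame(rows, columns=["repeat_class", "bin_lo", "bin_hi", "aligned_bp", "genome_pct"])


def plot_landscape(landscape: pd.DataFrame, ax=None):
    """Stacked-bar repeat landscape: divergence on x, genome % on y."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 3))
    finite = landscape[landscape.bin_hi != math.inf]
    bins = sorted(finite.bin_lo.unique())
    bottom = {b: 0.0 for b in bins}
    for cls, grp in finite.groupby("repeat_class"):
        heights = {b: 0.0 for b in bins}
        for r in grp.itertuples():
            heights[r.bin_lo] += r.genome_pct
        ax.bar(
            bins, [heights[b] for b in bins], width=0.9,
            bottom=[bottom[b] for b in bins], label=cls,
        )
        for b in bins:
            bottom[b] += heights[b]
    ax.set_xlabel("Kimura substitution level (%)")
    ax.set_ylabel("% of genome")
    ax.legend(fontsize="small")
    return ax


# ---------------------------------------------------------------------------
# telomeres


def _max_tandem_copies(window: str, motif: str) -> int:
    best = 0
    for pat in (motif, revcomp(motif)):
        for m in re.finditer(f"(?:{pat})+", window):
            best = max(best, (m.end() - m.start()) // len(motif))
    return best


def scan_telomeres(
    seq: GenomeSequence, cfg: CompositionConfig | None = None
) -> list[TelomereReport]:
    """Count tandem telomeric motif copies in each terminal window.

    Both the motif and its reverse complement are scanned, so a 5' end
    beginning with the minus-strand array is detected.  Presence requires
    >= ``telomere_min_copies`` tandem copies within ``telomere_end_window``
    bp of the end.
    """
    cfg = cfg or CompositionConfig()
    motif = cfg.telomere_motif.upper()
    w = min(len(seq.residues), cfg.telomere_end_window)
    reports = []
    for end, window in (("5p", seq.residues[:w]), ("3p", seq.residues[-w:])):
        copies = _max_tandem_copies(window, motif)
        reports.append(
            TelomereReport(
                seq_id=seq.seq_id,
                end=end,
                motif=motif,
                copies=copies,
                present=copies >= cfg.telomere_min_copies,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# full ledger


def summarize(
    features: list[RepeatFeature],
    genes: list[GeneFeature],
    genome_bp: int,
    cfg: CompositionConfig | None = None,
    species_id: str = "",
) -> CompositionSummary:
    """Complete composition ledger: repeat spans, genic/intergenic split,
    exon/intron spans and the non-repeat remainder."""
    cfg = cfg or CompositionConfig()
    summary = summarize_repeats(features, genome_bp, species_id)
    genic, intergenic = partition_genic(features, genes, cfg)
    summary.genic_repeat_bp_by_class = genic
    summary.intergenic_repeat_bp_by_class = intergenic
    summary.exon_bp, summary.intron_bp, _ = gene_span_stats(genes)
    return summary
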