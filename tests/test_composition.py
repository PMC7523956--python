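"""Genome-composition ledger: spans, partitions, Kimura, landscape, telomeres."""

import math

import numpy as np
import pytest

from myriakit import composition as comp
from myriakit.errors import KimuraDomainError, ParameterError, ValidationError
from myriakit.types import GeneFeature, GenomeSequence, RepeatFeature


def rep(seq_id, start, end, cls="LINE", div=None):
    return RepeatFeature(seq_id, (start, end), cls, divergence_pct=div)


def gene(gid, seq_id, start, end, exons):
    return GeneFeature(gid, seq_id, "+", (start, end), exons)


# ---------------------------------------------------------------------------
# repeat spans


def test_overlapping_repeats_counted_once():
    s = comp.summarize_repeats([rep("c", 100, 200), rep("c", 100, 200)], 1000)
    assert s.repeat_bp_by_class == {"LINE": 100}
    assert s.repeat_bp_total == 100
    assert s.repeat_bp_raw_sum == 200


def test_cross_class_overlap_union_vs_per_class():
    s = comp.summarize_repeats(
        [rep("c", 100, 200, "LINE"), rep("c", 150, 250, "DNA")], 1000
    )
    assert s.repeat_bp_by_class == {"LINE": 100, "DNA": 100}
    assert s.repeat_bp_total == 150  # union across classes


def test_empty_features_and_zero_genome():
    s = comp.summarize_repeats([], 500)
    assert (s.repeat_bp_total, s.repeat_pct, s.non_repeat_bp) == (0, 0.0, 500)
    with pytest.raises(ParameterError):
        comp.summarize_repeats([], 0)


# ---------------------------------------------------------------------------
# genic / intergenic partition


@pytest.mark.parametrize(
    "repeat_start,expected",
    [
        (11_500, "genic"),       # 1,500 bp downstream of the gene
        (12_500, "intergenic"),  # 2,500 bp away
        (12_000, "genic"),       # exactly 2,000 bp away: 1 bp overlap with window
    ],
)
def test_partition_two_kb_rule(repeat_start, expected):
    g = gene("g1", "c", 5_000, 10_000, [(5_000, 10_000)])
    feature = rep("c", repeat_start, repeat_start + 500)
    genic, intergenic = comp.partition_genic([feature], [g])
    got = "genic" if genic.get("LINE", 0) == 500 else "intergenic"
    assert got == expected
    assert genic.get("LINE", 0) + intergenic.get("LINE", 0) == 500


def test_partition_window_clamped_at_zero():
    g = gene("g1", "c", 500, 1_000, [(500, 1_000)])
    genic, _ = comp.partition_genic([rep("c", 0, 100)], [g])
    assert genic == {"LINE": 100}


# ---------------------------------------------------------------------------
# decomposition


def test_decompose_printed_arithmetic_shape():
    s = comp.CompositionSummary(
        species_id="x", genome_bp=1_000_000, repeat_bp_by_class={},
        repeat_bp_total=0, repeat_pct=0.0,
    )
    d = comp.decompose_genome(s).set_index("component")
    assert d.loc["non_repeat", "bp"] == 1_000_000  # zero repeats: all non-repeat


def test_decompose_rejects_repeats_exceeding_genome():
    s = comp.CompositionSummary("x", 100, {}, 200, 200.0)
    with pytest.raises(ValidationError):
        comp.decompose_genome(s)


def test_mb_display_rounds_half_away_from_zero():
    assert comp.mb_display(203_558_750) == 204
    assert comp.mb_display(146_500_000) == 147
    assert comp.mb_display(146_499_999) == 146


def test_nonrepeat_ratio_both_directions():
    up, down = comp.nonrepeat_ratio_pcts(204, 147)
    assert up == pytest.approx(100 * 57 / 147)
    assert down == pytest.approx(-100 * 57 / 204)


# ---------------------------------------------------------------------------
# gene spans


def test_intron_gaps_between_exons():
    g = gene("g1", "c", 0, 1000, [(0, 100), (900, 1000)])
    exon_bp, intron_bp, per_gene = comp.gene_span_stats([g])
    assert (exon_bp, intron_bp) == (200, 800)
    assert per_gene == {"g1": [800]}


def test_single_exon_gene_has_no_introns():
    exon_bp, intron_bp, per_gene = comp.gene_span_stats(
        [gene("g1", "c", 0, 500, [(0, 500)])]
    )
    assert (exon_bp, intron_bp, per_gene) == (500, 0, {"g1": []})


def test_overlapping_genes_use_union_semantics():
    genes = [
        gene("g1", "c", 0, 1000, [(0, 300), (700, 1000)]),
        gene("g2", "c", 100, 900, [(100, 400), (600, 900)]),
    ]
    exon_bp, intron_bp, _ = comp.gene_span_stats(genes)
    # per-base oracle over a 10 kb canvas
    exon_mask = np.zeros(10_000, bool)
    intron_mask = np.zeros(10_000, bool)
    for g in genes:
        exons = sorted(g.exon_intervals)
        for s, e in exons:
            exon_mask[s:e] = True
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            intron_mask[e1:s2] = True
    assert exon_bp == int(exon_mask.sum())
    assert intron_bp == int(intron_mask.sum())


# ---------------------------------------------------------------------------
# Kimura distance


def test_kimura_identity_and_frozen_value():
    assert comp.kimura_distance(0.0, 0.0) == 0.0
    # independent evaluation of -1/2 ln((1-2P-Q) sqrt(1-2Q)) at P=.1, Q=.05
    assert comp.kimura_distance(0.1, 0.05) == pytest.approx(0.170181, abs=1e-5)


@pytest.mark.parametrize("P,Q", [(0.45, 0.10), (0.5, 0.0), (0.2, 0.6), (0.0, 0.5)])
def test_kimura_domain_errors(P, Q):
    with pytest.raises(KimuraDomainError):
        comp.kimura_distance(P, Q)


def test_kimura_first_order_limit_and_monotonicity():
    P = Q = 1e-4
    d = comp.kimura_distance(P, Q)
    assert abs(d - (P + Q)) / (P + Q) < 0.01
    ds = [comp.kimura_distance(p, 0.05) for p in (0.01, 0.05, 0.1, 0.2)]
    assert ds == sorted(ds) and len(set(ds)) == 4


# ---------------------------------------------------------------------------
# landscape


def test_single_record_lands_in_its_bin():
    ls = comp.build_landscape([rep("c", 0, 1000, "LINE", div=3.2)], 100_000)
    row = ls.iloc[0]
    assert (row.bin_lo, row.bin_hi, row.genome_pct) == (3.0, 4.0, 1.0)


def test_landscape_mass_conservation(genome_fixture):
    (records, _genes, repeats, truth), _cfg = genome_fixture
    gbp = truth.genome_bp
    ls = comp.build_landscape(repeats, gbp)
    assert ls.genome_pct.sum() == pytest.approx(100 * truth.repeat_bp_total / gbp)


def test_landscape_matches_brute_force_binning():
    rng = np.random.default_rng(17)
    feats = [
        rep("c", i * 100, i * 100 + int(rng.integers(50, 100)),
            ["LINE", "DNA"][i % 2], div=float(rng.uniform(0, 60)))
        for i in range(50)
    ]
    cfg = comp.CompositionConfig()
    ls = comp.build_landscape(feats, 1_000_000, cfg)
    expected: dict[tuple[str, float], int] = {}
    for f in feats:
        b = min(int(f.divergence_pct), 50)  # overflow pooled at 50
        key = (f.repeat_class, float(b))
        expected[key] = expected.get(key, 0) + (f.interval[1] - f.interval[0])
    got = {(r.repeat_class, r.bin_lo): r.aligned_bp for r in ls.itertuples()}
    assert got == expected


# ---------------------------------------------------------------------------
# telomeres


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_planted_telomere_found_at_3prime():
    seq = GenomeSequence("s1", _random_seq(19, 12_000) + "TTAGG" * 100)
    r5, r3 = comp.scan_telomeres(seq)
    assert r3.present and r3.copies >= 100
    assert not r5.present


def test_reverse_complement_array_found_at_5prime():
    seq = GenomeSequence("s1", "CCTAA" * 30 + _random_seq(20, 12_000))
    r5, r3 = comp.scan_telomeres(seq)
    assert r5.present and r5.copies == 30
    assert not r3.present


def test_random_sequence_has_no_telomeres():
    seq = GenomeSequence("s1", _random_seq(21, 10_000))
    assert not any(r.present for r in comp.scan_telomeres(seq))


def test_bad_motif_rejected():
    with pytest.raises(ParameterError):
        comp.CompositionConfig(telomere_motif="TTAXG")


# ---------------------------------------------------------------------------
# full ledger on the synthetic fixture


def test_summarize_recovers_fixture_truth_exactly(genome_fixture):
    (records, genes, repeats, truth), _cfg = genome_fixture
    s = comp.summarize(repeats, genes, truth.genome_bp)
    assert s.repeat_bp_by_class == truth.repeat_bp_by_class
    assert s.genic_repeat_bp_by_class == truth.genic_repeat_bp_by_class
    assert s.intergenic_repeat_bp_by_class == truth.intergenic_repeat_bp_by_class
    assert (s.exon_bp, s.intron_bp) == (truth.exon_bp, truth.intron_bp)
    # conservation: genic + intergenic equals the class total, exactly
    for cls, total in s.repeat_bp_by_class.items():
        assert (
            s.genic_repeat_bp_by_class.get(cls, 0)
            + s.intergenic_repeat_bp_by_class.get(cls, 0)
            == total
        )
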