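"""Arm-selection rules: omega, dominance, consensus, switching, clusters,
reporter normalisation, and the model/results wrapper."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myriakit import armusage as au
from myriakit.errors import ParameterError, ValidationError

from conftest import make_hairpin

CFG = au.AnalysisConfig()


# ---------------------------------------------------------------------------
# omega


@pytest.mark.parametrize(
    "c5,c3,expected", [(80, 20, 0.8), (0, 100, 0.0), (100, 0, 1.0), (0, 0, None)]
)
def test_compute_omega(c5, c3, expected):
    assert au.compute_omega(c5, c3) == expected


def test_negative_counts_rejected():
    with pytest.raises(ParameterError):
        au.compute_omega(-1, 5)


@given(st.integers(0, 10_000), st.integers(0, 10_000))
@settings(max_examples=200, derandomize=True)
def test_omega_complement(a, b):
    if a + b > 0:
        assert au.compute_omega(a, b) + au.compute_omega(b, a) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# dominance


@pytest.mark.parametrize(
    "c5,c3,dominance",
    [
        (80, 20, "5p"),          # omega 0.8 > 0.7
        (20, 80, "3p"),          # omega 0.2 < 0.3
        (40, 30, "excluded"),    # neither arm exceeds 50 reads
        (300, 700, "undetermined"),  # omega exactly 0.3: strict inequality
        (700, 300, "undetermined"),  # omega exactly 0.7
        (51, 0, "5p"),           # inclusion needs count > 50, 51 qualifies
        (50, 0, "excluded"),     # 50 does not
    ],
)
def test_dominance_rules(c5, c3, dominance):
    rec = au.classify_dominance(c5, c3, CFG)
    assert rec.dominance == dominance
    assert rec.included == (dominance != "excluded")


@given(st.integers(0, 2000), st.integers(0, 2000), st.integers(1, 500))
@settings(max_examples=200, derandomize=True)
def test_dominance_monotone_in_5p_counts(c5, c3, bump):
    """Adding 5p reads never demotes a call toward 3p."""
    order = {"3p": 0, "excluded": 1, "undetermined": 1, "5p": 2}
    before = au.classify_dominance(c5, c3, CFG).dominance
    after = au.classify_dominance(c5 + bump, c3, CFG).dominance
    assert order[after] >= order[before]


# ---------------------------------------------------------------------------
# consensus


def _records(calls):
    return [
        au.ArmUsageRecord("f", f"s{i}", None, c != "excluded", c)
        for i, c in enumerate(calls)
    ]


def test_consensus_majority():
    cons = au.species_consensus(_records(["5p"] * 8 + ["undetermined"] * 2), CFG)
    assert (cons.consensus, cons.n_included_samples) == ("5p", 10)
    assert cons.frac_5p == pytest.approx(0.8)


def test_consensus_boundary_is_unresolved():
    cons = au.species_consensus(_records(["5p"] * 7 + ["undetermined"] * 3), CFG)
    assert cons.consensus == "unresolved"  # 0.7 is not > 0.7


def test_consensus_multi_copy_and_no_data():
    assert au.species_consensus(_records(["5p"] * 9), CFG, multi_copy=True).consensus == (
        "multi_copy_excluded"
    )
    assert au.species_consensus([], CFG).consensus == "no_data"
    assert au.species_consensus(_records(["excluded"] * 4), CFG).consensus == "no_data"


def test_excluded_samples_leave_denominator():
    cons = au.species_consensus(_records(["5p"] * 3 + ["excluded"] * 7), CFG)
    assert (cons.consensus, cons.n_included_samples) == ("5p", 3)


# ---------------------------------------------------------------------------
# switching


def _cons(family, species, call):
    return au.SpeciesConsensus(family, species, 3, 0.0, 0.0, call)


@pytest.mark.parametrize(
    "call_a,call_b,is_switch",
    [("5p", "3p", True), ("3p", "5p", True), ("5p", "unresolved", False),
     ("5p", "5p", False), ("no_data", "3p", False)],
)
def test_switch_verdicts(call_a, call_b, is_switch):
    (ev,) = au.detect_switching([_cons("f", "A", call_a), _cons("f", "B", call_b)])
    assert ev.is_switch == is_switch


def test_three_species_pairwise_enumeration():
    events = au.detect_switching(
        [_cons("f", "A", "5p"), _cons("f", "B", "3p"), _cons("f", "C", "5p")]
    )
    assert len(events) == 3
    assert sum(e.is_switch for e in events) == 2


def test_switching_symmetric_under_relabeling():
    consensus = [_cons("f", "A", "5p"), _cons("f", "B", "3p")]
    relabeled = [_cons("f", "B", "5p"), _cons("f", "A", "3p")]
    assert [e.is_switch for e in au.detect_switching(consensus)] == [
        e.is_switch for e in au.detect_switching(relabeled)
    ]


def test_switch_matrix_encoding():
    m = au.switch_matrix(
        [_cons("f1", "A", "5p"), _cons("f1", "B", "multi_copy_excluded"),
         _cons("f2", "A", "no_data"), _cons("f2", "B", "3p")]
    )
    assert m.loc["f1", "B"] == "multi-copy"
    assert m.loc["f2", "A"] == "no-data"


# ---------------------------------------------------------------------------
# clusters


def _locus(name, start, end, seq_id="c1"):
    hp = make_hairpin(name, seq_id=seq_id, start=0)
    hp.hairpin_interval = (start, end)
    return hp


def test_cluster_chaining_examples():
    loci = [_locus("a", 0, 60), _locus("b", 500, 560), _locus("c", 12_000, 12_060)]
    # gaps are end-to-start: a-b 440 bp, b-c 11,440 bp
    (cluster,) = au.detect_mirna_clusters(loci, max_gap=10_000)
    assert [h.mirna_id for h in cluster] == ["a", "b"]
    (full,) = au.detect_mirna_clusters(loci, max_gap=12_000)
    assert [h.mirna_id for h in full] == ["a", "b", "c"]
    assert au.detect_mirna_clusters(loci, max_gap=400) == []


def test_cluster_matches_transitive_closure_oracle():
    rng = np.random.default_rng(13)
    starts = sorted(int(s) for s in rng.integers(0, 60_000, 10))
    loci = [_locus(f"m{i}", s, s + 60) for i, s in enumerate(starts)]
    max_gap = 4_000

    # brute force: transitive closure over pairwise gaps
    parent = list(range(10))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(10):
        for j in range(i + 1, 10):
            gap = loci[j].hairpin_interval[0] - loci[i].hairpin_interval[1]
            if gap <= max_gap:
                parent[find(j)] = find(i)
    groups: dict[int, list[str]] = {}
    for i in range(10):
        groups.setdefault(find(i), []).append(loci[i].mirna_id)
    expected = sorted([sorted(g) for g in groups.values() if len(g) >= 2])

    got = sorted(
        sorted(h.mirna_id for h in c)
        for c in au.detect_mirna_clusters(loci, max_gap=max_gap)
    )
    assert got == expected


def test_cluster_monotone_in_max_gap():
    rng = np.random.default_rng(14)
    starts = sorted(int(s) for s in rng.integers(0, 40_000, 12))
    loci = [_locus(f"m{i}", s, s + 60) for i, s in enumerate(starts)]
    sizes = [
        sum(len(c) for c in au.detect_mirna_clusters(loci, max_gap=g))
        for g in (500, 2_000, 8_000, 50_000)
    ]
    assert sizes == sorted(sizes)


# ---------------------------------------------------------------------------
# reporter assay


def _meas(cid, ren, fire, control=False, rep=0):
    return au.ReporterMeasurement(cid, ren, fire, control, rep)


def test_reporter_normalization_and_relative_activity():
    meas = [
        _meas("m-5p", 5.0, 10.0), _meas("m-5p", 10.0, 10.0, control=True),
        _meas("m-3p", 8.0, 10.0), _meas("m-3p", 10.0, 10.0, control=True),
    ]
    table = au.normalize_reporter(meas)
    by = table.set_index("construct_id")["normalized"]
    assert by["m-5p"] == pytest.approx(0.5)
    assert by["m-3p"] == pytest.approx(0.8)
    assert au.relative_arm_activity(table, "m-5p", "m-3p") == pytest.approx(0.625)


def test_reporter_identity_and_missing_control():
    meas = [_meas("x", 3.0, 6.0), _meas("x", 3.0, 6.0, control=True)]
    assert au.normalize_reporter(meas).normalized.iloc[0] == pytest.approx(1.0)
    with pytest.raises(ValidationError, match="y"):
        au.normalize_reporter([_meas("y", 1.0, 1.0)])


# ---------------------------------------------------------------------------
# model / results


def test_model_fit_matches_scalar_rules(small_study):
    from myriakit import quant

    hairpins, truth, samples = small_study
    counts = pd.concat(
        [quant.quantify_sample(s, hairpins) for s in samples], ignore_index=True
    )
    res = au.ArmUsageModel(counts).fit()
    # every record's call agrees with the scalar rule applied to its counts
    for r in res.records.itertuples():
        assert r.dominance == au.classify_dominance(r.count_5p, r.count_3p, CFG).dominance
    assert set(res.consensus.consensus) <= {
        "5p", "3p", "unresolved", "multi_copy_excluded", "no_data"
    }
    text = res.summary()
    assert "omega" in text and "arm-switch events" in text


def test_model_recovers_planted_switches(small_study):
    from myriakit import quant

    hairpins, truth, samples = small_study
    counts = pd.concat(
        [quant.quantify_sample(s, hairpins) for s in samples], ignore_index=True
    )
    res = au.ArmUsageModel(counts).fit()
    assert set(res.switch_families) == truth.planted_switch


def test_model_missing_columns_rejected():
    with pytest.raises(ParameterError, match="missing columns"):
        au.ArmUsageModel(pd.DataFrame({"family_id": []}))
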