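"""Arm-selection statistics: omega, dominance, consensus, switching.

The arm-selection value of a miRNA in a sample is

    omega = count_5p / (count_5p + count_3p)

ranging from 0 (pure 3p usage) to 1 (pure 5p usage).  A miRNA enters the
analysis in a sample only when either arm exceeds 50 reads; it is called
5p-dominant when omega > 0.7 and 3p-dominant when omega < 0.3 (strict
inequalities; values at the cut-offs stay undetermined).  Per species, the
dominant arm is the call made in strictly more than 70% of included
samples; a family whose loci share identical mature sequences is excluded
as multi-copy, since reads cannot be attributed between copies.  An arm
switch is a family whose species-level consensus is 5p in one species and
3p in another.

The module exposes both the individual rules and a statsmodels-style
:class:`ArmUsageModel` whose :meth:`~ArmUsageModel.fit` returns an
:class:`ArmUsageResults` with the per-sample records, per-species
consensus, switch events, and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as mio
from .errors import ParameterError, ValidationError
from .types import HairpinAnnotation


@dataclass
class AnalysisConfig:
    low_threshold: float = 0.3
    high_threshold: float = 0.7
    min_count: int = 50
    consensus_fraction: float = 0.7

    def __post_init__(self):
        if not (0.0 < self.low_threshold < self.high_threshold < 1.0):
            raise ParameterError("require 0 < low_threshold < high_threshold < 1")
        if self.min_count < 0:
            raise ParameterError("min_count must be >= 0")
        if not (0.5 <= self.consensus_fraction < 1.0):
            raise ParameterError("consensus_fraction must be in [0.5, 1)")


@dataclass
class ArmUsageRecord:
    mirna_id: str
    sample_id: str
    omega: float | None
    included: bool
    dominance: str  # 5p / 3p / undetermined / excluded


@dataclass
class SpeciesConsensus:
    family_id: str
    species_id: str
    n_included_samples: int
    frac_5p: float
    frac_3p: float
    consensus: str  # 5p / 3p / unresolved / multi_copy_excluded / no_data


@dataclass
class SwitchEvent:
    family_id: str
    species_a: str
    species_b: str
    consensus_a: str
    consensus_b: str
    is_switch: bool


# ---------------------------------------------------------------------------
# elementary rules


def compute_omega(count_5p: int, count_3p: int) -> float | None:
    """5p / (5p + 3p); ``None`` when no arm reads exist."""
    if count_5p < 0 or count_3p < 0:
        raise ParameterError("arm counts must be non-negative")
    total = count_5p + count_3p
    if total == 0:
        return None
    return count_5p / total


def classify_dominance(
    count_5p: int,
    count_3p: int,
    cfg: AnalysisConfig | None = None,
    mirna_id: str = "",
    sample_id: str = "",
) -> ArmUsageRecord:
    """Inclusion filter plus dominance call for one miRNA in one sample."""
    cfg = cfg or AnalysisConfig()
    omega = compute_omega(count_5p, count_3p)
    included = max(count_5p, count_3p) > cfg.min_count
    if not included:
        dominance = "excluded"
    elif omega > cfg.high_threshold:
        dominance = "5p"
    elif omega < cfg.low_threshold:
        dominance = "3p"
    else:
        dominance = "undetermined"
    return ArmUsageRecord(mirna_id, sample_id, omega, included, dominance)


def species_consensus(
    records: list[ArmUsageRecord],
    cfg: AnalysisConfig | None = None,
    family_id: str = "",
    species_id: str = "",
    multi_copy: bool = False,
) -> SpeciesConsensus:
    """Majority arm call across a species' samples.

    The denominator is the number of included samples; a consensus needs
    one dominance category in strictly more than ``consensus_fraction`` of
    them.  Multi-copy families are excluded outright; no included samples
    yields ``no_data``.
    """
    cfg = cfg or AnalysisConfig()
    if multi_copy:
        return SpeciesConsensus(family_id, species_id, 0, 0.0, 0.0, "multi_copy_excluded")
    included = [r for r in records if r.included]
    n = len(included)
    if n == 0:
        return SpeciesConsensus(family_id, species_id, 0, 0.0, 0.0, "no_data")
    frac_5p = sum(r.dominance == "5p" for r in included) / n
    frac_3p = sum(r.dominance == "3p" for r in included) / n
    if frac_5p > cfg.consensus_fraction:
        call = "5p"
    elif frac_3p > cfg.consensus_fraction:
        call = "3p"
    else:
        call = "unresolved"
    return SpeciesConsensus(family_id, species_id, n, frac_5p, frac_3p, call)


def detect_switching(consensus_by_species: list[SpeciesConsensus]) -> list[SwitchEvent]:
    """All unordered species pairs per family; a switch is {5p, 3p}."""
    by_family: dict[str, list[SpeciesConsensus]] = {}
    for c in consensus_by_species:
        by_family.setdefault(c.family_id, []).append(c)
    events = []
    for family in sorted(by_family):
        group = sorted(by_family[family], key=lambda c: c.species_id)
        for a, b in itertools.combinations(group, 2):
            events.append(
                SwitchEvent(
                    family_id=family,
                    species_a=a.species_id,
                    species_b=b.species_id,
                    consensus_a=a.consensus,
                    consensus_b=b.consensus,
                    is_switch={a.consensus, b.consensus} == {"5p", "3p"},
                )
            )
    return events


def switch_matrix(consensus_by_species: list[SpeciesConsensus]) -> pd.DataFrame:
    """Family x species matrix of consensus calls (5p / 3p / unresolved /
    multi-copy / no-data), mirroring the published arm-usage overview."""
    label = {
        "5p": "5p",
        "3p": "3p",
        "unresolved": "unresolved",
        "multi_copy_excluded": "multi-copy",
        "no_data": "no-data",
    }
    rows = [
        {"family_id": c.family_id, "species_id": c.species_id, "call": label[c.consensus]}
        for c in consensus_by_species
    ]
    df = pd.DataFrame(rows)
    return df.pivot(index="family_id", columns="species_id", values="call").fillna("no-data")


# ---------------------------------------------------------------------------
# genomic clusters


def detect_mirna_clusters(
    loci: list[HairpinAnnotation], max_gap: int = 10_000, min_size: int = 2
) -> list[list[HairpinAnnotation]]:
    """Single-linkage chaining of loci along each sequence.

    Consecutive loci on the same seq_id join one cluster when the gap
    between them (next start minus previous end) is <= ``max_gap``;
    clusters with >= ``min_size`` members are returned in genomic order.
    """
    clusters: list[list[HairpinAnnotation]] = []
    by_seq: dict[str, list[HairpinAnnotation]] = {}
    for h in loci:
        by_seq.setdefault(h.seq_id, []).append(h)
    for seq_id in sorted(by_seq):
        chain: list[HairpinAnnotation] = []
        chain_end = None
        for h in sorted(by_seq[seq_id], key=lambda x: x.hairpin_interval):
            s, e = h.hairpin_interval
            if chain and s - chain_end <= max_gap:
                chain.append(h)
                chain_end = max(chain_end, e)
            else:
                if len(chain) >= min_size:
                    clusters.append(chain)
                chain = [h]
                chain_end = e
        if len(chain) >= min_size:
            clusters.append(chain)
    return clusters


# ---------------------------------------------------------------------------
# dual-luciferase reporter normalisation


@dataclass
class ReporterMeasurement:
    construct_id: str
    renilla: float
    firefly: float
    is_control: bool = False
    replicate: int = 0

    def __post_init__(self):
        if self.firefly <= 0:
            raise ValidationError(f"{self.construct_id}: firefly signal must be > 0")


def normalize_reporter(measurements: list[ReporterMeasurement]) -> pd.DataFrame:
    """Per-construct Renilla/firefly ratios normalised to matched controls.

    Controls share the experimental construct_id with ``is_control=True``
    (sensor transfected without the miRNA).  Returns one row per construct
    with the replicate-mean ratio, the control ratio and their quotient.
    """
    exp: dict[str, list[float]] = {}
    ctl: dict[str, list[float]] = {}
    for m in measurements:
        (ctl if m.is_control else exp).setdefault(m.construct_id, []).append(
            m.renilla / m.firefly
        )
    rows = []
    for cid in sorted(exp):
        if cid not in ctl:
            raise ValidationError(f"construct {cid!r} has no matched control")
        ratio = float(np.mean(exp[cid]))
        control = float(np.mean(ctl[cid]))
        rows.append(
            {
                "construct_id": cid,
                "ratio": ratio,
                "control_ratio": control,
                "normalized": ratio / control,
                "n_replicates": len(exp[cid]),
            }
        )
    return pd.DataFrame(rows)


def relative_arm_activity(normalized: pd.DataFrame, construct_5p: str, construct_3p: str) -> float:
    """Relative activity of the 5p sensor to the 3p sensor."""
    idx = normalized.set_index("construct_id")["normalized"]
    return float(idx[construct_5p] / idx[construct_3p])


def two_sample_t(a: list[float], b: list[float]) -> float:
    """Plain Welch t statistic, reported for convenience alongside sensors."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return float((a.mean() - b.mean()) / math.sqrt(va + vb))


# ---------------------------------------------------------------------------
# model / results objects


class ArmUsageModel:
    """Arm-usage analysis over an arm-count table.

    Parameters
    ----------
    counts
        DataFrame with columns mirna_id, family_id, sample_id, species_id,
        count_5p, count_3p, multi_copy (the output of
        :func:`myriakit.quant.count_arms`, possibly concatenated over
        samples).  Counts of one family's loci are summed per sample.
    config
        Thresholds; defaults follow the study design.
    """

    def __init__(self, counts: pd.DataFrame, config: AnalysisConfig | None = None):
        required = {"family_id", "sample_id", "species_id", "count_5p", "count_3p"}
        missing = required - set(counts.columns)
        if missing:
            raise ParameterError(f"counts table missing columns {sorted(missing)}")
        self.counts = counts.copy()
        if "multi_copy" not in self.counts.columns:
            self.counts["multi_copy"] = False
        self.config = config or AnalysisConfig()

    @classmethod
    def from_table(cls, path: str, config: AnalysisConfig | None = None) -> "ArmUsageModel":
        return cls(mio.read_table(path), config)

    def fit(self) -> "ArmUsageResults":
        cfg = self.config
        grouped = (
            self.counts.groupby(["family_id", "sample_id", "species_id"], as_index=False)
            .agg(
                count_5p=("count_5p", "sum"),
                count_3p=("count_3p", "sum"),
                multi_copy=("multi_copy", "any"),
            )
        )
        total = grouped["count_5p"] + grouped["count_3p"]
        omega = np.where(total > 0, grouped["count_5p"] / total.replace(0, np.nan), np.nan)
        included = np.maximum(grouped["count_5p"], grouped["count_3p"]) > cfg.min_count
        dominance = np.select(
            [~included, omega > cfg.high_threshold, omega < cfg.low_threshold],
            ["excluded", "5p", "3p"],
            default="undetermined",
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(omega * (1.0 - omega) / total.to_numpy(float))
        records = grouped.assign(
            omega=omega, omega_se=se, included=included, dominance=dominance
        )

        consensus_rows = []
        for (fam, sp), grp in records.groupby(["family_id", "species_id"]):
            recs = [
                ArmUsageRecord(fam, r.sample_id, r.omega, bool(r.included), r.dominance)
                for r in grp.itertuples()
            ]
            consensus_rows.append(
                species_consensus(
                    recs, cfg, family_id=fam, species_id=sp,
                    multi_copy=bool(grp["multi_copy"].any()),
                )
            )
        events = detect_switching(consensus_rows)
        return ArmUsageResults(self, records, consensus_rows, events)


class ArmUsageResults:
    """Fitted arm-usage analysis.

    Attributes
    ----------
    records : DataFrame
        Per (family, sample): counts, omega, its binomial standard error,
        inclusion flag and dominance call.
    consensus : DataFrame
        Per (family, species): included-sample tally, 5p/3p call fractions
        and the consensus category.
    switches : DataFrame
        Every unordered species pair per family with its switch verdict.
    """

    def __init__(self, model, records, consensus_list, events):
        self.model = model
        self.records = records
        self._consensus_list = consensus_list
        self._events = events
        cons_cols = [f.name for f in dataclasses.fields(SpeciesConsensus)]
        switch_cols = [f.name for f in dataclasses.fields(SwitchEvent)]
        self.consensus = pd.DataFrame(
            [c.__dict__ for c in consensus_list], columns=cons_cols
        ).sort_values(["family_id", "species_id"]).reset_index(drop=True)
        self.switches = pd.DataFrame(
            [e.__dict__ for e in events], columns=switch_cols
        ).sort_values(["family_id", "species_a", "species_b"]).reset_index(drop=True)

    @property
    def matrix(self) -> pd.DataFrame:
        return switch_matrix(self._consensus_list)

    @property
    def switch_families(self) -> list[str]:
        if self.switches.empty:
            return []
        return sorted(self.switches.loc[self.switches.is_switch, "family_id"].unique())

    def summary(self) -> str:
        cfg = self.model.config
        rec = self.records
        lines = [
            "Arm-usage analysis",
            "==================",
            f"thresholds: 3p-dominant omega < {cfg.low_threshold}, "
            f"5p-dominant omega > {cfg.high_threshold}",
            f"inclusion: either arm > {cfg.min_count} reads; "
            f"consensus: > {cfg.consensus_fraction:.0%} of included samples",
            f"records: {len(rec)} (family x sample); included: {int(rec.included.sum())}",
            "dominance calls: "
            + ", ".join(f"{k}={v}" for k, v in rec.dominance.value_counts().items()),
            f"families x species consensus rows: {len(self.consensus)}",
            "consensus calls: "
            + ", ".join(f"{k}={v}" for k, v in self.consensus.consensus.value_counts().items()),
            f"arm-switch events: {int(self.switches.is_switch.sum()) if len(self.switches) else 0}"
            + (f" (families: {', '.join(self.switch_families)})" if self.switch_families else ""),
        ]
        return "\n".join(lines)

    def plot_omega(self, ax=None):
        """Strip plot of per-sample omega by species, one point per record."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(6, 3))
        species = sorted(self.records.species_id.unique())
        for i, sp in enumerate(species):
            grp = self.records[(self.records.species_id == sp) & self.records.included]
            jitter = (np.arange(len(grp)) % 7 - 3) * 0.02
            ax.plot(np.full(len(grp), i) + jitter, grp.omega, ".", alpha=0.5, label=sp)
        for y, style in ((0.3, ":"), (0.7, ":")):
            ax.axhline(y, color="grey", linestyle=style, linewidth=0.8)
        ax.set_xticks(range(len(species)), species)
        ax.set_ylabel("omega (5p fraction)")
        ax.set_ylim(-0.02, 1.02)
        return ax
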