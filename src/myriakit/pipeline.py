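"""Stage orchestration: simulate -> quantify -> arm-usage -> switch, plus
the composition stages, with file-based handoff between stages.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so a stage can equally start from pre-existing files (resume).
A missing upstream file raises :class:`~myriakit.errors.MissingInputError`
naming the stage that would produce it.  All table outputs carry a header
comment with the tool version, the global seed and a hash of the
configuration; reruns with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from . import armusage as au
from . import composition as comp
from . import io as mio
from . import quant
from . import simulate as sim
from .errors import MissingInputError, ParameterError

STAGE_ORDER = [
    "simulate", "quantify", "arm-usage", "switch",
    "composition", "landscape", "telomere",
]


@dataclass
class RunConfig:
    """One configuration for the whole pipeline."""

    outdir: str
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    seed: int = 0
    # simulation design
    n_mirnas: int = 30
    dup_fraction: float = 0.1
    switch_fraction: float = 0.1
    species: list[str] = field(default_factory=lambda: ["mspA", "mspB"])
    stage_labels: list[str] = field(default_factory=lambda: list(sim.DEFAULT_STAGES))
    noise: sim.ReadNoiseConfig = field(default_factory=sim.ReadNoiseConfig)
    genome: sim.GenomeFixtureConfig = field(default_factory=sim.GenomeFixtureConfig)
    # analysis parameters
    preprocess: quant.PreprocessConfig = field(default_factory=quant.PreprocessConfig)
    analysis: au.AnalysisConfig = field(default_factory=au.AnalysisConfig)
    composition: comp.CompositionConfig = field(default_factory=comp.CompositionConfig)
    max_mismatch: int = 0

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ParameterError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw.update(overrides)
        for key, sub in (
            ("noise", sim.ReadNoiseConfig),
            ("genome", sim.GenomeFixtureConfig),
            ("preprocess", quant.PreprocessConfig),
            ("analysis", au.AnalysisConfig),
            ("composition", comp.CompositionConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where outputs land never changes what they contain
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"myriakit {__version__} seed={cfg.seed} config={cfg.hash()}"


def _require(path: str, producing_stage: str) -> str:
    if not os.path.exists(path):
        raise MissingInputError(
            f"missing input {path!r}: run the {producing_stage!r} stage first",
            stage=producing_stage,
        )
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> dict:
    out = cfg.outdir
    os.makedirs(os.path.join(out, "reads"), exist_ok=True)
    hairpins, fasta = sim.make_hairpin_set(
        cfg.n_mirnas, cfg.dup_fraction, cfg.seed, species_id=cfg.species[0]
    )
    truth = sim.make_arm_truth(hairpins, cfg.species, cfg.switch_fraction, cfg.seed)
    mio.write_mirna_gff(hairpins, os.path.join(out, "hairpins.gff3"))
    mio.write_fasta(fasta, os.path.join(out, "hairpins.fa"))
    with open(os.path.join(out, "truth.json"), "w") as fh:
        json.dump(
            {
                "true_omega": {f"{f}|{s}": w for (f, s), w in sorted(truth.true_omega.items())},
                "planted_switch": sorted(truth.planted_switch),
                "dup_copies": dict(sorted(truth.dup_copies.items())),
                "seed": truth.seed,
            },
            fh, indent=1, sort_keys=True,
        )
    rows = []
    n_reads = 0
    for sp in cfg.species:
        for stage_label in cfg.stage_labels:
            sample_id = f"{sp}_{stage_label}"
            sample = sim.simulate_sample(
                hairpins, truth, cfg.noise, sample_id, sp,
                seed=cfg.seed, stage_label=stage_label,
            )
            fq = os.path.join(out, "reads", f"{sample_id}.fastq")
            mio.write_fastq(sample, fq)
            n_reads += sample.n_reads()
            rows.append(
                {
                    "sample_id": sample_id,
                    "species_id": sp,
                    "stage_label": stage_label,
                    "fastq_path": os.path.relpath(fq, out),
                }
            )
    mio.write_manifest(pd.DataFrame(rows), os.path.join(out, "manifest.tsv"))
    sim.write_genome_fixture(out, cfg.genome, cfg.seed)
    return {"hairpin_loci": len(hairpins), "samples": len(rows), "reads_simulated": n_reads}


def stage_quantify(cfg: RunConfig) -> dict:
    out = cfg.outdir
    gff = _require(os.path.join(out, "hairpins.gff3"), "simulate")
    fa = _require(os.path.join(out, "hairpins.fa"), "simulate")
    manifest = mio.read_manifest(_require(os.path.join(out, "manifest.tsv"), "simulate"))
    hairpins = mio.read_mirna_gff(gff, hairpins=fa)
    tables = []
    tallies = {"reads_in": 0, "reads_kept": 0, "reads_placed": 0}
    for row in manifest.itertuples():
        fq = os.path.join(out, row.fastq_path)
        sample = sim.SmallRnaSample(
            row.sample_id, row.species_id, row.stage_label, mio.read_fastq(_require(fq, "simulate"))
        )
        table = quant.quantify_sample(sample, hairpins, cfg.preprocess, cfg.max_mismatch)
        table["species_id"] = row.species_id
        for k in tallies:
            tallies[k] += table.attrs["stats"].get(k, 0)
        tables.append(table)
    counts = pd.concat(tables, ignore_index=True)
    mio.write_table(
        counts, os.path.join(out, "counts.tsv"),
        sort_keys=["mirna_id", "sample_id"], header_comment=_header(cfg),
    )
    return {"count_rows": len(counts), **tallies}


def stage_arm_usage(cfg: RunConfig) -> dict:
    out = cfg.outdir
    counts = mio.read_table(_require(os.path.join(out, "counts.tsv"), "quantify"))
    results = au.ArmUsageModel(counts, cfg.analysis).fit()
    mio.write_table(
        results.records, os.path.join(out, "usage.tsv"),
        sort_keys=["family_id", "sample_id"], header_comment=_header(cfg),
    )
    mio.write_table(
        results.consensus, os.path.join(out, "consensus.tsv"),
        sort_keys=["family_id", "species_id"], header_comment=_header(cfg),
    )
    rec = results.records
    return {
        "usage_records": len(rec),
        "included_records": int(rec.included.sum()),
        "excluded_by_min_count": int((~rec.included).sum()),
        "multi_copy_families": int(
            results.consensus.consensus.eq("multi_copy_excluded").groupby(
                results.consensus.family_id
            ).any().sum()
        ),
    }


def stage_switch(cfg: RunConfig) -> dict:
    out = cfg.outdir
    cons_df = mio.read_table(_require(os.path.join(out, "consensus.tsv"), "arm-usage"))
    consensus = [
        au.SpeciesConsensus(
            r.family_id, r.species_id, int(r.n_included_samples),
            float(r.frac_5p), float(r.frac_3p), r.consensus,
        )
        for r in cons_df.itertuples()
    ]
    events = au.detect_switching(consensus)
    switches = pd.DataFrame([e.__dict__ for e in events])
    mio.write_table(
        switches, os.path.join(out, "switches.tsv"),
        sort_keys=["family_id", "species_a", "species_b"], header_comment=_header(cfg),
    )
    matrix = au.switch_matrix(consensus).reset_index()
    mio.write_table(
        matrix, os.path.join(out, "matrix.tsv"),
        sort_keys=["family_id"], header_comment=_header(cfg),
    )
    n_switch = int(switches.is_switch.sum()) if len(switches) else 0
    return {"species_pairs": len(switches), "switch_events": n_switch}


def stage_composition(cfg: RunConfig) -> dict:
    out = cfg.outdir
    genome = mio.read_fasta(_require(os.path.join(out, "genome.fa"), "simulate"))
    genes = mio.read_gene_gff(_require(os.path.join(out, "genes.gff3"), "simulate"))
    repeats = mio.read_repeatmasker_out(_require(os.path.join(out, "repeats.out"), "simulate"))
    genome_bp = sum(len(r) for r in genome)
    summary = comp.summarize(repeats, genes, genome_bp, cfg.composition)
    classes = sorted(summary.repeat_bp_by_class)
    rows = [
        {
            "repeat_class": cls,
            "repeat_bp": summary.repeat_bp_by_class[cls],
            "genic_bp": summary.genic_repeat_bp_by_class.get(cls, 0),
            "intergenic_bp": summary.intergenic_repeat_bp_by_class.get(cls, 0),
        }
        for cls in classes
    ]
    mio.write_table(
        pd.DataFrame(rows), os.path.join(out, "ledger.tsv"),
        sort_keys=["repeat_class"], header_comment=_header(cfg),
    )
    mio.write_table(
        comp.decompose_genome(summary), os.path.join(out, "decomposition.tsv"),
        sort_keys=[], header_comment=_header(cfg),
    )
    return {
        "genome_bp": genome_bp,
        "repeat_bp_total": summary.repeat_bp_total,
        "repeat_pct": round(summary.repeat_pct, 6),
        "exon_bp": summary.exon_bp,
        "intron_bp": summary.intron_bp,
    }


def stage_landscape(cfg: RunConfig) -> dict:
    out = cfg.outdir
    repeats = mio.read_repeatmasker_out(_require(os.path.join(out, "repeats.out"), "simulate"))
    genome = mio.read_fasta(_require(os.path.join(out, "genome.fa"), "simulate"))
    genome_bp = sum(len(r) for r in genome)
    landscape = comp.build_landscape(repeats, genome_bp, cfg.composition)
    mio.write_table(
        landscape, os.path.join(out, "landscape.tsv"),
        sort_keys=["repeat_class", "bin_lo"], header_comment=_header(cfg),
    )
    return {"landscape_bins": len(landscape)}


def stage_telomere(cfg: RunConfig) -> dict:
    out = cfg.outdir
    genome = mio.read_fasta(_require(os.path.join(out, "genome.fa"), "simulate"))
    reports = []
    for rec in genome:
        reports.extend(comp.scan_telomeres(rec, cfg.composition))
    mio.write_table(
        reports, os.path.join(out, "telomeres.tsv"),
        sort_keys=["seq_id", "end"], header_comment=_header(cfg),
    )
    return {
        "ends_scanned": len(reports),
        "telomeric_ends": sum(r.present for r in reports),
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "arm-usage": stage_arm_usage,
    "switch": stage_switch,
    "composition": stage_composition,
    "landscape": stage_landscape,
    "telomere": stage_telomere,
}


def run_pipeline(cfg: RunConfig, log=None) -> dict:
    """Run the selected stages in dependency order; returns the summary."""
    os.makedirs(cfg.outdir, exist_ok=True)
    t0 = time.monotonic()
    summary: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        if log:
            log(f"[{stage}] starting")
        tallies = _STAGE_FUNCS[stage](cfg)
        summary["stages"][stage] = tallies
        if log:
            log(f"[{stage}] done: {tallies}")
    summary["elapsed_s"] = round(time.monotonic() - t0, 3)
    return summary


def write_summary(summary: dict, path: str) -> None:
    """JSON with stable key order."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def normalized_summary(summary: dict) -> dict:
    """Summary with the wall-time field removed, for determinism checks."""
    out = dict(summary)
    out.pop("elapsed_s", None)
    return out
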