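"""Readers and writers for every external format the pipeline touches.

External conventions (GFF3 and RepeatMasker ``.out`` are 1-based inclusive)
are converted to the internal 0-based half-open convention here and nowhere
else.  FASTA/FASTQ go through Biopython's SeqIO; GFF3 is parsed with
gffutils; the RepeatMasker ``.out`` table is parsed directly from its
documented whitespace-delimited layout.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import asdict, is_dataclass

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .types import (
    GeneFeature,
    GenomeSequence,
    HairpinAnnotation,
    RepeatFeature,
    SmallRnaSample,
)

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str, species_id: str = "") -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records, order preserved."""
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file", line=1)
        if not first[1].startswith(">"):
            raise FormatError(f"{path}: expected FASTA header '>'", line=first[0])
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, str(rec.seq).upper(), species_id))
    return records


def write_fasta(records: list[GenomeSequence], path: str, width: int = 70) -> None:
    seqs = (SeqRecord(Seq(r.residues), id=r.seq_id, description="") for r in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_fastq(path: str) -> list[tuple[str, str]]:
    """Read FASTQ (Phred+33) into (sequence, quality-string) pairs."""
    out = []
    with open(path) as fh:
        for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(fh):
            out.append((seq.upper(), qual))
    return out


def write_fastq(sample: SmallRnaSample, path: str) -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(sample.reads):
            if qual is None:
                qual = "I" * len(seq)  # Q40 placeholder
            fh.write(f"@{sample.sample_id}_{i}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# miRNA GFF3 (miRBase dialect)

_ARM_RE = re.compile(r"-(5p|3p)$", re.IGNORECASE)
_SPECIES_PREFIX_RE = re.compile(
    r"^[A-Za-z]{3,4}-(?=(?:mir|let|lin|iab|bantam)\b)", re.IGNORECASE
)
# a copy suffix is a trailing number AFTER the family number: mir-100-1
_COPY_SUFFIX_RE = re.compile(r"^(.*\d.*)-\d+$")


def family_from_name(name: str) -> str:
    """Family id from a locus name: drop species prefix and copy suffix.

    ``hho-mir-100-1`` -> ``mir-100`` while ``mir-9`` stays ``mir-9`` (the
    trailing number is the family number, not a copy index).
    """
    name = name.lower()
    name = _ARM_RE.sub("", name)
    name = _SPECIES_PREFIX_RE.sub("", name, count=1)
    m = _COPY_SUFFIX_RE.match(name)
    return m.group(1) if m else name


def _attr(feature, key, default=None):
    vals = feature.attributes.get(key)
    return vals[0] if vals else default


def read_mirna_gff(
    path: str,
    hairpins: str | dict[str, str] | None = None,
    species_id: str = "",
) -> list[HairpinAnnotation]:
    """Parse a miRBase-dialect GFF3 of hairpins and mature arms.

    ``miRNA_primary_transcript`` features are hairpins; ``miRNA`` features
    reference their hairpin through ``Derives_from``.  Arms are identified
    by a ``-5p``/``-3p`` name suffix, falling back to genomic order
    (honouring strand).  ``hairpins`` may be a FASTA path or a mapping of
    hairpin name/id to sequence; when given, hairpin-local arm intervals
    are validated against the sequence and identical-mature loci are
    cross-linked via ``copy_ids``.
    """
    seq_by_name: dict[str, str] = {}
    if isinstance(hairpins, str):
        seq_by_name = {r.seq_id: r.residues for r in read_fasta(hairpins)}
    elif isinstance(hairpins, dict):
        seq_by_name = {k: v.upper() for k, v in hairpins.items()}

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    matures_by_parent: dict[str, list] = {}
    for m in db.features_of_type("miRNA"):
        parent = _attr(m, "Derives_from") or _attr(m, "Parent")
        if parent is None:
            raise ValidationError(f"mature miRNA {m.id} has no Derives_from/Parent")
        matures_by_parent.setdefault(parent, []).append(m)

    annotations: list[HairpinAnnotation] = []
    for hp in db.features_of_type("miRNA_primary_transcript"):
        name = _attr(hp, "Name", hp.id)
        matures = matures_by_parent.get(hp.id, []) + matures_by_parent.get(name, [])
        if not matures:
            warnings.warn(f"hairpin {name} has no mature arms; skipped")
            continue
        hs, he = hp.start - 1, hp.end  # GFF 1-based inclusive -> half-open
        strand = hp.strand

        def to_local(m) -> tuple[int, int]:
            ms, me = m.start - 1, m.end
            if not (hs <= ms < me <= he):
                raise ValidationError(
                    f"mature {_attr(m, 'Name', m.id)} outside hairpin {name}"
                )
            if strand == "+":
                return (ms - hs, me - hs)
            return (he - me, he - ms)

        arm5p = arm3p = None
        unnamed = []
        for m in matures:
            mname = _attr(m, "Name", m.id) or ""
            suff = _ARM_RE.search(mname)
            if suff and suff.group(1).lower() == "5p":
                arm5p = to_local(m)
            elif suff and suff.group(1).lower() == "3p":
                arm3p = to_local(m)
            else:
                unnamed.append(to_local(m))
        if unnamed:
            unnamed.sort()  # local order is 5'->3' regardless of strand
            if arm5p is None and unnamed:
                arm5p = unnamed.pop(0)
            if arm3p is None and unnamed:
                arm3p = unnamed.pop(-1)
        if arm5p is None or arm3p is None:
            warnings.warn(f"hairpin {name} lacks one arm; skipped")
            continue

        ann = HairpinAnnotation(
            mirna_id=name,
            family_id=family_from_name(name),
            species_id=species_id,
            seq_id=hp.seqid,
            strand=strand,
            hairpin_interval=(hs, he),
            hairpin_seq=seq_by_name.get(name) or seq_by_name.get(hp.id),
            arm5p=arm5p,
            arm3p=arm3p,
        )
        if ann.hairpin_seq is not None:
            ann.validate()
        annotations.append(ann)

    link_copies(annotations)
    return annotations


def link_copies(annotations: list[HairpinAnnotation]) -> None:
    """Cross-link loci (same species) sharing an identical mature sequence."""
    by_mature: dict[tuple[str, str], list[HairpinAnnotation]] = {}
    for ann in annotations:
        for mat in (ann.mature5p, ann.mature3p):
            if mat:
                by_mature.setdefault((ann.species_id, mat), []).append(ann)
    for group in by_mature.values():
        if len(group) < 2:
            continue
        ids = {a.mirna_id for a in group}
        for a in group:
            for other in sorted(ids - {a.mirna_id}):
                if other not in a.copy_ids:
                    a.copy_ids.append(other)
    for ann in annotations:
        ann.copy_ids.sort()


def write_mirna_gff(annotations: list[HairpinAnnotation], path: str) -> None:
    """Emit the miRBase-dialect GFF3 that :func:`read_mirna_gff` accepts."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            hs, he = ann.hairpin_interval
            fh.write(
                f"{ann.seq_id}\t.\tmiRNA_primary_transcript\t{hs + 1}\t{he}\t.\t"
                f"{ann.strand}\t.\tID={ann.mirna_id};Name={ann.mirna_id}\n"
            )
            for arm_name, (ls, le) in (("5p", ann.arm5p), ("3p", ann.arm3p)):
                if ann.strand == "+":
                    gs, ge = hs + ls, hs + le
                else:
                    gs, ge = he - le, he - ls
                fh.write(
                    f"{ann.seq_id}\t.\tmiRNA\t{gs + 1}\t{ge}\t.\t{ann.strand}\t.\t"
                    f"ID={ann.mirna_id}-{arm_name};Name={ann.mirna_id}-{arm_name};"
                    f"Derives_from={ann.mirna_id}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query            matching"
    "  repeat       position in repeat\n"
    "score   div. del. ins.  sequence  begin  end        (left)     repeat"
    "       class/family    begin  end    (left)  ID\n"
    "\n"
)


def read_repeatmasker_out(path: str) -> list[RepeatFeature]:
    """Parse a RepeatMasker ``.out`` file (3 header lines, then hits)."""
    features: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 13:
                raise FormatError(f"{path}: truncated RepeatMasker row", line=lineno)
            try:
                div = float(fields[1])
                seq_id = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                classfam = fields[10]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: unparseable RepeatMasker row ({exc})", line=lineno
                ) from None
            if "/" in classfam:
                rclass, family = classfam.split("/", 1)
            else:
                rclass, family = classfam, ""
            if not rclass or rclass == ".":
                rclass = "Unknown"
            features.append(
                RepeatFeature(
                    seq_id=seq_id,
                    interval=(begin - 1, end),
                    repeat_class=rclass,
                    family=family,
                    divergence_pct=div,
                )
            )
    return features


def write_repeatmasker_out(features: list[RepeatFeature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, f in enumerate(features, 1):
            classfam = (
                f"{f.repeat_class}/{f.family}" if f.family else f.repeat_class
            )
            s, e = f.interval
            div = f.divergence_pct if f.divergence_pct is not None else 0.0
            fh.write(
                f"{1000:>5} {div:>6.1f}  0.0  0.0  {f.seq_id:<10} {s + 1:>8} "
                f"{e:>8} (0) + rep{i:<6} {classfam:<16} 1 {e - s} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# gene GFF3


def read_gene_gff(path: str) -> list[GeneFeature]:
    """Parse gene models (``gene`` features with ``exon`` children)."""
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        gene = GeneFeature(
            gene_id=_attr(g, "ID", g.id),
            seq_id=g.seqid,
            strand=g.strand if g.strand in "+-" else "+",
            gene_interval=(g.start - 1, g.end),
            exon_intervals=exons,
        )
        gene.validate()
        genes.append(gene)
    return genes


def write_gene_gff(genes: list[GeneFeature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.gene_interval
            fh.write(
                f"{g.seq_id}\t.\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exon_intervals), 1):
                fh.write(
                    f"{g.seq_id}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# sample manifest + generic TSV tables

MANIFEST_COLUMNS = ["sample_id", "species_id", "stage_label", "fastq_path"]


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    return df


def write_manifest(df: pd.DataFrame, path: str) -> None:
    write_table(df[MANIFEST_COLUMNS], path, sort_keys=["sample_id"])


def write_table(
    records,
    path: str,
    sort_keys: list[str] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write tabular records as TSV: header row, floats at 6 decimals,
    deterministic row order (``sort_keys``, else all columns left-to-right).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
        df = pd.DataFrame(rows)
    if len(df):
        keys = sort_keys if sort_keys is not None else list(df.columns)
        keys = [k for k in keys if k in df.columns]
        if keys:
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    os.replace(tmp, path)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
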