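"""Raw small-RNA reads -> per-(miRNA, sample) arm counts.

Quantification follows the study design: reads are quality- and
length-filtered (all bases Q>=20 after 3' quality trimming, lengths 18–27
nt), matched ungapped against the hairpin set, and counted toward the arm
(5p or 3p) that contains a strict majority of the read's bases.  Reads
whose best placements span two miRNA families are discarded; reads hitting
several identical-sequence copies of one family are counted once and flag
the family as multi-copy (such families are excluded from arm-dominance
calls downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError
from .intervals import overlap_length
from .types import HairpinAnnotation, SmallRnaSample


@dataclass
class PreprocessConfig:
    min_phred: int = 20
    length_min: int = 18
    length_max: int = 27
    adapter: str | None = None

    def __post_init__(self):
        if not (0 < self.length_min <= self.length_max):
            raise ParameterError("require 0 < length_min <= length_max")
        if self.adapter is not None and len(self.adapter) < 8:
            raise ParameterError("adapter must be at least 8 nt")


@dataclass
class ReadPlacement:
    read_index: int
    mirna_id: str
    interval: tuple[int, int]  # hairpin-local
    mismatches: int
    arm_call: str = ""  # filled by count_arms: 5p / 3p / unassigned


@dataclass
class PlacementResult:
    placements: list[ReadPlacement]
    multi_copy_families: set[str]
    stats: dict = field(default_factory=dict)


def preprocess_reads(sample: SmallRnaSample, cfg: PreprocessConfig | None = None) -> SmallRnaSample:
    """Adapter trim, 3' quality trim, then whole-read Q and length filters.

    In order: (1) trim at the leftmost exact match of the adapter's first
    8 nt, when an adapter is configured; (2) trim 3' bases until the
    terminal base is >= ``min_phred``; (3) keep reads whose remaining bases
    are all >= ``min_phred`` and whose length is within
    [``length_min``, ``length_max``].  Idempotent.  Filter tallies are
    recorded in the returned sample's ``stats``.
    """
    cfg = cfg or PreprocessConfig()
    thresh = chr(cfg.min_phred + 33)
    adapter8 = cfg.adapter[:8] if cfg.adapter else None
    kept: list[tuple[str, str | None]] = []
    removed_quality = removed_length = 0
    for seq, qual in sample.reads:
        if adapter8:
            cut = seq.find(adapter8)
            if cut >= 0:
                seq = seq[:cut]
                qual = qual[:cut] if qual is not None else None
        if qual is not None:
            end = len(qual)
            while end > 0 and qual[end - 1] < thresh:
                end -= 1
            seq, qual = seq[:end], qual[:end]
            if seq and min(qual) < thresh:
                removed_quality += 1
                continue
        if not (cfg.length_min <= len(seq) <= cfg.length_max):
            removed_length += 1
            continue
        kept.append((seq, qual))
    out = SmallRnaSample(sample.sample_id, sample.species_id, sample.stage_label, kept)
    out.stats = {
        "reads_in": len(sample.reads),
        "reads_kept": len(kept),
        "removed_quality": removed_quality,
        "removed_length": removed_length,
    }
    return out


def _mismatches(read: str, hp: str, offset: int, limit: int) -> int:
    mm = 0
    for i, base in enumerate(read):
        if hp[offset + i] != base:
            mm += 1
            if mm > limit:
                return mm
    return mm


def place_reads(
    sample: SmallRnaSample,
    hairpins: list[HairpinAnnotation],
    max_mismatch: int = 0,
) -> PlacementResult:
    """Ungapped placement of every read on every hairpin at every offset.

    Placements with <= ``max_mismatch`` mismatches are kept; among those
    only minimal-mismatch ones survive.  A read whose minimal placements
    hit >= 2 distinct families is discarded; >= 2 same-family loci count
    the read once (lowest (mirna_id, offset)) and flag the family.
    """
    if max_mismatch < 0:
        raise ParameterError("max_mismatch must be >= 0")
    hp_list = sorted(hairpins, key=lambda h: h.mirna_id)
    family_of = {h.mirna_id: h.family_id for h in hp_list}

    by_seq: dict[str, list[int]] = {}
    for idx, (seq, _q) in enumerate(sample.reads):
        by_seq.setdefault(seq, []).append(idx)

    exact_index: dict[str, list[tuple[str, int]]] | None = None
    if max_mismatch == 0:
        lengths = sorted({len(s) for s in by_seq})
        exact_index = {}
        for h in hp_list:
            seq = h.hairpin_seq
            if seq is None:
                raise ParameterError(f"hairpin {h.mirna_id} has no sequence")
            for ln in lengths:
                for off in range(len(seq) - ln + 1):
                    exact_index.setdefault(seq[off:off + ln], []).append((h.mirna_id, off))

    placements: list[ReadPlacement] = []
    multi_copy: set[str] = set()
    n_unmapped = n_multifamily = 0
    for seq, idxs in by_seq.items():
        if exact_index is not None:
            hits = [(mid, off, 0) for mid, off in exact_index.get(seq, ())]
        else:
            hits = []
            best = max_mismatch
            for h in hp_list:
                hseq = h.hairpin_seq
                for off in range(len(hseq) - len(seq) + 1):
                    mm = _mismatches(seq, hseq, off, best)
                    if mm <= best:
                        hits.append((h.mirna_id, off, mm))
            if hits:
                best = min(mm for _, _, mm in hits)
                hits = [h for h in hits if h[2] == best]
        if not hits:
            n_unmapped += len(idxs)
            continue
        fams = {family_of[mid] for mid, _, _ in hits}
        if len(fams) >= 2:
            n_multifamily += len(idxs)
            continue
        loci = {mid for mid, _, _ in hits}
        if len(loci) >= 2:
            multi_copy.add(next(iter(fams)))
        mid, off, mm = min(hits)
        for idx in idxs:
            placements.append(ReadPlacement(idx, mid, (off, off + len(seq)), mm))
    placements.sort(key=lambda p: p.read_index)
    return PlacementResult(
        placements,
        multi_copy,
        stats={
            "reads_placed": len(placements),
            "reads_unmapped": n_unmapped,
            "reads_multifamily_discarded": n_multifamily,
        },
    )


def arm_call(hp: HairpinAnnotation, interval: tuple[int, int]) -> str:
    """Majority-overlap arm assignment: > 50% of read bases inside an arm."""
    n = interval[1] - interval[0]
    if 2 * overlap_length(interval, hp.arm5p) > n:
        return "5p"
    if 2 * overlap_length(interval, hp.arm3p) > n:
        return "3p"
    return "unassigned"


def count_arms(
    placement_result: PlacementResult,
    hairpins: list[HairpinAnnotation],
    sample_id: str = "",
    species_id: str = "",
) -> pd.DataFrame:
    """Aggregate placements into the per-(miRNA, sample) arm-count table.

    One row per hairpin locus (zero rows included) with columns
    mirna_id, family_id, sample_id, species_id, count_5p, count_3p,
    count_unassigned, multi_copy.
    """
    hp_by_id = {h.mirna_id: h for h in hairpins}
    counts: dict[str, list[int]] = {h.mirna_id: [0, 0, 0] for h in hairpins}
    call_cache: dict[tuple[str, tuple[int, int]], str] = {}
    for p in placement_result.placements:
        key = (p.mirna_id, p.interval)
        call = call_cache.get(key)
        if call is None:
            call = arm_call(hp_by_id[p.mirna_id], p.interval)
            call_cache[key] = call
        p.arm_call = call
        slot = {"5p": 0, "3p": 1, "unassigned": 2}[call]
        counts[p.mirna_id][slot] += 1
    multi = placement_result.multi_copy_families | {
        h.family_id for h in hairpins if len(h.copy_ids) > 0
    }
    rows = []
    for h in sorted(hairpins, key=lambda x: x.mirna_id):
        c5, c3, cu = counts[h.mirna_id]
        rows.append(
            {
                "mirna_id": h.mirna_id,
                "family_id": h.family_id,
                "sample_id": sample_id or "sample",
                "species_id": species_id or h.species_id,
                "count_5p": c5,
                "count_3p": c3,
                "count_unassigned": cu,
                "multi_copy": h.family_id in multi,
            }
        )
    return pd.DataFrame(rows)


def quantify_sample(
    sample: SmallRnaSample,
    hairpins: list[HairpinAnnotation],
    preprocess: PreprocessConfig | None = None,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """Preprocess, place and count one sample; returns the arm-count table."""
    pre = preprocess_reads(sample, preprocess)
    placed = place_reads(pre, hairpins, max_mismatch)
    table = count_arms(placed, hairpins, sample.sample_id, sample.species_id)
    table.attrs["stats"] = {**pre.stats, **placed.stats}
    return table
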