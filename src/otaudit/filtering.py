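"""Candidate de novo mutation extraction from per-sample variant calls.

The filter cascade removes, in order:

1. low-confidence calls (QUAL < 10 or total depth DP < 10),
2. calls failing GATK-style hard-filter thresholds
   (SNV: QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < -12.5,
   ReadPosRankSum < -8.0; indel: QD < 2.0, FS > 200.0,
   ReadPosRankSum < -20.0; a missing annotation never triggers removal),
3. calls with variant allele fraction below 5% (mosaic alleles down to 5%
   are retained),
4. alleles catalogued for the background strain,
5. variants inside or within 1 bp of merged repeat intervals,
6. variants shared by two or more samples of the cohort (likely systematic
   artifacts rather than independent de novo events).

All comparisons use strict inequalities exactly as written above, so a
record sitting exactly on a threshold is kept.  Variants are left-aligned
and parsimony-reduced before any key comparison so that "coincident" always
means an exact normalized (chrom, pos, ref, alt) match.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import DataIntegrityError, InvalidArgumentError, UndefinedVAFError

__all__ = [
    "VariantRecord",
    "IntervalSet",
    "FilterTrace",
    "normalize_variant",
    "apply_quality_gate",
    "apply_hard_filters",
    "compute_vaf",
    "merge_repeat_track",
    "filter_repeats",
    "filter_known_strain",
    "filter_shared",
    "candidate_dnms",
    "cohort_candidate_dnms",
]

HARD_FILTERS_SNV = {  # annotation -> (direction, threshold); "lt" removes when value < threshold
    "QD": ("lt", 2.0),
    "FS": ("gt", 60.0),
    "MQ": ("lt", 40.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}
HARD_FILTERS_INDEL = {
    "QD": ("lt", 2.0),
    "FS": ("gt", 200.0),
    "ReadPosRankSum": ("lt", -20.0),
}


@dataclass
class VariantRecord:
    """One normalized variant call for one sample.

    ``pos`` is 1-based (VCF convention); the reference footprint on the
    0-based half-open axis is [pos-1, pos-1+len(ref_allele)).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    total_depth: int = 0
    qual: float = 0.0
    allele_depths: tuple[int, int] = (0, 0)
    genotype: str = "het"  # het | hom_alt | hom_ref
    annotations: dict = field(default_factory=dict)
    sample_id: str = ""
    caller: str = "gatk"

    def __post_init__(self):
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if self.ref_allele == self.alt_allele:
            raise InvalidArgumentError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if (self.total_depth is not None and self.total_depth < 0) or any(
            d < 0 for d in self.allele_depths
        ):
            raise InvalidArgumentError("negative read depth")

    @property
    def variant_class(self) -> str:
        return "SNV" if len(self.ref_allele) == 1 and len(self.alt_allele) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def footprint(self) -> tuple[int, int]:
        """0-based half-open reference span of the REF allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref_allele))


def compute_vaf(record: VariantRecord) -> float:
    """Alternate allele fraction alt/(ref+alt) from the AD field."""
    ref_n, alt_n = record.allele_depths
    if ref_n + alt_n == 0:
        raise UndefinedVAFError(f"zero allele depth at {record.chrom}:{record.pos}")
    return alt_n / (ref_n + alt_n)


def _ref_slice(reference: Mapping[str, str], chrom: str, start0: int, end0: int) -> str:
    seq = reference[chrom]
    return str(seq[start0:end0]).upper()


def normalize_variant(record: VariantRecord, reference: Mapping[str, str]) -> VariantRecord:
    """Left-align and parsimony-reduce a variant against the reference.

    SNVs pass through unchanged; the operation is idempotent.  Raises
    DataIntegrityError when the REF allele disagrees with the reference.
    """
    ref, alt, pos = record.ref_allele, record.alt_allele, record.pos
    observed = _ref_slice(reference, record.chrom, pos - 1, pos - 1 + len(ref))
    if observed != ref:
        raise DataIntegrityError(
            f"REF {ref!r} does not match reference {observed!r} at {record.chrom}:{pos}"
        )
    # right-trim shared trailing bases, extending left when an allele empties
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:  # cannot extend past the chromosome start: restore the anchor
                left = _ref_slice(reference, record.chrom, 0, 1)
                ref, alt = left + ref, left + alt
                break
            pos -= 1
            left = _ref_slice(reference, record.chrom, pos - 1, pos)
            ref, alt = left + ref, left + alt
    # left-trim shared leading bases while both alleles stay non-empty
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    if (ref, alt, pos) == (record.ref_allele, record.alt_allele, record.pos):
        return record
    return replace(record, pos=pos, ref_allele=ref, alt_allele=alt)


def _quality_gate_reason(record: VariantRecord, min_qual: float, min_depth: int) -> Optional[str]:
    if record.total_depth is None:
        return "missing-depth"
    if record.qual < min_qual:
        return f"QUAL<{min_qual}"
    if record.total_depth < min_depth:
        return f"DP<{min_depth}"
    return None


def apply_quality_gate(
    records: Sequence[VariantRecord], min_qual: float = 10.0, min_depth: int = 10
) -> list[VariantRecord]:
    """Keep records with QUAL >= min_qual and DP >= min_depth (both inclusive)."""
    return [r for r in records if _quality_gate_reason(r, min_qual, min_depth) is None]


def apply_hard_filters(record: VariantRecord) -> tuple[bool, Optional[str]]:
    """(kept, reason) under the per-class hard-filter thresholds.

    A record is removed iff any condition for its class holds; an absent
    annotation makes that condition unevaluable (kept).
    """
    rules = HARD_FILTERS_SNV if record.variant_class == "SNV" else HARD_FILTERS_INDEL
    for name, (direction, threshold) in rules.items():
        value = record.annotations.get(name)
        if value is None:
            continue
        if (direction == "lt" and value < threshold) or (direction == "gt" and value > threshold):
            return False, name
    return True, None


class IntervalSet:
    """Sorted, maximally merged, non-overlapping intervals per chromosome.

    Intervals are 0-based half-open (BED convention).
    """

    def __init__(self, merged: Optional[dict[str, list[tuple[int, int]]]] = None):
        self._intervals: dict[str, list[tuple[int, int]]] = merged or {}
        self._starts = {c: [s for s, _ in ivs] for c, ivs in self._intervals.items()}

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._intervals.get(chrom, []))

    def chroms(self) -> list[str]:
        return sorted(self._intervals)

    def __len__(self) -> int:
        return sum(len(v) for v in self._intervals.values())

    def total_length(self) -> int:
        return sum(e - s for ivs in self._intervals.values() for s, e in ivs)

    def overlaps(self, chrom: str, start: int, end: int, pad: int = 0) -> bool:
        """Does [start, end) intersect any interval expanded by pad on each side?"""
        ivs = self._intervals.get(chrom)
        if not ivs:
            return False
        idx = bisect.bisect_right(self._starts[chrom], end + pad) - 1
        for i in (idx, idx + 1):
            if 0 <= i < len(ivs):
                s, e = ivs[i]
                if start < e + pad and s - pad < end:
                    return True
        return False

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        raw = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                raw.append((chrom, int(start), int(end)))
        return merge_repeat_track(raw)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._intervals):
                for s, e in self._intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def merge_repeat_track(
    raw_intervals: Iterable[tuple[str, int, int]] | Mapping[str, Iterable[tuple[int, int]]],
) -> IntervalSet:
    """Merge raw intervals into a maximal, sorted, non-adjacent IntervalSet.

    A base is covered by the output iff it is covered by some input interval
    (union-preserving); adjacent intervals are coalesced.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    if isinstance(raw_intervals, Mapping):
        items = [(c, s, e) for c, ivs in raw_intervals.items() for s, e in ivs]
    else:
        items = [(c, int(s), int(e)) for c, s, e in raw_intervals]
    for chrom, start, end in items:
        if start >= end:
            raise InvalidArgumentError(f"degenerate interval {chrom}:{start}-{end}")
        per_chrom[chrom].append((start, end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        out = [ivs[0]]
        for s, e in ivs[1:]:
            last_s, last_e = out[-1]
            if s <= last_e:  # overlap or adjacency
                out[-1] = (last_s, max(last_e, e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return IntervalSet(merged)


def filter_repeats(
    records: Sequence[VariantRecord], repeats: IntervalSet, pad: int = 1
) -> list[VariantRecord]:
    """Remove records whose REF footprint intersects a repeat expanded by pad bp."""
    return [r for r in records if not repeats.overlaps(r.chrom, *r.footprint, pad=pad)]


def filter_known_strain(
    records: Sequence[VariantRecord],
    catalog: Sequence[VariantRecord],
    match_alleles: bool = True,
) -> list[VariantRecord]:
    """Remove records coincident with a catalogued strain allele.

    "Coincident" is an exact normalized (chrom, pos, ref, alt) match by
    default; ``match_alleles=False`` relaxes this to position only.
    """
    if match_alleles:
        keys = {c.key for c in catalog}
        return [r for r in records if r.key not in keys]
    positions = {(c.chrom, c.pos) for c in catalog}
    return [r for r in records if (r.chrom, r.pos) not in positions]


def filter_shared(
    cohort_records: Mapping[str, Sequence[VariantRecord]],
) -> dict[str, list[VariantRecord]]:
    """Remove any variant key present in two or more distinct samples' lists."""
    shared = shared_keys(cohort_records)
    return {
        sample: [r for r in records if r.key not in shared]
        for sample, records in cohort_records.items()
    }


def shared_keys(cohort_records: Mapping[str, Sequence[VariantRecord]]) -> set:
    counts: dict[tuple, int] = defaultdict(int)
    for records in cohort_records.values():
        for key in {r.key for r in records}:
            counts[key] += 1
    return {key for key, n in counts.items() if n >= 2}


@dataclass
class FilterTrace:
    """Audit trail of the cascade: one removal entry or one final 'kept' entry
    per input variant, so removals + survivors always equals the input count."""

    entries: list[tuple[str, tuple, str, str, str]] = field(default_factory=list)
    # (sample_id, variant key, stage, action, reason)

    def record(self, record: VariantRecord, stage: str, action: str, reason: str = "") -> None:
        self.entries.append((record.sample_id, record.key, stage, action, reason))

    @property
    def n_removed(self) -> int:
        return sum(1 for e in self.entries if e[3] == "removed")

    @property
    def n_kept(self) -> int:
        return sum(1 for e in self.entries if e[3] == "kept")

    def stage_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for _, _, stage, action, _ in self.entries:
            if action == "removed":
                counts[stage] += 1
        return dict(counts)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "sample": sample,
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "stage": stage,
                "action": action,
                "reason": reason,
            }
            for sample, key, stage, action, reason in self.entries
        ]
        return pd.DataFrame(
            rows, columns=["sample", "chrom", "pos", "ref", "alt", "stage", "action", "reason"]
        )


STAGES = ("quality_gate", "hard_filters", "vaf", "strain_catalog", "repeats", "shared")


def _run_cascade(
    records: Sequence[VariantRecord],
    shared: set,
    catalog_keys: set,
    repeats: IntervalSet,
    min_vaf: float,
    min_qual: float,
    min_depth: int,
    pad: int,
    trace: FilterTrace,
) -> list[VariantRecord]:
    survivors = []
    for r in records:
        reason = _quality_gate_reason(r, min_qual, min_depth)
        if reason is not None:
            trace.record(r, "quality_gate", "removed", reason)
            continue
        kept, hf_reason = apply_hard_filters(r)
        if not kept:
            trace.record(r, "hard_filters", "removed", hf_reason or "")
            continue
        if compute_vaf(r) < min_vaf:
            trace.record(r, "vaf", "removed", f"VAF<{min_vaf}")
            continue
        if r.key in catalog_keys:
            trace.record(r, "strain_catalog", "removed", "catalogued strain allele")
            continue
        if repeats.overlaps(r.chrom, *r.footprint, pad=pad):
            trace.record(r, "repeats", "removed", f"within {pad} bp of merged repeat")
            continue
        if r.key in shared:
            trace.record(r, "shared", "removed", "shared by >=2 samples")
            continue
        trace.record(r, "final", "kept")
        survivors.append(r)
    return survivors


def cohort_candidate_dnms(
    cohort_records: Mapping[str, Sequence[VariantRecord]],
    strain_catalog: Sequence[VariantRecord],
    repeats: IntervalSet,
    min_vaf: float = 0.05,
    *,
    reference: Optional[Mapping[str, str]] = None,
    min_qual: float = 10.0,
    min_depth: int = 10,
    pad: int = 1,
) -> tuple[dict[str, list[VariantRecord]], dict[str, FilterTrace]]:
    """Run the full candidate-DNM cascade for every sample of a cohort.

    Cross-sample sharing is computed over the post-quality-gate sets of ALL
    samples (controls included) so that a shared artifact is detected even
    when another per-sample filter would mask it in one of its carriers.
    When ``reference`` is given, records and catalog are normalized first.
    """
    if reference is not None:
        cohort_records = {
            sample: [normalize_variant(r, reference) for r in records]
            for sample, records in cohort_records.items()
        }
        strain_catalog = [normalize_variant(r, reference) for r in strain_catalog]
    gated = {
        sample: apply_quality_gate(records, min_qual, min_depth)
        for sample, records in cohort_records.items()
    }
    shared = shared_keys(gated)
    catalog_keys = {c.key for c in strain_catalog}
    candidates: dict[str, list[VariantRecord]] = {}
    traces: dict[str, FilterTrace] = {}
    for sample, records in cohort_records.items():
        trace = FilterTrace()
        candidates[sample] = _run_cascade(
            records, shared, catalog_keys, repeats, min_vaf, min_qual, min_depth, pad, trace
        )
        traces[sample] = trace
    return candidates, traces


def candidate_dnms(
    sample_records: Sequence[VariantRecord],
    cohort_records: Mapping[str, Sequence[VariantRecord]],
    strain_catalog: Sequence[VariantRecord],
    repeats: IntervalSet,
    min_vaf: float = 0.05,
    *,
    reference: Optional[Mapping[str, str]] = None,
    min_qual: float = 10.0,
    min_depth: int = 10,
    pad: int = 1,
) -> tuple[list[VariantRecord], FilterTrace]:
    """Candidate de novo mutations for one sample, with a complete FilterTrace.

    ``cohort_records`` must contain every cohort sample (used for the
    shared-variant criterion); ``sample_records`` are the records audited.
    """
    if reference is not None:
        sample_records = [normalize_variant(r, reference) for r in sample_records]
        cohort_records = {
            sample: [normalize_variant(r, reference) for r in records]
            for sample, records in cohort_records.items()
        }
        strain_catalog = [normalize_variant(r, reference) for r in strain_catalog]
    gated = {
        sample: apply_quality_gate(records, min_qual, min_depth)
        for sample, records in cohort_records.items()
    }
    shared = shared_keys(gated)
    catalog_keys = {c.key for c in strain_catalog}
    trace = FilterTrace()
    survivors = _run_cascade(
        sample_records, shared, catalog_keys, repeats, min_vaf, min_qual, min_depth, pad, trace
    )
    return survivors, trace
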