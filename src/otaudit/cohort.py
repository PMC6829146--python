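"""Final-variant derivation, off-target attribution and transmission checks.

After the per-sample candidate DNM cascade, candidates of edited animals are
compared against the uninjected controls: any candidate coincident with a
control candidate is removed, and the survivors are the sample's *final*
variants.  Final variants are then attributed to predicted off-target sites
(footprint overlap with the protospacer+PAM interval expanded by a small
margin), and attributed founder variants are looked up in the offspring's
post-quality-gate call sets to decide germline transmission.  Inheritance is
deliberately checked against the *unfiltered* (quality-gated only) offspring
calls: the shared-variant criterion of the DNM cascade would otherwise mask
any transmitted allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .filtering import VariantRecord
from .offtargets import OfftargetSite
from .stats import median_count

__all__ = [
    "SampleMeta",
    "AttributionReport",
    "subtract_control_coincident",
    "attribute_offtargets",
    "check_inheritance",
    "build_counts_table",
]

#: default slack (bp) around a site interval when attributing variants;
#: Cas9 cleaves ~3 bp 5' of the PAM and left-alignment can shift indel anchors
DEFAULT_ATTRIBUTION_MARGIN = 5


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str  # e.g. edited_strain_A / edited_strain_B / control
    relationship: str  # founder | offspring | none
    parent_id: Optional[str] = None

    def __post_init__(self):
        if self.relationship == "offspring" and not self.parent_id:
            raise ValueError(f"offspring {self.sample_id} lacks a parent_id")


@dataclass
class AttributionReport:
    """Final variants attributed to predicted off-target sites for one sample."""

    sample_id: str
    attributed: list[tuple[VariantRecord, OfftargetSite]] = field(default_factory=list)
    unattributed: list[VariantRecord] = field(default_factory=list)
    predicted_site_counts: dict[str, int] = field(default_factory=dict)  # guide -> n sites
    margin: int = DEFAULT_ATTRIBUTION_MARGIN

    @property
    def n_attributed_variants(self) -> int:
        return len({r.key for r, _ in self.attributed})

    def attributed_keys(self) -> set:
        return {r.key for r, _ in self.attributed}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref_allele,
                "alt": r.alt_allele,
                "variant_class": r.variant_class,
                "guide": s.guide_name,
                "site_chrom": s.chrom,
                "site_start": s.start,
                "site_end": s.end,
                "site_strand": s.strand,
                "site_mismatches": s.mismatches,
            }
            for r, s in self.attributed
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sample", "chrom", "pos", "ref", "alt", "variant_class", "guide",
                "site_chrom", "site_start", "site_end", "site_strand", "site_mismatches",
            ],
        )


def subtract_control_coincident(
    candidates: Sequence[VariantRecord],
    control_candidate_sets: Mapping[str, Sequence[VariantRecord]],
) -> list[VariantRecord]:
    """Remove candidates whose normalized key occurs in ANY control's candidates."""
    control_keys = {
        r.key for records in control_candidate_sets.values() for r in records
    }
    return [r for r in candidates if r.key not in control_keys]


def attribute_offtargets(
    final_variants: Sequence[VariantRecord],
    sites: Sequence[OfftargetSite],
    margin: int = DEFAULT_ATTRIBUTION_MARGIN,
    sample_id: str = "",
) -> AttributionReport:
    """Attribute final variants to sites whose expanded interval they touch.

    A variant is attributed iff its REF footprint intersects
    [site.start - margin, site.end + margin); a variant overlapping several
    sites is reported once per site.
    """
    report = AttributionReport(sample_id=sample_id, margin=margin)
    for guide in sorted({s.guide_name for s in sites}):
        report.predicted_site_counts[guide] = sum(1 for s in sites if s.guide_name == guide)
    for record in final_variants:
        start, end = record.footprint
        hits = [
            s
            for s in sites
            if s.chrom == record.chrom and start < s.end + margin and s.start - margin < end
        ]
        if hits:
            for s in hits:
                report.attributed.append((record, s))
        else:
            report.unattributed.append(record)
    return report


def check_inheritance(
    attributed: AttributionReport,
    offspring_callsets: Mapping[str, Sequence[VariantRecord]],
) -> pd.DataFrame:
    """Presence of each attributed founder variant in each offspring call set.

    ``offspring_callsets`` must be the post-quality-gate sets (not the fully
    DNM-filtered sets).  Returns one row per (variant, offspring) with a
    ``present`` flag plus a ``transmitted_any`` summary per variant.
    """
    rows = []
    seen = set()
    for record, site in attributed.attributed:
        if record.key in seen:
            continue
        seen.add(record.key)
        offspring_present = {
            child: any(r.key == record.key for r in records)
            for child, records in offspring_callsets.items()
        }
        for child in sorted(offspring_present):
            rows.append(
                {
                    "founder": attributed.sample_id,
                    "chrom": record.chrom,
                    "pos": record.pos,
                    "ref": record.ref_allele,
                    "alt": record.alt_allele,
                    "guide": site.guide_name,
                    "offspring": child,
                    "present": offspring_present[child],
                    "transmitted_any": any(offspring_present.values()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "founder", "chrom", "pos", "ref", "alt", "guide",
            "offspring", "present", "transmitted_any",
        ],
    )


def _class_counts(records: Sequence[VariantRecord]) -> tuple[int, int]:
    snv = sum(1 for r in records if r.variant_class == "SNV")
    return snv, len(records) - snv


def build_counts_table(
    candidates: Mapping[str, Sequence[VariantRecord]],
    finals: Mapping[str, Sequence[VariantRecord]],
    sample_meta: pd.DataFrame,
    caller: str = "synthetic",
) -> pd.DataFrame:
    """Per-sample candidate/final SNV and indel counts with a median row.

    The median of an odd-length column is its middle order statistic.
    Controls have no final-variant entry (the control subtraction applies to
    edited animals); their final counts equal their candidate counts.
    """
    rows = []
    for row in sample_meta.itertuples(index=False):
        sample = row.sample_id
        cand_snv, cand_indel = _class_counts(candidates.get(sample, []))
        fin = finals.get(sample, candidates.get(sample, []))
        fin_snv, fin_indel = _class_counts(fin)
        rows.append(
            {
                "sample": sample,
                "group": row.group,
                "relationship": row.relationship,
                "caller": caller,
                "candidate_snvs": cand_snv,
                "candidate_indels": cand_indel,
                "final_snvs": fin_snv,
                "final_indels": fin_indel,
            }
        )
    table = pd.DataFrame(rows)
    median_row = {
        "sample": "median",
        "group": "",
        "relationship": "",
        "caller": caller,
        **{
            col: median_count(list(table[col]))
            for col in ("candidate_snvs", "candidate_indels", "final_snvs", "final_indels")
        },
    }
    return pd.concat([table, pd.DataFrame([median_row])], ignore_index=True)
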