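"""Self-contained synthetic cohort generator for the off-target audit.

Emulates, at toy genome scale, the structure of a CRISPR-Cas9 editing study
cohort: a small number of edited founders carrying mosaic off-target indels
planted at guide-matching sites, their offspring (Mendelian transmission of
constitutional heterozygous founder alleles), and uninjected controls.  Each
sample's call set mixes:

* background de novo SNVs and indels (Poisson-distributed per sample),
  either constitutional heterozygous (VAF 0.5) or mosaic (VAF drawn from a
  configurable range),
* planted off-target indels at the founder's guide sites, at a mosaic VAF,
* shared artifact variants recurring in two or more samples,
* strain-catalog variants present both in samples and in the catalog,
* caller annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum) drawn from a
  passing component for most records and a failing component for a
  configurable fraction, so the hard-filter logic is exercised,
* QUAL/DP values with a configurable low-quality fraction, and
* a random repeat track covering a configurable fraction of the genome.

Transmission model: only constitutional heterozygous variants (VAF = 0.5)
are germline and transmissible; mosaic variants (VAF < 0.5) are confined to
somatic lineages and never transmitted.  With the default mosaic off-target
VAF the planted off-target alleles therefore stay in the founder, which is
the regime the audit's round-trip checks assume; setting
``planted_offtarget_vaf=0.5`` makes off-targets transmissible with
probability ``transmission_prob``.

Every generated record is logged in a TruthTable (a tidy DataFrame) with its
label (background_dnm / planted_offtarget / shared_artifact / strain_variant
/ inherited), VAF, depth, quality, whether its annotations pass the hard
filters, and whether it falls in (or within 1 bp of) a repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError
from .filtering import (
    IntervalSet,
    VariantRecord,
    apply_hard_filters,
    merge_repeat_track,
    normalize_variant,
)
from .offtargets import GuideRNA, OfftargetSite, write_guides_table
from .sequences import IUPAC, reverse_complement, write_fasta
from .vcfio import write_vcf

__all__ = [
    "CohortDesign",
    "SimulatedCohort",
    "generate_reference",
    "plant_offtarget_sites",
    "simulate_cohort",
    "write_cohort",
]

TRUTH_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "label", "vaf", "dp", "qual",
    "anno_pass", "in_repeat", "site_id", "origin_founder",
]

#: minimum clearance (bp) kept between planted sites / variants and each other
SITE_CLEARANCE = 60
VARIANT_CLEARANCE = 12


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of the simulated cohort.

    Rates are expected events per sample (Poisson means) at toy genome
    scale; fractions are in [0, 1].  ``het_fraction`` is the probability a
    background founder/offspring/control variant is constitutional
    heterozygous (VAF 0.5, germline) rather than mosaic.
    """

    n_founders: int = 2
    n_offspring_per_founder: int = 2
    n_controls: int = 3
    background_snv_rate: float = 60.0
    background_indel_rate: float = 15.0
    mosaic_vaf_range: tuple[float, float] = (0.05, 0.5)
    n_planted_offtargets_per_founder: int = 2
    planted_offtarget_vaf: float = 0.35
    transmission_prob: float = 0.5
    n_shared_artifacts: int = 5
    n_strain_variants: int = 30
    repeat_fraction: float = 0.2
    het_fraction: float = 0.5
    lowqual_fraction: float = 0.05
    hardfilter_fail_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_founders, self.n_offspring_per_founder, self.n_controls) < 0:
            raise InvalidArgumentError("cohort sizes must be non-negative")
        if self.background_snv_rate < 0 or self.background_indel_rate < 0:
            raise InvalidArgumentError("rates must be >= 0")
        lo, hi = self.mosaic_vaf_range
        if not (0 < lo <= hi <= 1):
            raise InvalidArgumentError("mosaic_vaf_range must satisfy 0 < low <= high <= 1")
        for name in ("planted_offtarget_vaf", "transmission_prob", "repeat_fraction",
                     "het_fraction", "lowqual_fraction", "hardfilter_fail_fraction"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise InvalidArgumentError(f"{name} must be in [0,1], got {value}")
        if self.n_shared_artifacts > 0 and self.n_controls + self.n_founders * (
            1 + self.n_offspring_per_founder
        ) < 2:
            raise InvalidArgumentError("shared artifacts need a cohort of >= 2 samples")


@dataclass
class SimulatedCohort:
    """Everything the audit needs, in memory, plus the ground truth."""

    genome: dict[str, str]
    guides: list[GuideRNA]
    sites: list[OfftargetSite]
    samples: dict[str, list[VariantRecord]]
    sample_meta: pd.DataFrame  # sample_id, group, relationship, parent_id
    repeats: IntervalSet
    strain_catalog: list[VariantRecord]
    truth: pd.DataFrame
    design: CohortDesign = field(default_factory=CohortDesign)


def generate_reference(
    n_chromosomes: int, chrom_length: int, gc_fraction: float, seed: int
) -> dict[str, str]:
    """Random i.i.d. genome with the requested GC content; deterministic per seed."""
    if n_chromosomes < 1 or chrom_length < 1:
        raise InvalidArgumentError("need >= 1 chromosome of positive length")
    if not (0 < gc_fraction <= 1):
        raise InvalidArgumentError("gc_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(
            bases[rng.choice(4, size=chrom_length, p=[at, gc, gc, at])]
        )
        for i in range(n_chromosomes)
    }


def _concrete_pam(pattern: str) -> str:
    return "".join(sorted(IUPAC[c])[0] for c in pattern)


def _mutate_protospacer(protospacer: str, n_mismatches: int) -> str:
    """Deterministically introduce mismatches at the PAM-distal end.

    Cas9 tolerates PAM-distal mismatches best, so planted mismatches go at
    the 5' end; each substituted base cycles to the next base in ACGT order.
    """
    if n_mismatches > len(protospacer):
        raise InvalidArgumentError("more mismatches requested than protospacer bases")
    order = "ACGT"
    out = list(protospacer)
    for i in range(n_mismatches):
        out[i] = order[(order.index(out[i]) + 1) % 4]
    return "".join(out)


def plant_offtarget_sites(
    genome: dict[str, str],
    guide: GuideRNA,
    site_specs: Sequence[tuple],
) -> tuple[dict[str, str], list[OfftargetSite]]:
    """Write guide-matching windows into the genome at requested loci.

    Each spec is (mismatch_count, strand, position[, chrom]); chrom defaults
    to the first chromosome.  The planted locus, read 5'->3' on its strand,
    differs from the protospacer at exactly ``mismatch_count`` positions and
    is immediately followed by a window matching the PAM pattern.  Specs
    whose windows would overlap raise InvalidArgumentError.
    """
    new_genome = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    default_chrom = next(iter(genome))
    w_len = guide.window_length
    planted: list[OfftargetSite] = []
    occupied: list[tuple[str, int, int]] = []
    for spec in site_specs:
        if len(spec) == 3:
            mm, strand, pos = spec
            chrom = default_chrom
        else:
            mm, strand, pos, chrom = spec
        if mm < 0:
            raise InvalidArgumentError("mismatch count must be >= 0")
        if strand not in "+-":
            raise InvalidArgumentError(f"bad strand {strand!r}")
        if pos < 0 or pos + w_len > len(new_genome[chrom]):
            raise InvalidArgumentError(f"site at {chrom}:{pos} leaves no room for protospacer+PAM")
        for oc, os_, oe in occupied:
            if oc == chrom and pos < oe and os_ < pos + w_len:
                raise InvalidArgumentError(f"planted sites overlap at {chrom}:{pos}")
        occupied.append((chrom, pos, pos + w_len))
        window = _mutate_protospacer(guide.protospacer, mm) + _concrete_pam(guide.pam_pattern)
        genomic = window if strand == "+" else reverse_complement(window)
        new_genome[chrom][pos : pos + w_len] = genomic.encode("ascii")
        planted.append(
            OfftargetSite(
                chrom=chrom,
                start=pos,
                end=pos + w_len,
                strand=strand,
                mismatches=mm,
                site_sequence=window,
                guide_name=guide.name,
            )
        )
    return {name: seq.decode("ascii") for name, seq in new_genome.items()}, planted


class _PositionPool:
    """Draws variant positions keeping clearance from planted sites and each other."""

    def __init__(self, genome: dict[str, str], rng: np.random.Generator,
                 forbidden: Sequence[tuple[str, int, int]]):
        self.genome = genome
        self.rng = rng
        self.chroms = sorted(genome)
        self.lengths = np.array([len(genome[c]) for c in self.chroms], dtype=float)
        self.forbidden = list(forbidden)
        self.used: dict[str, list[int]] = {c: [] for c in self.chroms}

    def draw(self, span: int = 1, clearance: int = VARIANT_CLEARANCE) -> tuple[str, int]:
        """A fresh (chrom, 0-based position) with room for ``span`` bases."""
        weights = self.lengths / self.lengths.sum()
        for _ in range(10_000):
            chrom = self.chroms[int(self.rng.choice(len(self.chroms), p=weights))]
            limit = len(self.genome[chrom]) - span - 2
            pos = int(self.rng.integers(2, limit))
            if any(
                c == chrom and pos - clearance < e and s < pos + span + clearance
                for c, s, e in self.forbidden
            ):
                continue
            if any(abs(pos - u) < clearance for u in self.used[chrom]):
                continue
            self.used[chrom].append(pos)
            return chrom, pos
        raise InvalidArgumentError("could not place a variant; genome too small for the design")


def _draw_annotations(rng: np.random.Generator, variant_class: str, fail: bool) -> dict:
    """Caller annotations from a passing or a failing mixture component."""
    if not fail:
        return {
            "QD": float(rng.uniform(5.0, 30.0)),
            "FS": float(rng.uniform(0.0, 20.0)),
            "MQ": float(rng.uniform(50.0, 60.0)),
            "MQRankSum": float(rng.uniform(-3.0, 3.0)),
            "ReadPosRankSum": float(rng.uniform(-3.0, 3.0)),
        }
    anno = {
        "QD": float(rng.uniform(5.0, 30.0)),
        "FS": float(rng.uniform(0.0, 20.0)),
        "MQ": float(rng.uniform(50.0, 60.0)),
        "MQRankSum": float(rng.uniform(-3.0, 3.0)),
        "ReadPosRankSum": float(rng.uniform(-3.0, 3.0)),
    }
    if variant_class == "SNV":
        culprit = rng.choice(["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"])
        fail_values = {
            "QD": rng.uniform(0.1, 1.9),
            "FS": rng.uniform(61.0, 300.0),
            "MQ": rng.uniform(5.0, 39.0),
            "MQRankSum": rng.uniform(-30.0, -13.0),
            "ReadPosRankSum": rng.uniform(-30.0, -8.5),
        }
    else:
        culprit = rng.choice(["QD", "FS", "ReadPosRankSum"])
        fail_values = {
            "QD": rng.uniform(0.1, 1.9),
            "FS": rng.uniform(201.0, 500.0),
            "ReadPosRankSum": rng.uniform(-40.0, -20.5),
        }
    anno[str(culprit)] = float(fail_values[str(culprit)])
    return anno


def _depth_qual(rng: np.random.Generator, lowqual: bool) -> tuple[int, float]:
    if lowqual:
        if rng.random() < 0.5:
            return int(rng.integers(2, 10)), float(rng.uniform(30.0, 500.0))
        return max(12, int(round(rng.normal(100.0, 15.0)))), float(rng.uniform(0.0, 9.5))
    return max(20, int(round(rng.normal(100.0, 15.0)))), float(rng.uniform(50.0, 2000.0))


def _make_record(
    rng: np.random.Generator,
    genome: dict[str, str],
    chrom: str,
    pos0: int,
    kind: str,  # "SNV" | "indel"
    vaf: float,
    sample_id: str,
    lowqual: bool,
    anno_fail: bool,
) -> VariantRecord:
    """Build one normalized VariantRecord at a 0-based position."""
    seq = genome[chrom]
    if kind == "SNV":
        ref = seq[pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        pos1 = pos0 + 1
    else:
        length = int(rng.integers(1, 5))
        if rng.random() < 0.5:  # deletion anchored at pos0
            ref = seq[pos0 : pos0 + 1 + length]
            alt = seq[pos0]
        else:  # insertion after pos0
            ref = seq[pos0]
            alt = ref + "".join(rng.choice(list("ACGT"), size=length))
        pos1 = pos0 + 1
    dp, qual = _depth_qual(rng, lowqual)
    alt_reads = max(1, int(round(dp * vaf)))
    alt_reads = min(alt_reads, dp)
    record = VariantRecord(
        chrom=chrom,
        pos=pos1,
        ref_allele=ref,
        alt_allele=alt,
        total_depth=dp,
        qual=qual,
        allele_depths=(dp - alt_reads, alt_reads),
        genotype="het" if vaf < 1.0 else "hom_alt",
        annotations=_draw_annotations(rng, "SNV" if kind == "SNV" else "indel", anno_fail),
        sample_id=sample_id,
        caller="synthetic",
    )
    return normalize_variant(record, genome)


def _cut_position(site: OfftargetSite, pam_len: int) -> int:
    """0-based blunt-cut coordinate, 3 bp inside the protospacer from the PAM."""
    if site.strand == "+":
        return site.end - pam_len - 3
    return site.start + pam_len + 3


def _random_repeat_track(
    rng: np.random.Generator,
    genome: dict[str, str],
    repeat_fraction: float,
    forbidden: Sequence[tuple[str, int, int]],
) -> IntervalSet:
    """Random intervals totalling ~repeat_fraction of the genome, avoiding sites."""
    total = sum(len(s) for s in genome.values())
    target = repeat_fraction * total
    raw: list[tuple[str, int, int]] = []
    covered = 0.0
    chroms = sorted(genome)
    attempts = 0
    while covered < target and attempts < 20_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(200, 2000))
        if length + 2 >= len(genome[chrom]):
            continue
        start = int(rng.integers(0, len(genome[chrom]) - length))
        end = start + length
        if any(c == chrom and start - 5 < e and s < end + 5 for c, s, e in forbidden):
            continue
        raw.append((chrom, start, end))
        covered += length  # approximation; overlaps double-count slightly
    if not raw:
        return IntervalSet({})
    return merge_repeat_track(raw)


def _guides_for_founder(guides: Sequence[GuideRNA], founder_index: int, n_founders: int):
    """Split the guide list evenly across founders (contiguous blocks)."""
    per = max(1, len(guides) // max(1, n_founders))
    block = guides[founder_index * per : (founder_index + 1) * per]
    return list(block) if block else [guides[founder_index % len(guides)]]


def simulate_cohort(
    genome: dict[str, str],
    guides: Sequence[GuideRNA],
    design: CohortDesign,
) -> SimulatedCohort:
    """Generate the full synthetic cohort; deterministic for a fixed design.

    Off-target sites for each founder's guides are planted into the genome
    first (the returned cohort carries the modified genome), then per-sample
    variant call sets, the repeat track, the strain catalog and the
    TruthTable are drawn from the design's seed.
    """
    if not guides:
        raise InvalidArgumentError("at least one guide is required")
    if design.n_shared_artifacts > 0 and design.n_controls == 0 and design.n_founders == 0:
        raise InvalidArgumentError("shared artifacts need samples to share")
    rng = np.random.default_rng(design.seed)

    # --- sample roster -------------------------------------------------
    letter_pool = "MPQRSTUVWXYZABCDEFGHIJKLNO"
    letters = [letter_pool[i % len(letter_pool)] for i in range(design.n_founders)]
    meta_rows = []
    founder_ids: list[str] = []
    for i, letter in enumerate(letters):
        group = f"edited_strain_{chr(ord('A') + i)}"
        founder = f"{letter}01"
        founder_ids.append(founder)
        meta_rows.append((founder, group, "founder", ""))
        for j in range(design.n_offspring_per_founder):
            meta_rows.append((f"{letter}{j + 2:02d}", group, "offspring", founder))
    for j in range(design.n_controls):
        meta_rows.append((f"WT{j + 1}", "control", "none", ""))
    sample_meta = pd.DataFrame(meta_rows, columns=["sample_id", "group", "relationship", "parent_id"])
    sample_ids = list(sample_meta["sample_id"])

    # --- plant off-target sites ---------------------------------------
    sites: list[OfftargetSite] = []
    sites_by_founder: dict[str, list[OfftargetSite]] = {f: [] for f in founder_ids}
    chroms = sorted(genome)
    occupied: list[tuple[str, int, int]] = []
    for i, founder in enumerate(founder_ids):
        founder_guides = _guides_for_founder(list(guides), i, design.n_founders)
        specs_per_guide: dict[str, list[tuple]] = {g.name: [] for g in founder_guides}
        for k in range(design.n_planted_offtargets_per_founder):
            guide = founder_guides[k % len(founder_guides)]
            w_len = guide.window_length
            for _ in range(10_000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(100, len(genome[chrom]) - w_len - 100))
                if any(
                    c == chrom and pos - SITE_CLEARANCE < e and s < pos + w_len + SITE_CLEARANCE
                    for c, s, e in occupied
                ):
                    continue
                occupied.append((chrom, pos, pos + w_len))
                break
            else:
                raise InvalidArgumentError("guide not plantable: no room left in genome")
            mm = int(rng.integers(0, 3))
            strand = "+" if rng.random() < 0.5 else "-"
            specs_per_guide[guide.name].append((mm, strand, pos, chrom))
        for guide in founder_guides:
            if specs_per_guide[guide.name]:
                genome, planted = plant_offtarget_sites(genome, guide, specs_per_guide[guide.name])
                sites.extend(planted)
                sites_by_founder[founder].extend(planted)
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))

    # --- repeat track --------------------------------------------------
    site_zones = [(s.chrom, s.start - SITE_CLEARANCE, s.end + SITE_CLEARANCE) for s in sites]
    repeats = _random_repeat_track(rng, genome, design.repeat_fraction, site_zones)

    pool = _PositionPool(genome, rng, site_zones)
    samples: dict[str, list[VariantRecord]] = {s: [] for s in sample_ids}
    truth_rows: list[dict] = []

    def log(record: VariantRecord, label: str, vaf: float, site_id: str = "",
            origin_founder: str = "") -> None:
        kept, _ = apply_hard_filters(record)
        # the realized allele fraction (after integer AD rounding) is what the
        # VAF gate sees, so that is what the truth table records
        vaf = record.allele_depths[1] / max(1, sum(record.allele_depths))
        truth_rows.append(
            {
                "sample": record.sample_id,
                "chrom": record.chrom,
                "pos": record.pos,
                "ref": record.ref_allele,
                "alt": record.alt_allele,
                "label": label,
                "vaf": vaf,
                "dp": record.total_depth,
                "qual": record.qual,
                "anno_pass": kept,
                "in_repeat": repeats.overlaps(record.chrom, *record.footprint, pad=1),
                "site_id": site_id,
                "origin_founder": origin_founder,
            }
        )

    # --- strain-catalog variants --------------------------------------
    strain_catalog: list[VariantRecord] = []
    for _ in range(design.n_strain_variants):
        chrom, pos0 = pool.draw()
        template = _make_record(rng, genome, chrom, pos0, "SNV", 0.5, "", False, False)
        strain_catalog.append(template)
        carriers = [s for s in sample_ids if rng.random() < 0.8]
        if not carriers:
            carriers = [sample_ids[int(rng.integers(len(sample_ids)))]]
        for s in carriers:
            dp, qual = _depth_qual(rng, False)
            alt_n = max(1, int(round(dp * 0.5)))
            rec = replace(
                template,
                sample_id=s,
                total_depth=dp,
                qual=qual,
                allele_depths=(dp - alt_n, alt_n),
                annotations=_draw_annotations(rng, template.variant_class, False),
            )
            samples[s].append(rec)
            log(rec, "strain_variant", 0.5)

    # --- shared artifacts ----------------------------------------------
    if design.n_shared_artifacts > 0 and len(sample_ids) >= 2:
        for _ in range(design.n_shared_artifacts):
            chrom, pos0 = pool.draw(span=6)
            kind = "SNV" if rng.random() < 0.5 else "indel"
            vaf = float(rng.uniform(0.1, 0.5))
            template = _make_record(rng, genome, chrom, pos0, kind, vaf, "", False, False)
            n_carriers = int(rng.integers(2, len(sample_ids) + 1))
            carrier_idx = rng.choice(len(sample_ids), size=n_carriers, replace=False)
            for ci in sorted(carrier_idx.tolist()):
                s = sample_ids[ci]
                rec = replace(template, sample_id=s)
                samples[s].append(rec)
                log(rec, "shared_artifact", vaf)

    # --- background de novo mutations ----------------------------------
    germline: dict[str, list[tuple[VariantRecord, float]]] = {f: [] for f in founder_ids}
    for s in sample_ids:
        n_snv = int(rng.poisson(design.background_snv_rate))
        n_indel = int(rng.poisson(design.background_indel_rate))
        for kind, n in (("SNV", n_snv), ("indel", n_indel)):
            for _ in range(n):
                chrom, pos0 = pool.draw(span=6)
                is_het = rng.random() < design.het_fraction
                vaf = 0.5 if is_het else float(rng.uniform(*design.mosaic_vaf_range))
                lowqual = rng.random() < design.lowqual_fraction
                anno_fail = rng.random() < design.hardfilter_fail_fraction
                rec = _make_record(rng, genome, chrom, pos0, kind, vaf, s, lowqual, anno_fail)
                samples[s].append(rec)
                log(rec, "background_dnm", vaf)
                if is_het and s in germline:
                    germline[s].append((rec, vaf))

    # --- planted off-target indels -------------------------------------
    pam_len = None
    guide_by_name = {g.name: g for g in guides}
    for founder in founder_ids:
        for site in sites_by_founder[founder]:
            pam_len = len(guide_by_name[site.guide_name].pam_pattern)
            cut = _cut_position(site, pam_len)
            dlen = int(rng.integers(1, 4))
            ref = genome[site.chrom][cut - 1 : cut + dlen]
            alt = genome[site.chrom][cut - 1]
            dp, qual = _depth_qual(rng, False)
            vaf = design.planted_offtarget_vaf
            alt_n = max(1, int(round(dp * vaf)))
            rec = VariantRecord(
                chrom=site.chrom,
                pos=cut,  # 1-based anchor = 0-based cut-1 + 1
                ref_allele=ref,
                alt_allele=alt,
                total_depth=dp,
                qual=qual,
                allele_depths=(dp - alt_n, alt_n),
                genotype="het",
                annotations=_draw_annotations(rng, "indel", False),
                sample_id=founder,
                caller="synthetic",
            )
            rec = normalize_variant(rec, genome)
            samples[founder].append(rec)
            log(rec, "planted_offtarget", vaf, site_id=site.site_id)
            if vaf >= 0.5:
                germline[founder].append((rec, vaf))

    # --- Mendelian transmission ----------------------------------------
    offspring_of = {
        f: list(sample_meta.loc[sample_meta["parent_id"] == f, "sample_id"]) for f in founder_ids
    }
    for founder in founder_ids:
        for rec, _vaf in germline[founder]:
            site_id = next(
                (
                    row["site_id"]
                    for row in truth_rows
                    if row["sample"] == founder
                    and (row["chrom"], row["pos"], row["ref"], row["alt"]) == rec.key
                    and row["label"] == "planted_offtarget"
                ),
                "",
            )
            for child in offspring_of[founder]:
                if rng.random() < design.transmission_prob:
                    dp, qual = _depth_qual(rng, False)
                    alt_n = max(1, int(round(dp * 0.5)))
                    child_rec = replace(
                        rec,
                        sample_id=child,
                        total_depth=dp,
                        qual=qual,
                        allele_depths=(dp - alt_n, alt_n),
                        annotations=_draw_annotations(rng, rec.variant_class, False),
                    )
                    samples[child].append(child_rec)
                    log(child_rec, "inherited", 0.5, site_id=site_id, origin_founder=founder)

    for s in samples:
        samples[s].sort(key=lambda r: (r.chrom, r.pos, r.ref_allele, r.alt_allele))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["sample", "chrom", "pos", "ref", "alt"]).reset_index(drop=True)
    return SimulatedCohort(
        genome=genome,
        guides=list(guides),
        sites=sites,
        samples=samples,
        sample_meta=sample_meta,
        repeats=repeats,
        strain_catalog=strain_catalog,
        truth=truth,
        design=design,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Materialize a simulated cohort in the directory layout the audit expects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "samples").mkdir(exist_ok=True)
    contigs = {name: len(seq) for name, seq in cohort.genome.items()}
    paths = {
        "genome": outdir / "genome.fa",
        "guides": outdir / "guides.tsv",
        "samples_dir": outdir / "samples",
        "sample_meta": outdir / "samples.tsv",
        "repeats": outdir / "repeats.bed",
        "strain_catalog": outdir / "strain_catalog.vcf",
        "truth": outdir / "truth.tsv",
        "design": outdir / "design.yaml",
    }
    write_fasta(cohort.genome, paths["genome"])
    write_guides_table(cohort.guides, paths["guides"])
    for sample_id, records in cohort.samples.items():
        write_vcf(outdir / "samples" / f"{sample_id}.vcf", records, contigs, sample_id)
    cohort.sample_meta.to_csv(paths["sample_meta"], sep="\t", index=False)
    cohort.repeats.to_bed(paths["repeats"])
    write_vcf(paths["strain_catalog"], cohort.strain_catalog, contigs, sample_id=None)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    design_dict = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cohort.design).items()
    }
    with open(paths["design"], "w") as fh:
        yaml.safe_dump(design_dict, fh, sort_keys=True)
    return paths
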