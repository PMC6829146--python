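"""Filter cascade stages, each checked against a naive predicate/set oracle."""

import numpy as np
import pytest

from otaudit.errors import DataIntegrityError, InvalidArgumentError, UndefinedVAFError
from otaudit.filtering import (
    IntervalSet,
    VariantRecord,
    apply_hard_filters,
    apply_quality_gate,
    candidate_dnms,
    compute_vaf,
    filter_known_strain,
    filter_repeats,
    filter_shared,
    merge_repeat_track,
    normalize_variant,
)


def make_record(chrom="chr1", pos=100, ref="A", alt="G", dp=50, qual=100.0,
                ad=(25, 25), annotations=None, sample="S1"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt, total_depth=dp,
        qual=qual, allele_depths=ad, annotations=annotations or {}, sample_id=sample,
    )


# --- normalization -------------------------------------------------------

def _equivalent_haplotype(seq, pos, ref, alt):
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]


def minimal_leftmost_representation(seq, pos, ref, alt):
    """Oracle: enumerate every equivalent (pos', ref', alt') in a window and
    return the shortest one, breaking length ties by the leftmost position."""
    target = _equivalent_haplotype(seq, pos, ref, alt)
    best = None
    for p in range(max(1, pos - 30), min(len(seq), pos + len(ref) + 5) + 1):
        for rl in range(0, 30):
            if p - 1 + rl > len(seq):
                break
            r = seq[p - 1 : p - 1 + rl]
            a = target[p - 1 : len(target) - (len(seq) - (p - 1 + rl))]
            if not r or not a or r == a:
                continue
            if _equivalent_haplotype(seq, p, r, a) != target:
                continue
            cand = (len(r) + len(a), p, r, a)
            if best is None or cand < best:
                best = cand
    assert best is not None
    return best[1], best[2], best[3]


def test_snv_normalization_is_identity():
    seq = {"chr1": "ACGTACGTACGT"}
    rec = make_record(pos=5, ref="A", alt="G")
    assert normalize_variant(rec, seq) is rec


def test_deletion_in_homopolymer_left_aligns():
    seq = {"chr1": "GGCAAATGG"}  # run of As at 1-based 4-6
    rec = make_record(pos=5, ref="AA", alt="A")  # written mid-run
    norm = normalize_variant(rec, seq)
    assert (norm.pos, norm.ref_allele, norm.alt_allele) == (3, "CA", "C")
    assert normalize_variant(norm, seq) == norm  # idempotent


def test_parsimony_trims_shared_bases():
    seq = {"chr1": "TTACGTACGT"}
    rec = make_record(pos=3, ref="ACG", alt="ATG")  # embedded SNV
    norm = normalize_variant(rec, seq)
    assert (norm.pos, norm.ref_allele, norm.alt_allele) == (4, "C", "T")


def test_reference_mismatch_raises():
    with pytest.raises(DataIntegrityError):
        normalize_variant(make_record(pos=1, ref="T", alt="G"), {"chr1": "AAAA"})


@pytest.mark.parametrize("seed", range(6))
def test_random_indels_match_exhaustive_left_shift_oracle(seed):
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    # low-complexity sequence so shifts actually occur
    seq = "".join(rng.choice(list("AACCGT")) for _ in range(300))
    genome = {"chr1": seq}
    for _ in range(40):
        pos = int(rng.integers(40, 260))
        if rng.random() < 0.5:  # deletion
            dlen = int(rng.integers(1, 5))
            ref, alt = seq[pos - 1 : pos + dlen], seq[pos - 1]
        else:  # insertion
            ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 5))))
            ref, alt = seq[pos - 1], seq[pos - 1] + ins
        norm = normalize_variant(make_record(pos=pos, ref=ref, alt=alt), genome)
        assert (norm.pos, norm.ref_allele, norm.alt_allele) == minimal_leftmost_representation(
            seq, pos, ref, alt
        )
        assert normalize_variant(norm, genome) == norm


# --- quality gate --------------------------------------------------------

def test_quality_gate_boundaries():
    assert apply_quality_gate([make_record(qual=9.9, dp=100)]) == []
    kept = make_record(qual=10.0, dp=10)
    assert apply_quality_gate([kept]) == [kept]
    assert apply_quality_gate([make_record(qual=100, dp=9)]) == []
    assert apply_quality_gate([make_record(qual=100, dp=None)]) == []


def test_quality_gate_equals_predicate_oracle():
    rng = np.random.default_rng(1)
    records = [
        make_record(pos=i + 1, qual=float(rng.uniform(0, 30)), dp=int(rng.integers(0, 30)))
        for i in range(100)
    ]
    kept = apply_quality_gate(records)
    assert kept == [r for r in records if r.qual >= 10 and r.total_depth >= 10]


# --- hard filters --------------------------------------------------------

@pytest.mark.parametrize(
    "ref,alt,annotations,expect_kept,expect_reason",
    [
        ("A", "G", {"QD": 1.5}, False, "QD"),
        ("A", "G", {"FS": 61.0}, False, "FS"),
        ("A", "G", {"MQ": 39.9}, False, "MQ"),
        ("A", "G", {"MQRankSum": -13.0}, False, "MQRankSum"),
        ("A", "G", {"ReadPosRankSum": -8.1}, False, "ReadPosRankSum"),
        ("A", "AT", {"FS": 100.0}, True, None),  # indel FS threshold is 200
        ("A", "AT", {"FS": 201.0}, False, "FS"),
        ("A", "AT", {"MQ": 10.0}, True, None),  # MQ is not an indel condition
        ("A", "AT", {"ReadPosRankSum": -20.5}, False, "ReadPosRankSum"),
        ("A", "G", {"QD": 2.0, "FS": 60.0, "MQ": 40.0, "MQRankSum": -12.5,
                    "ReadPosRankSum": -8.0}, True, None),  # strict inequalities
        ("A", "G", {}, True, None),  # absent annotations never remove
    ],
)
def test_hard_filter_thresholds(ref, alt, annotations, expect_kept, expect_reason):
    kept, reason = apply_hard_filters(make_record(ref=ref, alt=alt, annotations=annotations))
    assert kept is expect_kept
    assert reason == expect_reason


# --- VAF -----------------------------------------------------------------

@pytest.mark.parametrize("ad,expected", [((95, 5), 0.05), ((0, 20), 1.0), ((7, 3), 0.3)])
def test_vaf_arithmetic(ad, expected):
    assert compute_vaf(make_record(ad=ad)) == pytest.approx(expected)


def test_vaf_zero_depth_is_an_error():
    with pytest.raises(UndefinedVAFError):
        compute_vaf(make_record(ad=(0, 0)))


# --- repeat track merging ------------------------------------------------

def test_merge_overlap_and_adjacency():
    merged = merge_repeat_track([("chr1", 10, 20), ("chr1", 15, 30)])
    assert merged.intervals("chr1") == [(10, 30)]
    merged = merge_repeat_track([("chr1", 10, 20), ("chr1", 20, 30)])
    assert merged.intervals("chr1") == [(10, 30)]


def test_merge_rejects_degenerate_interval():
    with pytest.raises(InvalidArgumentError):
        merge_repeat_track([("chr1", 10, 10)])


def test_merge_equals_coverage_bitmap_oracle():
    rng = np.random.default_rng(2)
    raw = []
    for _ in range(200):
        start = int(rng.integers(0, 990))
        raw.append(("chr1", start, start + int(rng.integers(1, 40))))
    merged = merge_repeat_track(raw)
    bitmap = np.zeros(1100, dtype=bool)
    for _, s, e in raw:
        bitmap[s:e] = True
    merged_bitmap = np.zeros(1100, dtype=bool)
    for s, e in merged.intervals("chr1"):
        merged_bitmap[s:e] = True
    assert np.array_equal(bitmap, merged_bitmap)
    ivs = merged.intervals("chr1")
    assert all(e > s for s, e in ivs)
    assert all(ivs[i + 1][0] > ivs[i][1] for i in range(len(ivs) - 1))  # non-adjacent


# --- repeat proximity filter --------------------------------------------

def test_repeat_filter_pad_boundary():
    repeats = merge_repeat_track([("chr1", 10, 30)])
    at_31 = make_record(pos=31)  # footprint {30} touches (9, 31) once padded
    at_32 = make_record(pos=32)
    assert filter_repeats([at_31, at_32], repeats, pad=1) == [at_32]
    assert filter_repeats([at_31, at_32], IntervalSet({}), pad=1) == [at_31, at_32]


def test_repeat_filter_equals_interval_arithmetic_oracle():
    rng = np.random.default_rng(3)
    raw = [("chr1", int(s), int(s) + int(rng.integers(5, 50)))
           for s in rng.integers(0, 5000, size=60)]
    repeats = merge_repeat_track(raw)
    records = [
        make_record(pos=int(p), ref="ACGTA"[: int(rng.integers(1, 5))] or "A")
        for p in rng.integers(1, 5000, size=300)
    ]
    pad = 1
    bitmap = np.zeros(6000, dtype=bool)
    for _, s, e in raw:
        bitmap[max(0, s - pad) : e + pad] = True
    expected = [r for r in records if not bitmap[r.footprint[0] : r.footprint[1]].any()]
    assert filter_repeats(records, repeats, pad=pad) == expected


# --- strain catalog ------------------------------------------------------

def test_strain_filter_is_allele_aware():
    catalog = [make_record(pos=100, ref="A", alt="G")]
    same = make_record(pos=100, ref="A", alt="G", sample="X")
    different_alt = make_record(pos=100, ref="A", alt="T", sample="X")
    assert filter_known_strain([same, different_alt], catalog) == [different_alt]
    # position-only matching removes both
    assert filter_known_strain([same, different_alt], catalog, match_alleles=False) == []


def test_strain_filter_equals_set_difference_oracle():
    rng = np.random.default_rng(4)
    def rand_records(n, sample):
        return [
            make_record(pos=int(rng.integers(1, 50)),
                        ref="A", alt=str(rng.choice(["G", "T", "C"])), sample=sample)
            for _ in range(n)
        ]
    records, catalog = rand_records(200, "S1"), rand_records(100, "")
    keys = {c.key for c in catalog}
    assert filter_known_strain(records, catalog) == [r for r in records if r.key not in keys]


# --- cross-sample sharing ------------------------------------------------

def test_shared_variant_removed_from_every_carrier():
    shared = dict(pos=500, ref="A", alt="T")
    cohort = {
        "S1": [make_record(sample="S1", **shared), make_record(sample="S1", pos=10)],
        "S2": [make_record(sample="S2", **shared)],
        "S3": [make_record(sample="S3", pos=20)],
    }
    result = filter_shared(cohort)
    assert [r.pos for r in result["S1"]] == [10]
    assert result["S2"] == []
    assert [r.pos for r in result["S3"]] == [20]


def test_shared_filter_equals_multiplicity_oracle():
    rng = np.random.default_rng(5)
    cohort = {
        f"S{i}": [
            make_record(pos=int(rng.integers(1, 60)), sample=f"S{i}") for i in range(30)
        ]
        for i in range(6)
    }
    from collections import Counter
    counts = Counter()
    for sample, records in cohort.items():
        for key in {r.key for r in records}:
            counts[key] += 1
    result = filter_shared(cohort)
    for sample, records in cohort.items():
        assert result[sample] == [r for r in records if counts[r.key] == 1]


# --- full cascade --------------------------------------------------------

def test_cascade_removes_each_truth_category_at_its_stage(default_cohort):
    truth = default_cohort.truth
    candidates, traces = {}, {}
    from otaudit.filtering import cohort_candidate_dnms
    candidates, traces = cohort_candidate_dnms(
        default_cohort.samples,
        default_cohort.strain_catalog,
        default_cohort.repeats,
        reference=default_cohort.genome,
    )
    removal_stage = {}
    for sample, trace in traces.items():
        for sid, key, stage, action, _ in trace.entries:
            if action == "removed":
                removal_stage[(sid,) + key] = stage
    for row in truth.itertuples(index=False):
        key = (row.sample, row.chrom, row.pos, row.ref, row.alt)
        if not (row.qual >= 10 and row.dp >= 10):
            assert removal_stage.get(key) == "quality_gate", key
        elif not row.anno_pass:
            assert removal_stage.get(key) == "hard_filters", key
        elif row.vaf < 0.05:
            assert removal_stage.get(key) == "vaf", key
        elif row.label == "strain_variant":
            assert removal_stage.get(key) == "strain_catalog", key
    # surviving background DNMs: passing, >=5% VAF, outside repeats, unshared
    for sample, records in candidates.items():
        kept_keys = {r.key for r in records}
        sample_truth = truth[truth["sample"] == sample]
        for row in sample_truth.itertuples(index=False):
            if (
                row.label == "background_dnm"
                and row.qual >= 10 and row.dp >= 10 and row.anno_pass
                and row.vaf >= 0.05 and not row.in_repeat
            ):
                key = (row.chrom, row.pos, row.ref, row.alt)
                # het background DNMs may have been transmitted (then shared)
                transmitted = (
                    (truth["chrom"] == row.chrom) & (truth["pos"] == row.pos)
                    & (truth["ref"] == row.ref) & (truth["alt"] == row.alt)
                ).sum() > 1
                if not transmitted:
                    assert key in kept_keys, (sample, key)


def test_cascade_conservation_and_subset_property(default_cohort):
    from otaudit.filtering import cohort_candidate_dnms
    candidates, traces = cohort_candidate_dnms(
        default_cohort.samples,
        default_cohort.strain_catalog,
        default_cohort.repeats,
        reference=default_cohort.genome,
    )
    for sample, records in default_cohort.samples.items():
        trace = traces[sample]
        assert trace.n_kept + trace.n_removed == len(records)
        assert trace.n_kept == len(candidates[sample])
        input_keys = {
            normalize_variant(r, default_cohort.genome).key for r in records
        }
        assert {r.key for r in candidates[sample]} <= input_keys


def test_relaxing_thresholds_never_shrinks_survivors(default_cohort):
    """Lower min_vaf, pad 0 and an empty catalog can only keep more variants.

    The quality gate is not varied here: it feeds the cross-sample shared
    set, so relaxing it can legitimately create new shared keys and remove
    previously unique survivors.
    """
    from otaudit.filtering import cohort_candidate_dnms
    kwargs = dict(reference=default_cohort.genome)
    strict, _ = cohort_candidate_dnms(
        default_cohort.samples, default_cohort.strain_catalog, default_cohort.repeats,
        min_vaf=0.05, pad=1, **kwargs,
    )
    relaxed, _ = cohort_candidate_dnms(
        default_cohort.samples, [], default_cohort.repeats,
        min_vaf=0.0, pad=0, **kwargs,
    )
    for sample in strict:
        assert {r.key for r in strict[sample]} <= {r.key for r in relaxed[sample]}


def test_single_sample_cascade_reports_vaf_removal():
    genome = {"chr1": "A" * 200}
    low_vaf = make_record(pos=50, ref="A", alt="G", ad=(96, 4))  # VAF 0.04
    survivors, trace = candidate_dnms(
        [low_vaf], {"S1": [low_vaf]}, [], IntervalSet({}), reference=genome
    )
    assert survivors == []
    assert trace.entries[0][2:4] == ("vaf", "removed")

    survivors, trace = candidate_dnms([], {}, [], IntervalSet({}))
    assert survivors == [] and trace.entries == []
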