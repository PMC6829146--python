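# Methods

`otaudit` audits CRISPR-Cas9 editing experiments for off-target mutagenesis
starting from per-sample variant call sets (VCF) of edited founders, their
offspring and uninjected controls. This note documents the models and
procedures implemented, the parameters that matter, what the synthetic
cohort generator does and does not emulate, and the design choices made
where the design was genuinely open.

## The audit procedure

1. **Off-target site prediction.** For each guide (17–20 nt protospacer
   plus a 3′ IUPAC PAM pattern, default `NGG`), every genomic window on
   either strand is reported whose protospacer slot is within a Hamming
   distance budget of the guide and whose PAM slot matches the pattern.
   Mismatch counting is Hamming-only — DNA/RNA bulges are out of scope —
   and PAM positions are never counted as mismatches. Ambiguous reference
   bases (N) match nothing. The implementation scans encoded windows with
   numpy but is exhaustively tested against a naive per-position sliding
   scan; the two are equivalent by construction. The default budget of 4
   mismatches is the common operating point of genome-wide predictors; it
   is an exposed parameter because predicted-site counts depend on it
   strongly.

2. **Candidate de novo mutation (DNM) extraction.** Per sample, after
   left-alignment and parsimony reduction of alleles against the reference
   (the standard VCF normalization, so that "the same variant" is always
   the same `(chrom, pos, ref, alt)` key):
   - *quality gate:* keep calls with `QUAL >= 10` and total depth
     `DP >= 10` (inclusive bounds; a record missing DP is removed
     conservatively);
   - *hard filters:* remove SNVs with `QD < 2.0`, `FS > 60.0`,
     `MQ < 40.0`, `MQRankSum < -12.5` or `ReadPosRankSum < -8.0`, and
     indels with `QD < 2.0`, `FS > 200.0` or `ReadPosRankSum < -20.0`
     (strict inequalities; an absent annotation never removes a record);
   - *allele-fraction floor:* keep variant allele fraction
     `VAF = alt/(ref+alt) >= 0.05`, low enough to retain mosaic alleles in
     founders injected at the zygote stage;
   - *strain catalog:* remove alleles catalogued for the background
     strain (exact normalized key match by default; a position-only mode
     exists as a toggle);
   - *repeat mask:* remove variants whose reference footprint lies inside
     or within 1 bp of the merged repeat track (insertions count their
     single anchor base);
   - *cross-sample sharing:* remove any key present in two or more
     samples' post-quality-gate sets — recurrent calls across unrelated
     samples are systematic artifacts, not independent DNMs.

   Sharing is computed over the post-quality-gate sets of **all** cohort
   samples, controls included, before the per-sample filters, so an
   artifact is caught even when another filter masks it in one carrier.
   A consequence worth knowing: relaxing the quality gate can *shrink*
   the surviving set, because newly admitted low-quality duplicates create
   new shared keys. The other thresholds (VAF floor, repeat pad, catalog)
   are monotone as expected. Every removal is logged in a `FilterTrace`
   with its stage and reason; removals plus survivors always equal the
   input count.

3. **Final variants.** Candidates of each edited animal are compared
   against the pooled candidates of the uninjected controls; coincident
   keys are removed. Controls themselves are subtracted leave-one-out
   against the other controls so the counts table has a final column for
   every sample. Note that when cross-sample sharing already ran over the
   whole cohort, control subtraction is a near-identity; it is retained as
   an explicit, separately testable step because the two criteria differ
   in scope (sharing uses post-gate sets, subtraction uses candidate
   sets) and in reporting.

4. **Attribution and transmission.** A final variant is attributed to a
   predicted site when its reference footprint intersects the
   protospacer+PAM interval expanded by a 5 bp margin (Cas9 cleaves ~3 bp
   5′ of the PAM and left-alignment can shift indel anchors; the margin is
   configurable). Attributed founder variants are then looked up in the
   offspring's **post-quality-gate** call sets to decide germline
   transmission — deliberately not in the offspring's final variants,
   where the sharing criterion would mask any transmitted allele.

5. **Burden comparison.** Per-sample candidate and final SNV/indel counts
   are compared across treatment groups with a tie-corrected
   Kruskal-Wallis rank-sum test,

   `H = [12/(N(N+1)) · Σ R_i²/n_i − 3(N+1)] / C`, `C = 1 − Σ(t³−t)/(N³−N)`,

   with an asymptotic chi-squared p-value on k−1 degrees of freedom, and
   between the two edited strains with a two-sided Wilcoxon rank-sum
   (Mann-Whitney) test. `W` is the Mann-Whitney U of the first group
   (strain A), so argument order is part of the report schema. For
   tie-free pooled samples with n+m ≤ 20 the p-value enumerates the exact
   rank-sum null (dynamic programme over rank subsets) and doubles the
   smaller tail, capped at 1; with ties it falls back to a tie-corrected
   normal approximation without continuity correction. Both tests are
   implemented here and cross-checked in the suite against
   `scipy.stats.kruskal` / `mannwhitneyu` and against brute-force
   enumeration of all C(n+m, n) assignments.

## The synthetic cohort generator

The generator emulates the statistical structure the audit assumes, at toy
scale: by default 2 founders (strains M and P, one per pair of guides),
2 offspring per founder, 3 controls, on a 2 × 100 kb random genome with GC
0.42. Per-sample call sets mix Poisson-distributed background DNMs
(defaults: 60 SNVs and 15 indels per sample, scaled to the toy genome),
planted off-target indels at guide-matching sites (2 per founder,
mismatch counts 0–2, indel placed at the cut site 3 bp from the PAM),
shared artifacts (5 keys in ≥2 samples), strain-catalog variants (30,
present in samples and catalog), and a random repeat track covering ~20%
of the genome. Caller annotations are drawn from a passing component with
a 5% failing component per record, and 5% of records draw a failing
QUAL/DP, so every filter stage is exercised. All randomness flows from the
single design seed; identical designs give byte-identical outputs.

**Transmission model.** Only constitutional heterozygous variants
(VAF = 0.5) are treated as germline; mosaic variants (VAF < 0.5) are
confined to somatic lineages and never transmitted. Half of background
DNMs are heterozygous by default and transmit to each offspring
independently with probability 0.5 (Mendelian). Planted off-targets
default to VAF 0.35 — mosaic, hence untransmitted — which is the regime
in which the round-trip invariant "attributed set equals planted truth"
can hold exactly (a transmitted off-target would be shared between founder
and offspring and removed by the sharing criterion, exactly the masking
the transmission check is designed to sidestep). Setting
`planted_offtarget_vaf=0.5` makes off-targets germline and transmissible.

**What the generator does not emulate:** read-level errors and alignment
artifacts (no FASTQ/BAM), realistic repeat families (intervals are random,
not RepeatMasker-like), linked inheritance (each variant transmits
independently), caller disagreement (one call set per sample), multiallelic
sites, and the empirical VAF distribution of true mosaics (uniform on the
configured range is a stand-in). Passing round-trip tests therefore
demonstrates the correctness of the filtering/attribution logic, not the
end-to-end sensitivity of any particular caller on real reads.

## Numerical and interface choices

- Coordinates are 0-based half-open internally (BED-compatible interval
  algebra); 1-based only at VCF boundaries.
- Threshold comparisons are strict exactly as listed; records at a
  threshold are kept.
- Normalization is checked against an oracle that enumerates every
  equivalent representation in a window and picks the shortest, leftmost
  one; normalization is idempotent, and a variant at position 1 that
  cannot extend further left keeps its anchor.
- The Kruskal-Wallis statistic is undefined when all observations are
  identical (tie correction C = 0); this raises a degenerate-data error
  rather than returning 0.
- The counts-table median is the middle order statistic for odd n, the
  mean of the two middle order statistics for even n.
- Report files are TSV with fixed column orders and deterministic row
  ordering, so reruns are byte-identical.

## Problem sizes

The bundled cohort-counts table has nine samples; all rank statistics on
it are exact recomputations. Synthetic round-trips use the default design
above (a few hundred variant records over 200 kb), which keeps a full
simulate-plus-audit cycle to a couple of seconds while still exercising
every filter stage and both strands of the site search; the search itself
is validated against the exhaustive naive scan on genomes up to 100 kb
with budgets up to 4 mismatches.

## Known limitations

- Off-target activity is not scored (no CFD/MIT-style weights); the
  prediction step enumerates, it does not rank.
- Bulge-tolerant matching is not implemented.
- The predicted-site count for a real genome depends on the mismatch
  budget and PAM set, which must be chosen by the user; on random toy
  genomes, guide matches beyond the planted sites are vanishingly rare.
- The audit consumes variant calls; it cannot recover events the caller
  never emitted, and a "visual inspection" curation step used in practice
  has no algorithmic counterpart here — only reproducible filters are
  implemented.
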