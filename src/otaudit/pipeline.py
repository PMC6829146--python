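"""End-to-end orchestration: predict -> filter -> compare -> stats.

``run_simulate`` materializes a synthetic cohort on disk in the layout
``run_audit`` expects; ``run_audit`` runs the full audit from a single
RunConfig and writes the report bundle (site table, filter trace, counts
table, attribution table, inheritance table, stats table, run log).  Both
are deterministic for fixed inputs/seed.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    AttributionReport,
    attribute_offtargets,
    build_counts_table,
    check_inheritance,
    subtract_control_coincident,
)
from .errors import ConfigError, DegenerateDataError
from .filtering import (
    FilterTrace,
    IntervalSet,
    VariantRecord,
    apply_quality_gate,
    cohort_candidate_dnms,
    normalize_variant,
)
from .offtargets import (
    GuideRNA,
    find_offtarget_sites,
    read_guides_table,
    write_site_table,
)
from .sequences import read_fasta
from .stats import kruskal_wallis, wilcoxon_rank_sum
from .synthetic import CohortDesign, generate_reference, simulate_cohort, write_cohort
from .vcfio import read_vcf

__all__ = ["RunConfig", "AuditResult", "run_audit", "run_simulate"]


@dataclass
class RunConfig:
    """Paths and thresholds for one audit run.

    Threshold defaults are the audit's standard operating point: QUAL >= 10,
    DP >= 10, VAF >= 5%, 1 bp repeat padding, 4 protospacer mismatches, 5 bp
    attribution margin.
    """

    genome: str
    guides: str
    samples_dir: str
    sample_meta: str
    repeats: str
    strain_catalog: str
    outdir: str
    min_qual: float = 10.0
    min_depth: int = 10
    min_vaf: float = 0.05
    pad: int = 1
    max_mismatches: int = 4
    margin: int = 5
    caller: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.min_vaf <= 1):
            raise ConfigError(f"min_vaf outside [0,1]: {self.min_vaf}")
        if self.min_depth < 0 or self.min_qual < 0 or self.pad < 0 or self.margin < 0:
            raise ConfigError("thresholds must be non-negative")
        if self.max_mismatches < 0:
            raise ConfigError("max_mismatches must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad run configuration {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class AuditResult:
    sites: pd.DataFrame
    candidates: dict[str, list[VariantRecord]]
    finals: dict[str, list[VariantRecord]]
    traces: dict[str, FilterTrace]
    counts_table: pd.DataFrame
    attribution: pd.DataFrame
    attribution_reports: dict[str, AttributionReport] = field(default_factory=dict)
    inheritance: pd.DataFrame = field(default_factory=pd.DataFrame)
    stats_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    outdir: Optional[Path] = None


def _load_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "group", "relationship"}
    if not required.issubset(meta.columns):
        raise ConfigError(f"sample metadata must have columns {sorted(required)}")
    if "parent_id" not in meta.columns:
        meta["parent_id"] = ""
    for row in meta.itertuples(index=False):
        if row.relationship == "offspring" and not row.parent_id:
            raise ConfigError(f"offspring {row.sample_id} lacks parent_id")
    return meta


def build_stats_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Rank-test summary of a counts table (one row per comparison).

    Kruskal-Wallis compares all treatment groups; the Wilcoxon rank-sum
    compares the two edited strains (first strain as x, so W is the
    Mann-Whitney U of strain A over strain B).
    """
    body = counts[counts["sample"] != "median"]
    groups_order = sorted(body["group"].unique(), key=lambda g: (g == "control", g))
    edited = [g for g in groups_order if g != "control"]
    rows = []
    for column in ("candidate_snvs", "candidate_indels", "final_snvs", "final_indels"):
        values = [list(body.loc[body["group"] == g, column]) for g in groups_order]
        if len(values) >= 2 and all(values):
            try:
                kw = kruskal_wallis(values)
                rows.append(
                    {
                        "groups": ",".join(groups_order),
                        "value_compared": column,
                        "test": "Kruskal-Wallis rank sum",
                        "statistic": round(kw.statistic, 4),
                        "df": kw.df,
                        "p_value": round(kw.p_value, 5),
                        "method": kw.method,
                    }
                )
            except DegenerateDataError:
                rows.append(
                    {
                        "groups": ",".join(groups_order),
                        "value_compared": column,
                        "test": "Kruskal-Wallis rank sum",
                        "statistic": float("nan"),
                        "df": len(groups_order) - 1,
                        "p_value": float("nan"),
                        "method": "degenerate",
                    }
                )
    if len(edited) >= 2:
        for column in ("final_snvs", "final_indels"):
            x = list(body.loc[body["group"] == edited[0], column])
            y = list(body.loc[body["group"] == edited[1], column])
            res = wilcoxon_rank_sum(x, y)
            rows.append(
                {
                    "groups": f"{edited[0]},{edited[1]}",
                    "value_compared": column,
                    "test": "Wilcoxon rank sum",
                    "statistic": res.statistic,
                    "df": "",
                    "p_value": round(res.p_value, 5),
                    "method": res.method,
                }
            )
    return pd.DataFrame(
        rows, columns=["groups", "value_compared", "test", "statistic", "df", "p_value", "method"]
    )


def run_audit(config: RunConfig) -> AuditResult:
    """Run the full audit and write the report bundle to ``config.outdir``."""
    for name in ("genome", "guides", "samples_dir", "sample_meta", "repeats", "strain_catalog"):
        if not Path(getattr(config, name)).exists():
            raise ConfigError(f"{name} path does not exist: {getattr(config, name)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_fasta(config.genome)
    guides = read_guides_table(config.guides)
    meta = _load_sample_meta(config.sample_meta)
    repeats = IntervalSet.from_bed(config.repeats)
    catalog = read_vcf(config.strain_catalog)

    founders = list(meta.loc[meta["relationship"] == "founder", "sample_id"])
    controls = list(meta.loc[meta["group"] == "control", "sample_id"])
    if not founders or not controls:
        warnings.warn("cohort lacks founders or controls; comparisons may be identities")

    # off-target prediction
    sites = []
    for guide in guides:
        sites.extend(find_offtarget_sites(genome, guide, config.max_mismatches))
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand, s.guide_name))
    write_site_table(sites, outdir / "sites.tsv")

    # load and filter the cohort
    cohort_records: dict[str, list[VariantRecord]] = {}
    for sample_id in meta["sample_id"]:
        vcf_path = Path(config.samples_dir) / f"{sample_id}.vcf"
        if not vcf_path.exists():
            raise ConfigError(f"missing sample VCF: {vcf_path}")
        cohort_records[sample_id] = read_vcf(vcf_path, sample_id=sample_id, caller=config.caller)
    candidates, traces = cohort_candidate_dnms(
        cohort_records,
        catalog,
        repeats,
        min_vaf=config.min_vaf,
        reference=genome,
        min_qual=config.min_qual,
        min_depth=config.min_depth,
        pad=config.pad,
    )
    trace_frame = pd.concat([t.to_dataframe() for t in traces.values()], ignore_index=True)
    trace_frame.to_csv(outdir / "filter_trace.tsv", sep="\t", index=False)

    # post-quality-gate sets (normalized), for transmission queries
    gated = {
        s: apply_quality_gate(
            [normalize_variant(r, genome) for r in records], config.min_qual, config.min_depth
        )
        for s, records in cohort_records.items()
    }

    # control subtraction -> final variants
    control_sets = {c: candidates[c] for c in controls}
    finals: dict[str, list[VariantRecord]] = {}
    for sample_id in meta["sample_id"]:
        if sample_id in controls:
            others = {c: candidates[c] for c in controls if c != sample_id}
            finals[sample_id] = subtract_control_coincident(candidates[sample_id], others)
        else:
            finals[sample_id] = subtract_control_coincident(candidates[sample_id], control_sets)

    counts = build_counts_table(candidates, finals, meta, caller=config.caller)
    counts.to_csv(outdir / "counts_table.tsv", sep="\t", index=False)

    # attribution for edited animals; inheritance for founders
    reports: dict[str, AttributionReport] = {}
    attribution_frames = []
    inheritance_frames = []
    for row in meta.itertuples(index=False):
        if row.group == "control":
            continue
        report = attribute_offtargets(
            finals[row.sample_id], sites, margin=config.margin, sample_id=row.sample_id
        )
        reports[row.sample_id] = report
        attribution_frames.append(report.to_dataframe())
        if row.relationship == "founder":
            children = {
                child: gated[child]
                for child in meta.loc[meta["parent_id"] == row.sample_id, "sample_id"]
            }
            inheritance_frames.append(check_inheritance(report, children))
    attribution = (
        pd.concat(attribution_frames, ignore_index=True) if attribution_frames else pd.DataFrame()
    )
    inheritance = (
        pd.concat(inheritance_frames, ignore_index=True) if inheritance_frames else pd.DataFrame()
    )
    attribution.to_csv(outdir / "attribution.tsv", sep="\t", index=False)
    inheritance.to_csv(outdir / "inheritance.tsv", sep="\t", index=False)

    stats_table = build_stats_table(counts)
    stats_table.to_csv(outdir / "stats.tsv", sep="\t", index=False)

    log = {
        "otaudit_version": __version__,
        "thresholds": {
            "min_qual": config.min_qual,
            "min_depth": config.min_depth,
            "min_vaf": config.min_vaf,
            "repeat_pad": config.pad,
            "max_mismatches": config.max_mismatches,
            "attribution_margin": config.margin,
        },
        "seed": config.seed,
        "caller": config.caller,
        "n_predicted_sites": len(sites),
        "per_sample_stage_removals": {s: traces[s].stage_counts() for s in sorted(traces)},
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)

    return AuditResult(
        sites=pd.read_csv(outdir / "sites.tsv", sep="\t"),
        candidates=candidates,
        finals=finals,
        traces=traces,
        counts_table=counts,
        attribution=attribution,
        attribution_reports=reports,
        inheritance=inheritance,
        stats_table=stats_table,
        outdir=outdir,
    )


def _random_guides(rng: np.random.Generator, n_founders: int) -> list[GuideRNA]:
    """Two random 20-nt NGG guides per founder (a 5' and a 3' guide per strain)."""
    guides = []
    for i in range(n_founders):
        strain = chr(ord("A") + i)
        for end in ("5p", "3p"):
            protospacer = "".join(rng.choice(list("ACGT"), size=20))
            guides.append(GuideRNA(name=f"sg{strain}-{end}", protospacer=protospacer))
    return guides


def run_simulate(
    design: CohortDesign,
    outdir,
    force: bool = False,
    n_chromosomes: int = 2,
    chrom_length: int = 100_000,
    gc_fraction: float = 0.42,
    guides: Optional[list[GuideRNA]] = None,
) -> dict[str, Path]:
    """Generate a synthetic cohort on disk plus a ready-to-run config.yaml."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ConfigError(f"output directory {outdir} is not empty (use force to overwrite)")
    if design.n_controls == 0:
        warnings.warn("design has no controls: control subtraction will be an identity")
    genome = generate_reference(n_chromosomes, chrom_length, gc_fraction, seed=design.seed)
    if guides is None:
        rng = np.random.default_rng([design.seed, 1])
        guides = _random_guides(rng, design.n_founders)
    cohort = simulate_cohort(genome, guides, design)
    paths = write_cohort(cohort, outdir)
    config = RunConfig(
        genome=str(paths["genome"]),
        guides=str(paths["guides"]),
        samples_dir=str(paths["samples_dir"]),
        sample_meta=str(paths["sample_meta"]),
        repeats=str(paths["repeats"]),
        strain_catalog=str(paths["strain_catalog"]),
        outdir=str(outdir / "audit"),
        seed=design.seed,
    )
    config.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths
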