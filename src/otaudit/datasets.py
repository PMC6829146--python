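"""Bundled example data.

``load_study_counts`` returns the per-sample variant-count summary of a
published nine-mouse CRISPR-Cas9 editing cohort (two edited strains, each
one founder plus two offspring, and three uninjected controls; variants
called independently with GATK and bcftools).  The table is the package's
worked example for the rank-statistics layer: group comparisons and column
medians computed from it can be checked against the published summary.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_study_counts() -> pd.DataFrame:
    """Per-sample quality-passed, candidate-DNM and final variant counts.

    Columns: sample, group, relationship, then SNV/indel counts per stage
    and caller.  One row per animal (no precomputed summary rows).
    """
    with resources.files("otaudit.data").joinpath("study_cohort_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def study_group_counts(frame: pd.DataFrame, column: str) -> list[list[float]]:
    """Counts of ``column`` grouped by treatment group, edited strains first."""
    order = sorted(frame["group"].unique(), key=lambda g: (g == "control", g))
    return [list(frame.loc[frame["group"] == g, column]) for g in order]
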