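import numpy as np
import pytest

from otaudit.offtargets import GuideRNA
from otaudit.pipeline import RunConfig, run_audit, run_simulate
from otaudit.sequences import IUPAC, reverse_complement
from otaudit.synthetic import CohortDesign, generate_reference, simulate_cohort


def random_genome(rng: np.random.Generator, length: int, n_chroms: int = 1) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(bases[rng.integers(0, 4, size=length)]) for i in range(n_chroms)
    }


def naive_offtarget_scan(genome, guide: GuideRNA, max_mismatches: int):
    """Exhaustive sliding-window oracle: every position, both strands, counted naively."""
    p_len = len(guide.protospacer)
    w_len = p_len + len(guide.pam_pattern)
    hits = []
    for chrom in sorted(genome):
        fwd = genome[chrom].upper()
        for strand, seq in (("+", fwd), ("-", reverse_complement(fwd))):
            for i in range(len(seq) - w_len + 1):
                window = seq[i : i + w_len]
                if any(b not in "ACGT" for b in window):
                    continue
                mm = sum(a != b for a, b in zip(window[:p_len], guide.protospacer))
                if mm > max_mismatches:
                    continue
                if any(
                    window[p_len + j] not in IUPAC[c] for j, c in enumerate(guide.pam_pattern)
                ):
                    continue
                start = i if strand == "+" else len(seq) - (i + w_len)
                hits.append((chrom, start, strand, mm))
    return sorted(hits)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (fixed seed)."""
    design = CohortDesign(seed=11)
    genome = generate_reference(2, 100_000, 0.42, seed=11)
    rng = np.random.default_rng([11, 1])
    bases = np.array(list("ACGT"))
    guides = [
        GuideRNA(name=f"sg{i}", protospacer="".join(bases[rng.integers(0, 4, size=20)]))
        for i in range(4)
    ]
    return simulate_cohort(genome, guides, design)


@pytest.fixture(scope="session")
def audited_cohort(tmp_path_factory):
    """Default cohort simulated to disk and fully audited (shared, read-only)."""
    outdir = tmp_path_factory.mktemp("cohort")
    paths = run_simulate(CohortDesign(seed=7), outdir / "sim")
    config = RunConfig.from_yaml(paths["config"])
    result = run_audit(config)
    return paths, config, result
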