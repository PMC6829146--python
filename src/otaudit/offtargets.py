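"""PAM-anchored, mismatch-tolerant protospacer search.

Enumerates every genomic window, on both strands, whose protospacer slot is
within a Hamming-distance budget of a guide's protospacer and whose adjacent
slot matches the PAM pattern (IUPAC codes allowed for the PAM only).  This is
the classic exhaustive off-target prediction step performed for sgRNA design:
no bulges, no activity scoring — every candidate site within the mismatch
budget is reported.

Coordinates are 0-based half-open on the forward strand of the reference; a
minus-strand site's ``site_sequence`` is the window read 5'->3' on the minus
strand (i.e. the reverse complement of the reference slice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .sequences import IUPAC, encode, reverse_complement, validate_concrete, validate_iupac

__all__ = ["GuideRNA", "OfftargetSite", "find_offtarget_sites", "write_site_table", "read_site_table"]


@dataclass(frozen=True)
class GuideRNA:
    """A guide: protospacer (17-20 nt, concrete bases) plus a 3' PAM pattern."""

    name: str
    protospacer: str
    pam_pattern: str = "NGG"
    pam_side: str = "3prime"

    def __post_init__(self):
        object.__setattr__(self, "protospacer", validate_concrete(self.protospacer, "protospacer"))
        object.__setattr__(self, "pam_pattern", validate_iupac(self.pam_pattern, "pam_pattern"))
        if not (17 <= len(self.protospacer) <= 20):
            raise InvalidArgumentError(
                f"protospacer length must be 17-20 nt, got {len(self.protospacer)}"
            )
        if self.pam_side != "3prime":
            raise InvalidArgumentError("only 3' PAMs are supported")

    @property
    def window_length(self) -> int:
        return len(self.protospacer) + len(self.pam_pattern)


@dataclass(frozen=True)
class OfftargetSite:
    """A genomic interval (protospacer+PAM span) matching a guide."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # "+" or "-"
    mismatches: int
    site_sequence: str  # 5'->3' on the matching strand
    guide_name: str

    @property
    def site_id(self) -> str:
        return f"{self.guide_name}:{self.chrom}:{self.start}:{self.strand}"


def _scan_strand(codes: np.ndarray, proto_codes: np.ndarray, pam_allowed: list[np.ndarray],
                 max_mismatches: int) -> tuple[np.ndarray, np.ndarray]:
    """Offsets and mismatch counts of matching windows in one encoded strand."""
    p_len, w_len = len(proto_codes), len(proto_codes) + len(pam_allowed)
    if len(codes) < w_len:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w_len)
    # ambiguous genome bases encode to 4, which never equals a concrete code
    mism = (windows[:, :p_len] != proto_codes).sum(axis=1)
    pam_ok = np.ones(len(windows), dtype=bool)
    for j, allowed in enumerate(pam_allowed):
        pam_ok &= np.isin(windows[:, p_len + j], allowed)
    hits = np.nonzero(pam_ok & (mism <= max_mismatches))[0]
    return hits, mism[hits]


def find_offtarget_sites(
    genome: Mapping[str, str], guide: GuideRNA, max_mismatches: int
) -> list[OfftargetSite]:
    """All sites on either strand within ``max_mismatches`` of the protospacer.

    PAM positions are matched against the IUPAC pattern and never counted as
    mismatches.  Results are sorted by (chrom, start, strand); ambiguous
    genome bases (N) never match any protospacer base and never satisfy the
    PAM.
    """
    if max_mismatches < 0:
        raise InvalidArgumentError("max_mismatches must be >= 0")
    if not genome:
        raise InvalidArgumentError("genome is empty")
    proto_codes = encode(guide.protospacer)
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    pam_allowed = [
        np.array(sorted(base_code[b] for b in IUPAC[c]), dtype=np.uint8)
        for c in guide.pam_pattern
    ]
    w_len = guide.window_length
    sites: list[OfftargetSite] = []
    for chrom in sorted(genome):
        fwd = str(genome[chrom]).upper()
        length = len(fwd)
        rev = reverse_complement(fwd)
        for strand, seq in (("+", fwd), ("-", rev)):
            hits, mism = _scan_strand(encode(seq), proto_codes, pam_allowed, max_mismatches)
            for off, mm in zip(hits.tolist(), mism.tolist()):
                if strand == "+":
                    start = off
                else:
                    start = length - (off + w_len)
                sites.append(
                    OfftargetSite(
                        chrom=chrom,
                        start=start,
                        end=start + w_len,
                        strand=strand,
                        mismatches=int(mm),
                        site_sequence=seq[off : off + w_len],
                        guide_name=guide.name,
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


_TABLE_COLUMNS = ["chrom", "start", "end", "strand", "mismatches", "site_sequence", "guide_name"]


def write_site_table(sites: Sequence[OfftargetSite], destination) -> None:
    """Write sites as a TSV (one row per site); round-trips via read_site_table."""
    frame = pd.DataFrame([vars(s) for s in sites], columns=_TABLE_COLUMNS)
    frame.to_csv(destination, sep="\t", index=False)


def read_site_table(source) -> list[OfftargetSite]:
    frame = pd.read_csv(
        source, sep="\t", dtype={"chrom": str, "strand": str, "site_sequence": str, "guide_name": str}
    )
    return [
        OfftargetSite(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            mismatches=int(row.mismatches),
            site_sequence=row.site_sequence,
            guide_name=row.guide_name,
        )
        for row in frame.itertuples(index=False)
    ]


def read_guides_table(source) -> list[GuideRNA]:
    """Read guides from a TSV with columns name, protospacer[, pam_pattern]."""
    frame = pd.read_csv(source, sep="\t", dtype=str)
    if "pam_pattern" not in frame.columns:
        frame["pam_pattern"] = "NGG"
    return [
        GuideRNA(name=row["name"], protospacer=row["protospacer"], pam_pattern=row["pam_pattern"])
        for row in frame.to_dict("records")
    ]


def write_guides_table(guides: Iterable[GuideRNA], destination) -> None:
    frame = pd.DataFrame(
        [(g.name, g.protospacer, g.pam_pattern) for g in guides],
        columns=["name", "protospacer", "pam_pattern"],
    )
    frame.to_csv(destination, sep="\t", index=False)
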