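"""Paired-LTR divergence dating of full-length HERVH units.

A full-length unit is LTR7 / HERVH-int / LTR7 on one strand. Because the
two LTRs of a provirus are identical at insertion, their pairwise
divergence dates the insertion: align them globally, count transition (P)
and transversion (Q) proportions over ungapped non-N columns, correct with
the Kimura 2-parameter formula

    K = 1/2 ln[1/(1 - 2P - Q)] + 1/4 ln[1/(1 - 2Q)]

and convert to years with the substitution rate r = 1.28e-8 per site per
year. The default time convention is T = K / (2 r): the two LTRs accumulate
divergence along two independent lineages since insertion (a T = K / r mode
exists for sensitivity analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .intervals import GenomicInterval
from .io import GenomeLike, extract_sequence

#: Human per-site per-year substitution rate used for T = K / (2 r).
DEFAULT_RATE = 1.28e-8


class K2pSaturationError(ValueError):
    """P/Q outside the K2P domain (1 - 2P - Q <= 0 or 1 - 2Q <= 0)."""


@dataclass(frozen=True)
class FullLengthUnit:
    """An LTR7-internal-LTR7 unit on one chromosome strand."""

    unit_id: str
    chrom: str
    strand: str
    ltr5: GenomicInterval
    internal: GenomicInterval
    ltr3: GenomicInterval

    def __post_init__(self) -> None:
        if not (self.ltr5.end <= self.internal.start and self.internal.end <= self.ltr3.start):
            raise ValueError("unit segments must be ordered ltr5 < internal < ltr3")


@dataclass(frozen=True)
class PairedLtrRecord:
    """Alignment-derived P, Q, K and divergence time for one unit's LTR pair."""

    unit_id: str
    aligned_columns: int
    P: float
    Q: float
    K: float | None
    T: float | None
    flag: str = "ok"  # ok | saturated


def find_full_length_units(loci: pd.DataFrame, gap_tolerance: int = 100) -> list[FullLengthUnit]:
    """Scan repeat annotation for LTR7 -> HERVH-int(s) -> LTR7 triples.

    Consecutive segments must be separated by at most ``gap_tolerance`` bp
    on the same chromosome and strand; adjacent internal fragments are
    merged. Solo LTRs are never reported. The scan is greedy left to right
    and resumes after each unit's 3' LTR.
    """
    units: list[FullLengthUnit] = []
    relevant = loci[loci["subfamily"].isin(("LTR7", "HERVH-int"))]
    counter = 0
    for (chrom, strand), group in relevant.groupby(["chrom", "strand"], sort=True):
        rows = group.sort_values("start")
        recs = list(rows.itertuples())
        i = 0
        while i < len(recs):
            if recs[i].subfamily != "LTR7":
                i += 1
                continue
            ltr5 = recs[i]
            j = i + 1
            internals = []
            while (
                j < len(recs)
                and recs[j].subfamily == "HERVH-int"
                and recs[j].start - (internals[-1].end if internals else ltr5.end) <= gap_tolerance
            ):
                internals.append(recs[j])
                j += 1
            if (
                internals
                and j < len(recs)
                and recs[j].subfamily == "LTR7"
                and recs[j].start - internals[-1].end <= gap_tolerance
            ):
                ltr3 = recs[j]
                counter += 1
                units.append(
                    FullLengthUnit(
                        unit_id=str(getattr(ltr5, "unit_id", None) or f"flu{counter:04d}"),
                        chrom=chrom,
                        strand=strand,
                        ltr5=GenomicInterval(chrom, ltr5.start, ltr5.end, strand),
                        internal=GenomicInterval(
                            chrom, internals[0].start, internals[-1].end, strand
                        ),
                        ltr3=GenomicInterval(chrom, ltr3.start, ltr3.end, strand),
                    )
                )
                i = j + 1
            else:
                i += 1
    return units


# ---------------------------------------------------------------------------
# Alignment and P/Q counting


def _make_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap_open: float = -5.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> tuple[str, str, float]:
    """Global pairwise alignment; returns the two gapped strings and the score.

    A length-L gap costs gap_open + (L - 1) * gap_extend. Ties are broken
    deterministically (first alignment in the aligner's canonical order).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_ACGT = frozenset("ACGT")


def count_pq(aligned_a: str, aligned_b: str) -> tuple[float, float, int]:
    """Transition (P) and transversion (Q) proportions over usable columns.

    Columns with a gap or N in either sequence are excluded from both the
    numerator and the denominator.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(aligned_a, aligned_b):
        if a not in _ACGT or b not in _ACGT:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no usable (ungapped, non-N) aligned columns")
    return ts / n, tv / n, n


def k2p_distance(P: float, Q: float) -> float:
    """Kimura 2-parameter distance K = 1/2 ln[1/(1-2P-Q)] + 1/4 ln[1/(1-2Q)]."""
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be >= 0")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise K2pSaturationError(f"saturated divergence: P={P:.4f}, Q={Q:.4f}")
    return 0.5 * math.log(1.0 / w1) + 0.25 * math.log(1.0 / w2)


def divergence_time(K: float, rate: float = DEFAULT_RATE, lineages: int = 2) -> float:
    """Years since insertion: T = K / (lineages * rate).

    ``lineages=2`` (default) treats the LTR pair as diverging along two
    independent lineages; ``lineages=1`` gives the single-lineage reading.
    """
    if K < 0 or not math.isfinite(K):
        raise ValueError("K must be finite and >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return K / (lineages * rate)


def date_pair(
    seq_a: str, seq_b: str, rate: float = DEFAULT_RATE, lineages: int = 2, unit_id: str = ""
) -> PairedLtrRecord:
    """Full dating of one LTR pair: align, count P/Q, K2P-correct, convert to years.

    Saturated pairs (outside the K2P domain) are flagged and carry K = T =
    None rather than a clamped value.
    """
    aln_a, aln_b, _score = align_pair(seq_a, seq_b)
    P, Q, n = count_pq(aln_a, aln_b)
    try:
        K = k2p_distance(P, Q)
    except K2pSaturationError:
        return PairedLtrRecord(unit_id, n, P, Q, None, None, "saturated")
    return PairedLtrRecord(unit_id, n, P, Q, K, divergence_time(K, rate, lineages))


def date_units(
    units: Sequence[FullLengthUnit],
    genome: GenomeLike,
    rate: float = DEFAULT_RATE,
    lineages: int = 2,
) -> pd.DataFrame:
    """Per-unit dating report (unit_id, chrom, strand, aligned columns, P, Q, K, T)."""
    rows = []
    for unit in units:
        ltr5_seq = extract_sequence(genome, unit.ltr5)
        ltr3_seq = extract_sequence(genome, unit.ltr3)
        rec = date_pair(ltr5_seq, ltr3_seq, rate, lineages, unit.unit_id)
        rows.append(
            {"unit_id": rec.unit_id, "chrom": unit.chrom, "strand": unit.strand,
             "aligned_columns": rec.aligned_columns, "P": rec.P, "Q": rec.Q,
             "K": rec.K, "T_years": rec.T, "flag": rec.flag}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression-stratified group comparison


@dataclass(frozen=True)
class GroupComparison:
    """Divergence-time comparison between top and bottom expression groups."""

    test: str
    statistic: float
    p: float
    median_top: float
    median_bottom: float
    n_top: int
    n_bottom: int


def compare_divergence_groups(
    times: Sequence[float],
    ranking: Sequence[float],
    top_n: int = 200,
    test: str = "mannwhitney",
) -> GroupComparison:
    """Compare divergence times of the top_n highest vs top_n lowest ranked records.

    ``ranking`` (expression or |log2FC|) must align with ``times``; records
    with non-finite time are dropped first. Default test is the two-sided
    Mann-Whitney U (exact for small samples); "ks" and "ttest" are
    available alternatives.
    """
    times = np.asarray(times, dtype=float)
    ranking = np.asarray(ranking, dtype=float)
    if len(times) != len(ranking):
        raise ValueError("times and ranking must align")
    finite = np.isfinite(times)
    times, ranking = times[finite], ranking[finite]
    if len(times) < 2 * top_n:
        raise ValueError(f"need >= {2 * top_n} records with finite divergence time")
    order = np.argsort(ranking, kind="stable")
    bottom = times[order[:top_n]]
    top = times[order[-top_n:]]
    if test == "mannwhitney":
        method = "exact" if top_n + top_n <= 25 else "auto"
        res = stats.mannwhitneyu(top, bottom, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "ks":
        res = stats.ks_2samp(top, bottom, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "ttest":
        res = stats.ttest_ind(top, bottom, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        test, stat, p, float(np.median(top)), float(np.median(bottom)), top_n, top_n
    )
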