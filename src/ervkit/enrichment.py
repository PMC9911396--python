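"""ChIP-peak enrichment over genomic feature classes.

The enrichment score for a peak set against a feature class (e.g. the LTR
repeats) is log2(A/B), where A is the fraction of peak base pairs
overlapping the merged feature set and B the fraction of the genome covered
by it. Significance comes from a permutation null that uniformly re-places
each peak (length preserved) on its own chromosome. Also assigns peaks to
genomic categories and to HERVH full-length units within a 10-kb flank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, MergedCoverage
from .io import AnnotationRecord
from .tss import AnnotationIndex

NEG_INF = float("-inf")


@dataclass(frozen=True)
class EnrichmentResult:
    """A-ratio, B-ratio, log2(A/B) score and permutation p for one feature class."""

    feature_class: str
    A_ratio: float
    B_ratio: float
    score: float
    perm_p: float | None = None
    n_perm: int = 0


@dataclass(frozen=True)
class PeakHervhAssociation:
    """A peak's relation to the nearest full-length HERVH unit."""

    peak_id: str
    association: str  # on_LTR7 | on_internal | flank_10kb | unassociated
    unit_id: str | None
    distance: int | None


def feature_overlap_ratio(
    peaks: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> float:
    """Fraction of peak base pairs overlapping the merged feature set."""
    if not peaks:
        raise ValueError("empty peak set")
    cov = MergedCoverage(features)
    total = 0
    inside = 0
    for p in peaks:
        total += p.length
        inside += int(cov.overlap_bp(p.chrom, np.array([p.start]), np.array([p.end]))[0])
    return inside / total


def genome_background_ratio(
    features: Sequence[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> float:
    """Merged feature bp over total genome bp."""
    if not features:
        raise ValueError("empty feature set (background ratio undefined)")
    for iv in features:
        if iv.chrom not in chrom_sizes or iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(
                f"feature {iv.chrom}:{iv.start}-{iv.end} outside chromosome sizes"
            )
    cov = MergedCoverage(features)
    return cov.total() / sum(chrom_sizes.values())


def enrichment_score(a_ratio: float, b_ratio: float) -> float:
    """log2(A/B); A = 0 maps to -inf (flagged by callers), B = 0 is an error."""
    if b_ratio <= 0:
        raise ValueError("B ratio must be > 0")
    if a_ratio < 0:
        raise ValueError("A ratio must be >= 0")
    if a_ratio == 0:
        return NEG_INF
    return math.log2(a_ratio / b_ratio)


def permutation_null(
    peaks: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    features: Sequence[GenomicInterval],
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    feature_class: str = "",
) -> EnrichmentResult:
    """Empirical p for the observed enrichment score under random placement.

    Each permutation re-places every peak uniformly on its original
    chromosome with its length preserved; perm_p uses the add-one estimator
    (1 + #{permuted score >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    for p in peaks:
        if p.length > chrom_sizes[p.chrom]:
            raise ValueError(f"peak longer than chromosome {p.chrom}")

    a_obs = feature_overlap_ratio(peaks, features)
    b = genome_background_ratio(features, chrom_sizes)
    obs_score = enrichment_score(a_obs, b)

    cov = MergedCoverage(features)
    total_bp = sum(p.length for p in peaks)
    by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.length)

    perm_inside = np.zeros(n_perm, dtype=np.int64)
    for chrom, lengths in by_chrom.items():
        lens = np.array(lengths, dtype=np.int64)
        max_start = chrom_sizes[chrom] - lens + 1  # per-peak exclusive bound
        u = rng.random((n_perm, len(lens)))
        starts = (u * max_start).astype(np.int64)
        ends = starts + lens
        inside = cov.overlap_bp(chrom, starts.ravel(), ends.ravel()).reshape(n_perm, -1)
        perm_inside += inside.sum(axis=1)

    perm_a = perm_inside / total_bp
    with np.errstate(divide="ignore"):
        perm_scores = np.log2(np.where(perm_a > 0, perm_a / b, np.nan))
    perm_scores = np.where(np.isnan(perm_scores), NEG_INF, perm_scores)
    n_ge = int((perm_scores >= obs_score).sum())
    perm_p = (1 + n_ge) / (n_perm + 1)
    return EnrichmentResult(feature_class, a_obs, b, obs_score, perm_p, n_perm)


def peak_count_ratio(
    peaks: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> float:
    """Alternative count-weighted A: fraction of peaks overlapping the features."""
    if not peaks:
        raise ValueError("empty peak set")
    cov = MergedCoverage(features)
    hits = sum(
        int(cov.overlap_bp(p.chrom, np.array([p.start]), np.array([p.end]))[0]) > 0
        for p in peaks
    )
    return hits / len(peaks)


def assign_peak_categories(
    peaks: Sequence[GenomicInterval],
    annotation: Sequence[AnnotationRecord],
    tss_distance_bp: int = 1000,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Genomic category per peak midpoint, plus category fractions (sum to 1)."""
    index = AnnotationIndex(annotation)
    rows = []
    for i, p in enumerate(peaks):
        category, dist = index.categorize(p.chrom, p.midpoint, tss_distance_bp)
        rows.append({"peak_id": f"peak{i:05d}", "chrom": p.chrom, "start": p.start,
                     "end": p.end, "category": category, "distance_to_tss": dist})
    df = pd.DataFrame(rows)
    fractions = (df["category"].value_counts() / len(df)).to_dict() if len(df) else {}
    return df, fractions


def associate_peaks_hervh(
    peaks: Sequence[GenomicInterval],
    units: pd.DataFrame,
    flank: int = 10_000,
) -> list[PeakHervhAssociation]:
    """Assign each peak to a full-length HERVH unit by priority.

    Priority: overlaps an LTR7 segment -> on_LTR7; overlaps the internal
    segment -> on_internal; within ``flank`` bp of either LTR7 ->
    flank_10kb; otherwise unassociated. Distance is the bp gap to the
    nearest LTR7 edge (0 for overlaps).
    """
    rank = {"on_LTR7": 0, "on_internal": 1, "flank_10kb": 2}
    out: list[PeakHervhAssociation] = []
    for i, p in enumerate(peaks):
        pid = f"peak{i:05d}"
        best: tuple[int, str, str] | None = None  # (distance, association, unit_id)
        for u in units.itertuples():
            if u.chrom != p.chrom:
                continue
            ltr_spans = [(u.ltr5_start, u.ltr5_end), (u.ltr3_start, u.ltr3_end)]
            ltr_overlap = any(_overlap(p, s, e) for s, e in ltr_spans)
            d_ltr = min(_gap(p, s, e) for s, e in ltr_spans)
            if ltr_overlap:
                cand = (0, "on_LTR7", u.Index)
            elif _overlap(p, u.int_start, u.int_end):
                cand = (0, "on_internal", u.Index)
            elif d_ltr <= flank:
                cand = (d_ltr, "flank_10kb", u.Index)
            else:
                continue
            if best is None or (rank[cand[1]], cand[0]) < (rank[best[1]], best[0]):
                best = cand
        if best is None:
            out.append(PeakHervhAssociation(pid, "unassociated", None, None))
        else:
            out.append(PeakHervhAssociation(pid, best[1], str(best[2]), best[0]))
    return out


def _overlap(peak: GenomicInterval, start: int, end: int) -> bool:
    return peak.start < end and start < peak.end


def _gap(peak: GenomicInterval, start: int, end: int) -> int:
    """bp gap between a peak and a half-open span (0 when they overlap or abut)."""
    if _overlap(peak, start, end):
        return 0
    return start - peak.end if start >= peak.end else peak.start - end


def enrichment_report(results: Sequence[EnrichmentResult], seed: int | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "feature_class": [r.feature_class for r in results],
            "A_ratio": [r.A_ratio for r in results],
            "B_ratio": [r.B_ratio for r in results],
            "score": [r.score for r in results],
            "perm_p": [r.perm_p for r in results],
            "n_perm": [r.n_perm for r in results],
        }
    )
    if seed is not None:
        df["seed"] = seed
    return df
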