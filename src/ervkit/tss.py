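"""nanoCAGE read processing and TSS-peak analysis.

Demultiplex barcoded 5'-capture reads (Hamming distance <= 2, ties
unassigned), trim the 11-nt non-genomic prefix, cluster read 5' ends into
TSS peaks, keep peaks supported by >= 30 unique reads, annotate them
relative to gene models (<1 kb from an annotated TSS => TSS peak), extract
300-bp proximal promoters (250 bp upstream / 50 bp downstream of the TSS),
and test known-motif enrichment between promoter sets with Fisher's exact
test and Benjamini-Hochberg correction (significant at p < 0.01 and
q < 0.01).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, reverse_complement
from .io import AnnotationRecord, FastqRead, GenomeLike, as_genome_dict

logger = logging.getLogger(__name__)

CATEGORIES = ("TSS", "exonic", "intronic", "three_prime_utr", "intergenic")


@dataclass(frozen=True)
class TssPeak:
    """A cluster of read 5' ends treated as one transcription start site."""

    interval: GenomicInterval
    mode_position: int
    read_support: int
    sample: str = ""
    category: str = ""
    distance_to_tss: int | None = None

    def __post_init__(self) -> None:
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")
        if not self.interval.start <= self.mode_position < self.interval.end:
            raise ValueError("mode_position must lie within the peak interval")


@dataclass(frozen=True)
class PromoterWindow:
    """A 300-bp proximal promoter containing its TSS (strand-adjusted)."""

    interval: GenomicInterval
    tss_position: int
    sequence: str
    clipped: bool = False


# ---------------------------------------------------------------------------
# Demultiplexing and trimming


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Sequence[FastqRead],
    barcodes: Mapping[str, str],
    max_mismatch: int = 2,
) -> tuple[dict[str, list[FastqRead]], list[FastqRead]]:
    """Assign each read to the unique barcode within ``max_mismatch`` of its prefix.

    Reads with no qualifying barcode, or with two or more barcodes tied
    within the budget, go to the unassigned bin (conservative rule: no
    sample bleed-through).
    """
    values = list(barcodes.values())
    if len(set(values)) != len(values):
        raise ValueError("duplicate barcodes")
    if len({len(b) for b in values}) > 1:
        raise ValueError("barcodes must be equal length")
    bc_len = len(values[0])
    assigned: dict[str, list[FastqRead]] = {s: [] for s in barcodes}
    unassigned: list[FastqRead] = []
    for read in reads:
        prefix = read.seq[:bc_len]
        hits = [s for s, bc in barcodes.items() if hamming(prefix, bc) <= max_mismatch]
        if len(hits) == 1:
            assigned[hits[0]].append(read)
        else:
            unassigned.append(read)
    return assigned, unassigned


def trim_reads(reads: Sequence[FastqRead], n: int = 11) -> tuple[list[FastqRead], int]:
    """Remove the first n (non-genomic) bases; too-short reads are dropped."""
    out: list[FastqRead] = []
    dropped = 0
    for read in reads:
        if len(read.seq) <= n:
            dropped += 1
            continue
        out.append(FastqRead(read.id, read.seq[n:], read.qual[n:] if read.qual else ""))
    if dropped:
        logger.info("trim_reads dropped %d reads of length <= %d", dropped, n)
    return out, dropped


# ---------------------------------------------------------------------------
# TSS clustering and filtering


def call_tss_clusters(
    positions: Iterable[tuple[str, int, str]],
    merge_window: int = 20,
    sample: str = "",
) -> list[TssPeak]:
    """Greedy strand-separated clustering of read 5' positions.

    Positions are sorted per (chromosome, strand); a cluster extends while
    the next position is within ``merge_window`` bp of the cluster's current
    right boundary. The peak spans the cluster, read_support counts its
    reads, and mode_position is the most frequent 5' end (leftmost on tie).
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for chrom, pos, strand in positions:
        by_key.setdefault((chrom, strand), []).append(pos)
    peaks: list[TssPeak] = []
    for (chrom, strand) in sorted(by_key):
        pos_sorted = sorted(by_key[(chrom, strand)])
        cluster: list[int] = [pos_sorted[0]]
        for p in pos_sorted[1:]:
            if p - cluster[-1] <= merge_window:
                cluster.append(p)
            else:
                peaks.append(_cluster_to_peak(chrom, strand, cluster, sample))
                cluster = [p]
        peaks.append(_cluster_to_peak(chrom, strand, cluster, sample))
    return peaks


def _cluster_to_peak(chrom: str, strand: str, cluster: list[int], sample: str) -> TssPeak:
    counts: dict[int, int] = {}
    for p in cluster:
        counts[p] = counts.get(p, 0) + 1
    mode = min((p for p in counts), key=lambda p: (-counts[p], p))
    iv = GenomicInterval(chrom, cluster[0], cluster[-1] + 1, strand)
    return TssPeak(iv, mode, len(cluster), sample)


def filter_peaks(peaks: Sequence[TssPeak], min_reads: int = 30) -> list[TssPeak]:
    """Keep peaks supported by at least ``min_reads`` unique reads."""
    kept = [p for p in peaks if p.read_support >= min_reads]
    logger.info("filter_peaks removed %d of %d peaks", len(peaks) - len(kept), len(peaks))
    return kept


# ---------------------------------------------------------------------------
# Annotation


class AnnotationIndex:
    """Positional lookup over gene models: transcript 5' ends, exons, 3'UTRs."""

    def __init__(self, annotation: Iterable[AnnotationRecord]):
        self.tss: list[tuple[str, int, str]] = []  # (chrom, pos, strand)
        self._by_kind: dict[str, dict[str, list[tuple[int, int]]]] = {
            "three_prime_utr": {}, "exon": {}, "transcript": {}
        }
        for rec in annotation:
            iv = rec.interval
            if rec.feature_kind == "transcript":
                pos = iv.start if iv.strand != "-" else iv.end - 1
                self.tss.append((iv.chrom, pos, iv.strand))
            if rec.feature_kind in self._by_kind:
                self._by_kind[rec.feature_kind].setdefault(iv.chrom, []).append(
                    (iv.start, iv.end)
                )
        self._tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for chrom, pos, strand in self.tss:
            by_chrom.setdefault(chrom, []).append((pos, strand))
        for chrom, entries in by_chrom.items():
            entries.sort()
            self._tss_by_chrom[chrom] = (
                np.array([p for p, _ in entries]),
                [s for _, s in entries],
            )
        for kind in self._by_kind:
            for chrom in self._by_kind[kind]:
                self._by_kind[kind][chrom].sort()

    @property
    def empty(self) -> bool:
        return not self.tss

    def nearest_tss(self, chrom: str, pos: int) -> tuple[int, str] | None:
        """Signed distance to the nearest annotated transcript 5' end.

        The sign is strand-aware: positive means the query lies downstream
        of that TSS along the transcript's direction of transcription.
        """
        if chrom not in self._tss_by_chrom:
            return None
        positions, strands = self._tss_by_chrom[chrom]
        i = int(np.searchsorted(positions, pos))
        best = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(positions):
                d_abs = abs(pos - int(positions[j]))
                if best is None or d_abs < best[0]:
                    best = (d_abs, j)
        if best is None:
            return None
        j = best[1]
        raw = pos - int(positions[j])
        signed = raw if strands[j] != "-" else -raw
        return signed, strands[j]

    def _contains(self, kind: str, chrom: str, pos: int) -> bool:
        spans = self._by_kind[kind].get(chrom)
        if not spans:
            return False
        # spans are sorted by start; scan the candidates with start <= pos
        for s, e in spans:
            if s > pos:
                break
            if s <= pos < e:
                return True
        return False

    def categorize(self, chrom: str, pos: int, tss_distance_bp: int = 1000) -> tuple[str, int | None]:
        near = self.nearest_tss(chrom, pos)
        dist = near[0] if near is not None else None
        if dist is not None and abs(dist) < tss_distance_bp:
            return "TSS", dist
        # priority after the TSS rule: 3'UTR > exonic > intronic
        if self._contains("three_prime_utr", chrom, pos):
            return "three_prime_utr", dist
        if self._contains("exon", chrom, pos):
            return "exonic", dist
        if self._contains("transcript", chrom, pos):
            return "intronic", dist
        return "intergenic", dist


def annotate_peaks(
    peaks: Sequence[TssPeak],
    annotation: Iterable[AnnotationRecord],
    tss_distance_bp: int = 1000,
) -> list[TssPeak]:
    """Assign each peak a genomic category and signed distance to the nearest TSS."""
    index = annotation if isinstance(annotation, AnnotationIndex) else AnnotationIndex(annotation)
    if index.empty:
        logger.warning("empty annotation: all peaks will be intergenic")
    out = []
    for peak in peaks:
        category, dist = index.categorize(
            peak.interval.chrom, peak.mode_position, tss_distance_bp
        )
        out.append(replace(peak, category=category, distance_to_tss=dist))
    return out


# ---------------------------------------------------------------------------
# Promoter extraction


def extract_promoters(
    peaks: Sequence[TssPeak],
    genome: GenomeLike,
    upstream: int = 250,
    downstream: int = 50,
) -> list[PromoterWindow]:
    """Proximal promoter windows around each peak's mode position.

    Plus strand: [t - upstream, t + downstream); minus strand the mirrored
    window [t - downstream + 1, t + upstream + 1) with the sequence
    reverse-complemented. Both contain the TSS base and have length
    upstream + downstream. Windows hitting a chromosome edge are clipped
    and flagged (callers exclude them from motif statistics).
    """
    seqs = as_genome_dict(genome)
    out: list[PromoterWindow] = []
    for peak in peaks:
        chrom = peak.interval.chrom
        t = peak.mode_position
        strand = peak.interval.strand
        if strand == "-":
            lo, hi = t - downstream + 1, t + upstream + 1
        else:
            lo, hi = t - upstream, t + downstream
        chrom_len = len(seqs[chrom])
        clipped = lo < 0 or hi > chrom_len
        lo_c, hi_c = max(0, lo), min(chrom_len, hi)
        seq = seqs[chrom][lo_c:hi_c]
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(PromoterWindow(GenomicInterval(chrom, lo_c, hi_c, strand), t, seq, clipped))
    return out


# ---------------------------------------------------------------------------
# Stage specificity


def stage_specific_peaks(
    peaks_by_stage: Mapping[str, Sequence[TssPeak]],
    min_reads: int = 30,
) -> dict[str, list[TssPeak]]:
    """Peaks passing the read filter in one stage and absent from all others.

    A peak is stage-specific if it has >= min_reads support in its stage and
    overlaps (same strand, >= 1 bp) no filtered peak of any other stage.
    """
    if len(peaks_by_stage) < 2:
        raise ValueError("need at least two stages")
    filtered = {s: filter_peaks(list(p), min_reads) for s, p in peaks_by_stage.items()}
    specific: dict[str, list[TssPeak]] = {}
    for stage, peaks in filtered.items():
        others = [p for s, ps in filtered.items() if s != stage for p in ps]
        keep = []
        for peak in peaks:
            if not any(peak.interval.overlaps(o.interval, stranded=True) for o in others):
                keep.append(peak)
        specific[stage] = keep
    return specific


# ---------------------------------------------------------------------------
# Known-motif enrichment


@dataclass(frozen=True)
class Pwm:
    """A position probability matrix (4 x L, rows A/C/G/T) with background."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        bg = self.background if self.background is not None else np.full(4, 0.25)
        bg = np.asarray(bg, dtype=float)
        object.__setattr__(self, "background", bg)
        if mat.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, eps: float = 1e-4) -> np.ndarray:
        return np.log2((self.matrix + eps) / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())


_BASE_TO_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_hits(sequence: str, pwm: Pwm, score_fraction: float = 0.8) -> bool:
    """True if any window (either orientation) scores >= score_fraction * max.

    Windows containing N are skipped.
    """
    threshold = score_fraction * pwm.max_score()
    lo = pwm.log_odds()
    for seq in (sequence, reverse_complement(sequence)):
        L = pwm.length
        if len(seq) < L:
            continue
        rows = np.array([_BASE_TO_ROW.get(b, -1) for b in seq])
        for i in range(len(seq) - L + 1):
            window = rows[i : i + L]
            if (window < 0).any():
                continue
            if lo[window, np.arange(L)].sum() >= threshold:
                return True
    return False


def motif_enrichment(
    foreground: Sequence[PromoterWindow],
    background: Sequence[PromoterWindow],
    pwms: Sequence[Pwm],
    score_fraction: float = 0.8,
    p_threshold: float = 0.01,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Fisher's exact test of motif presence in foreground vs background promoters.

    Clipped windows are excluded. Reports per PWM the 2x2 hit table, odds
    ratio, two-sided p, BH-adjusted q across PWMs, and significance at the
    joint p/q thresholds.
    """
    fg = [w.sequence for w in foreground if not w.clipped]
    bg = [w.sequence for w in background if not w.clipped]
    if not fg or not bg:
        raise ValueError("foreground and background must each have >= 1 usable promoter")
    window_len = max(len(s) for s in fg + bg)
    rows = []
    for pwm in pwms:
        if pwm.length > window_len:
            logger.warning("PWM %s longer than promoter windows; skipped", pwm.name)
            continue
        fg_hits = sum(pwm_hits(s, pwm, score_fraction) for s in fg)
        bg_hits = sum(pwm_hits(s, pwm, score_fraction) for s in bg)
        table = [[fg_hits, len(fg) - fg_hits], [bg_hits, len(bg) - bg_hits]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {"pwm": pwm.name, "fg_hits": fg_hits, "fg_total": len(fg),
             "bg_hits": bg_hits, "bg_total": len(bg), "odds_ratio": float(odds),
             "p": float(p)}
        )
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    report["q"] = multipletests(report["p"], method="fdr_bh")[1]
    report["significant"] = (report["p"] < p_threshold) & (report["q"] < q_threshold)
    return report


def read_jaspar(path: Union[str, Path]) -> list[Pwm]:
    """Parse JASPAR-style PWM text (counts or probabilities per base row)."""
    pwms: list[Pwm] = []
    name = None
    rows: dict[str, list[float]] = {}
    order = "ACGT"

    def flush() -> None:
        if name is None:
            return
        if set(rows) != set(order):
            raise ValueError(f"PWM {name!r} is missing base rows")
        mat = np.array([rows[b] for b in order], dtype=float)
        mat = mat / mat.sum(axis=0, keepdims=True)
        pwms.append(Pwm(name, mat))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = {}
            else:
                m = re.match(r"([ACGT])\s*\[?\s*([-\d.\s]+?)\s*\]?\s*$", line)
                if not m:
                    raise ValueError(f"unparseable PWM line: {line!r}")
                rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    flush()
    return pwms


def peaks_to_frame(peaks: Sequence[TssPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.interval.chrom for p in peaks],
            "start": [p.interval.start for p in peaks],
            "end": [p.interval.end for p in peaks],
            "strand": [p.interval.strand for p in peaks],
            "mode_position": [p.mode_position for p in peaks],
            "read_support": [p.read_support for p in peaks],
            "sample": [p.sample for p in peaks],
            "category": [p.category for p in peaks],
            "distance_to_tss": [p.distance_to_tss for p in peaks],
        }
    )
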