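"""Per-locus repeat quantification and subfamily-level fold-change statistics.

The central objects are a :class:`CountTable` (loci x samples raw counts with
CPM normalisation and per-locus log2 fold changes between knockdown and
control) and two-sample Kolmogorov-Smirnov comparisons of a retrotransposon
subtype's fold-change distribution against a reference set. Also houses the
HERVH-lncRNA overlap/correlation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, overlap_intervals
from .io import AnnotationRecord

logger = logging.getLogger(__name__)

CONTROL = "control"
KNOCKDOWN = "knockdown"

#: Subfamilies making up the LTR7/HERVH group (the full-length unit parts).
HERVH_SUBFAMILIES = ("LTR7", "HERVH-int")


@dataclass(frozen=True)
class KsResult:
    """Two-sample KS statistic D with its two-sided p-value."""

    D: float
    p: float
    n1: int
    n2: int


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation R with its two-sided p-value over n pairs."""

    R: float
    p: float
    n: int


@dataclass
class CountTable:
    """Raw counts (loci x samples) plus sample and locus metadata.

    ``counts`` is indexed by locus_id with one column per sample;
    ``samples`` is indexed by sample id with a ``condition`` column
    (control/knockdown) and a ``replicate`` column; ``loci`` is indexed by
    locus_id and carries repeat_class / family / subfamily (and optionally
    coordinates and unit_id).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    loci: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.samples.index):
            if set(self.counts.columns) != set(self.samples.index):
                raise ValueError("counts columns and sample table disagree")
            self.samples = self.samples.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def sample_ids(self, condition: str | None = None) -> list[str]:
        if condition is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["condition"] == condition])

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.loci.join(self.counts) if not self.loci.empty else self.counts
        out.to_csv(path, sep="\t", index_label="locus_id")


def quantify_repeats(
    fragments: Mapping[str, Sequence[GenomicInterval]],
    loci: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    unique_assignment: bool = False,
) -> CountTable:
    """Count fragments overlapping each repeat locus by >= 1 bp per sample.

    By default a fragment overlapping k loci increments all k; with
    ``unique_assignment`` it goes only to the locus with the largest overlap
    (ties to the leftmost locus).
    """
    locus_ivs = [
        GenomicInterval(r.chrom, r.start, r.end, getattr(r, "strand", "."))
        for r in loci.itertuples()
    ]
    mat = np.zeros((len(loci), len(fragments)), dtype=np.int64)
    for s_idx, (sample, frags) in enumerate(fragments.items()):
        pairs = overlap_intervals(list(frags), locus_ivs)
        if unique_assignment:
            best: dict[int, tuple[int, int]] = {}
            for qi, si, bp in pairs:
                cur = best.get(qi)
                if cur is None or bp > cur[1] or (bp == cur[1] and si < cur[0]):
                    best[qi] = (si, bp)
            for si, _bp in best.values():
                mat[si, s_idx] += 1
        else:
            for _qi, si, _bp in pairs:
                mat[si, s_idx] += 1
    counts = pd.DataFrame(mat, index=loci.index, columns=list(fragments))
    if samples is None:
        samples = pd.DataFrame(index=counts.columns)
        samples["condition"] = [c.rsplit("_", 1)[0] for c in counts.columns]
        samples["replicate"] = range(1, len(counts.columns) + 1)
    return CountTable(counts, samples, loci)


def cpm_normalize(table: CountTable) -> pd.DataFrame:
    """Counts-per-million per sample: cpm[i, s] = raw[i, s] / total[s] * 1e6."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    return table.counts / totals * 1e6


def log2_fold_change(table: CountTable, pseudocount: float = 0.5) -> pd.Series:
    """Per-locus log2((mean knockdown CPM + c) / (mean control CPM + c))."""
    cpm = cpm_normalize(table)
    kd = cpm[table.sample_ids(KNOCKDOWN)].mean(axis=1)
    ctrl = cpm[table.sample_ids(CONTROL)].mean(axis=1)
    if kd.empty or ctrl.empty:
        raise ValueError("need at least one replicate per condition")
    return np.log2((kd + pseudocount) / (ctrl + pseudocount)).rename("log2fc")


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sided two-sample KS test.

    Exact enumeration of the null for small samples (n1 + n2 <= 20),
    asymptotic Kolmogorov distribution with effective n = n1*n2/(n1+n2)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS test requires non-empty samples")
    method = "exact" if len(x) + len(y) <= 20 else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return KsResult(float(res.statistic), float(res.pvalue), len(x), len(y))


# ---------------------------------------------------------------------------
# Subtype grouping and the KS scan

#: Group definitions mirror the standard retrotransposon subtype breakdown:
#: broad classes, the ERV1 family, LTR7/HERVH, the MER subfamilies of ERV1
#: and the ERV1 remainder.
def make_subtype_groups(loci: pd.DataFrame) -> dict[str, pd.Index]:
    cls = loci["repeat_class"].astype(str)
    fam = loci["family"].astype(str)
    sub = loci["subfamily"].astype(str)
    erv1 = fam == "ERV1"
    hervh = sub.isin(HERVH_SUBFAMILIES)
    mers = erv1 & sub.str.startswith("MER")
    groups = {
        "LINE": loci.index[cls == "LINE"],
        "SINE": loci.index[cls == "SINE"],
        "LTR": loci.index[cls == "LTR"],
        "ERV1": loci.index[erv1],
        "LTR7/HERVH": loci.index[hervh],
        "MERs": loci.index[mers],
        "other-ERV1": loci.index[erv1 & ~hervh & ~mers],
    }
    return {name: idx for name, idx in groups.items() if len(idx) > 0}


def subfamily_ks_scan(
    log2fc: pd.Series,
    loci: pd.DataFrame,
    groups: Mapping[str, pd.Index] | None = None,
    reference: str = "background",
) -> pd.DataFrame:
    """KS test of each subtype's log2FC distribution against a reference.

    ``reference`` is either "background" (all loci outside the group) or the
    name of another group (e.g. "MERs"). A group is never compared against
    itself.
    """
    if groups is None:
        groups = make_subtype_groups(loci)
    rows = []
    for name, idx in groups.items():
        if name == reference:
            continue
        if reference == "background":
            ref_idx = log2fc.index.difference(idx)
        else:
            if reference not in groups:
                raise ValueError(f"unknown reference group {reference!r}")
            ref_idx = groups[reference]
            if idx.equals(ref_idx):
                raise ValueError(f"group {name!r} equals its reference; self-comparison disallowed")
        if len(idx) == 0 or len(ref_idx) == 0:
            logger.warning("skipping empty group %s", name)
            continue
        res = ks_two_sample(log2fc.loc[idx], log2fc.loc[ref_idx])
        rows.append(
            {"group": name, "reference": reference, "D": res.D, "p": res.p,
             "n1": res.n1, "n2": res.n2}
        )
    return pd.DataFrame(rows)


def cross_kd_correlation(
    fc_a: pd.Series, fc_b: pd.Series, subset: pd.Index | None = None
) -> CorrelationResult:
    """Pearson correlation of per-locus fold changes between two perturbations."""
    shared = fc_a.index.intersection(fc_b.index)
    if subset is not None:
        shared = shared.intersection(subset)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared loci")
    a = fc_a.loc[shared].to_numpy(dtype=float)
    b = fc_b.loc[shared].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant fold-change vector")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(float(r), float(p), len(shared))


# ---------------------------------------------------------------------------
# HERVH-overlapping lncRNAs


def lncrna_hervh_overlap(
    lncrnas: Iterable[AnnotationRecord],
    loci: pd.DataFrame,
    stranded: bool = False,
) -> pd.DataFrame:
    """(lncRNA, HERVH unit) pairs for lncRNA genes overlapping LTR7/HERVH loci.

    Overlap is >= 1 bp and strand-agnostic by default (HERVH can drive both
    sense and antisense transcripts). Each lncRNA is listed once per
    overlapping full-length unit; solo LTR7 loci count as their own unit.
    """
    genes = [r for r in lncrnas if r.feature_kind == "gene" and r.biotype == "lncRNA"]
    hervh = loci[loci["subfamily"].isin(HERVH_SUBFAMILIES)]
    hervh_ivs = [
        GenomicInterval(r.chrom, r.start, r.end, getattr(r, "strand", "."))
        for r in hervh.itertuples()
    ]
    unit_ids = [
        (r.unit_id if ("unit_id" in hervh.columns and pd.notna(r.unit_id)) else r.Index)
        for r in hervh.itertuples()
    ]
    pairs = set()
    for qi, si, _bp in overlap_intervals([g.interval for g in genes], hervh_ivs, stranded=stranded):
        pairs.add((genes[qi].gene_id, unit_ids[si]))
    out = pd.DataFrame(sorted(pairs), columns=["lncrna_id", "unit_id"])
    return out


def expressed_lncrna_filter(
    table: CountTable, lncrna_ids: Iterable[str], threshold: float = 1.0
) -> list[str]:
    """lncRNAs with mean control-condition CPM strictly greater than threshold."""
    cpm = cpm_normalize(table)
    ctrl_mean = cpm[table.sample_ids(CONTROL)].mean(axis=1)
    ids = [i for i in lncrna_ids if i in ctrl_mean.index]
    return [i for i in ids if ctrl_mean.loc[i] > threshold]


def unit_log2fc(table: CountTable, pseudocount: float = 0.5) -> pd.Series:
    """Fold change per full-length unit, pooling counts over its segments.

    Loci with a unit_id have their raw counts summed per unit before CPM
    (library totals from the full table) and fold-change computation.
    """
    if "unit_id" not in table.loci.columns:
        raise ValueError("locus table has no unit_id column")
    has_unit = table.loci["unit_id"].notna()
    pooled = table.counts[has_unit.to_numpy()].groupby(table.loci.loc[has_unit, "unit_id"]).sum()
    totals = table.counts.sum(axis=0)
    cpm = pooled / totals * 1e6
    kd = cpm[table.sample_ids(KNOCKDOWN)].mean(axis=1)
    ctrl = cpm[table.sample_ids(CONTROL)].mean(axis=1)
    return np.log2((kd + pseudocount) / (ctrl + pseudocount)).rename("unit_log2fc")


def hervh_lncrna_correlation(
    pairs: pd.DataFrame,
    unit_fc: pd.Series,
    lncrna_fc: pd.Series,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Pearson correlation between HERVH-unit and overlapping-lncRNA fold changes.

    ``pairs`` must already be restricted to expressed lncRNAs. Returns the
    correlation plus the per-pair table behind it.
    """
    rows = []
    for r in pairs.itertuples():
        if r.unit_id in unit_fc.index and r.lncrna_id in lncrna_fc.index:
            rows.append(
                {"lncrna_id": r.lncrna_id, "unit_id": r.unit_id,
                 "unit_log2fc": float(unit_fc.loc[r.unit_id]),
                 "lncrna_log2fc": float(lncrna_fc.loc[r.lncrna_id])}
            )
    per_pair = pd.DataFrame(rows)
    if len(per_pair) < 3:
        raise ValueError("need >= 3 (lncRNA, unit) pairs with fold changes")
    r_val, p = stats.pearsonr(per_pair["unit_log2fc"], per_pair["lncrna_log2fc"])
    return CorrelationResult(float(r_val), float(p), len(per_pair)), per_pair


def read_locus_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a repeat-locus TSV (locus_id, chrom, start, end, strand, class...)."""
    df = pd.read_csv(path, sep="\t")
    if "locus_id" in df.columns:
        df = df.set_index("locus_id")
    return df


def read_count_table(counts_path: Union[str, Path], design_path: Union[str, Path]) -> CountTable:
    """Read counts (locus_id + one column per sample) and a sample design TSV."""
    samples = pd.read_csv(design_path, sep="\t").set_index("sample")
    raw = pd.read_csv(counts_path, sep="\t").set_index("locus_id")
    meta_cols = [c for c in raw.columns if c not in samples.index]
    loci = raw[meta_cols]
    counts = raw[[c for c in raw.columns if c in samples.index]]
    return CountTable(counts, samples, loci)
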