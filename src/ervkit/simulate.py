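"""Synthetic data with planted structure for every pipeline stage.

Generates toy genomes carrying full-length LTR7-HERVH-LTR7 units whose
flanking LTRs diverged under a Kimura 2-parameter process at known distance,
solo repeats of background subfamilies, lncRNA genes overlapping HERVH
units, negative-binomial count tables with planted per-subfamily log2
fold-change shifts, ChIP-like peak sets with controlled base-pair
enrichment, and barcoded 5'-capture reads piling up at planted TSS
positions. Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, MergedCoverage, reverse_complement
from .io import (
    AnnotationRecord,
    FastqRead,
    SequenceRecord,
    write_bed,
    write_fasta,
    write_fastq,
    write_gtf,
)
from .repeats import CONTROL, KNOCKDOWN, CountTable


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}

#: Default sample barcodes: 6-mers at pairwise Hamming distance 6, so the
#: <=2-mismatch demultiplexer can never be ambiguous.
DEFAULT_BARCODES = {
    "day0_rep1": "AAAAAA",
    "day0_rep2": "CCCCCC",
    "day5_rep1": "GGGGGG",
    "day5_rep2": "TTTTTT",
}


@dataclass
class SimulationConfig:
    """Stated world for the toy genome and its derived datasets.

    Element counts and lengths are desk-scale stand-ins for the genome-scale
    analysis: 60 full-length units (vs 940 genome-wide), 300 loci per
    background subfamily (matching the per-group sizes the recovery
    properties are stated at), LTR length 450 bp (real LTR7 is ~450 bp) and
    a shortened 2 kb internal segment.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = dc_field(
        default_factory=lambda: {"chr1": 1_200_000, "chr2": 1_200_000}
    )
    n_hervh_units: int = 60
    ltr_length: int = 450
    internal_length: int = 2000
    k_true: float = 0.05  # expected pairwise LTR-LTR K2P distance per unit
    k_true_per_unit: list[float] | None = None  # overrides k_true unit by unit
    kappa: float = 4.0  # transition/transversion rate ratio alpha/beta
    n_solo_ltr7: int = 20
    n_repeat_loci: int = 300  # per background subfamily
    n_lncrna_overlapping: int = 56
    n_lncrna_background: int = 24
    n_coding_genes: int = 20
    gap_range: tuple[int, int] = (200, 800)
    # count model
    planted_log2fc: dict[str, float] = dc_field(default_factory=dict)
    nb_dispersion: float = 0.05
    base_mean: float = 200.0
    base_log_sd: float = 1.0
    n_replicates: int = 3
    # peaks
    peak_count: int = 300
    peak_length: int = 200
    peak_enrichment_factor: float = 1.0
    # CAGE reads
    barcodes: dict[str, str] = dc_field(default_factory=lambda: dict(DEFAULT_BARCODES))
    barcode_error_rate: float = 0.0
    cage_genomic_length: int = 30

    def __post_init__(self) -> None:
        if self.k_true < 0:
            raise ConfigurationError("k_true must be >= 0")
        for name in ("n_hervh_units", "n_solo_ltr7", "n_repeat_loci",
                     "n_lncrna_overlapping", "n_lncrna_background", "n_coding_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_lncrna_overlapping > self.n_hervh_units:
            raise ConfigurationError(
                "n_lncrna_overlapping cannot exceed n_hervh_units (one lncRNA per unit)"
            )
        if self.k_true_per_unit is not None and len(self.k_true_per_unit) != self.n_hervh_units:
            raise ConfigurationError("k_true_per_unit must have one value per unit")


# ---------------------------------------------------------------------------
# K2P sequence evolution


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(len(arr), dtype=np.int8)
    for byte, idx in _BASE_INDEX.items():
        out[arr == byte] = idx
    if not np.isin(arr, list(_BASE_INDEX)).all():
        raise ValueError("sequence must be over {A,C,G,T}")
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def k2p_site_probabilities(alpha: float, beta: float, t: float) -> tuple[float, float]:
    """Exact (transition, per-target transversion) substitution probabilities.

    For the K2P chain with instantaneous transition rate ``alpha`` and rate
    ``beta`` to each of the two transversion targets, run for time ``t``.
    """
    e_tv = np.exp(-4.0 * beta * t)
    e_ts = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv
    return float(p_ts), float(p_tv)


def evolve_pair_k2p(
    ancestor: str,
    alpha: float,
    beta: float,
    t: float,
    rng: np.random.Generator,
) -> str:
    """Evolve ``ancestor`` for time t under the K2P substitution process.

    Each site evolves independently using the exact finite-time transition
    probabilities of the chain; the expected number of substitutions per
    site along the branch is (alpha + 2*beta) * t.
    """
    if alpha < 0 or beta < 0 or t < 0:
        raise ValueError("rates and branch length must be non-negative")
    codes = _encode(ancestor)
    p_ts, p_tv = k2p_site_probabilities(alpha, beta, t)
    u = rng.random(len(codes))
    ts_partner = codes ^ 2  # A<->G, C<->T
    tv1 = codes ^ 1
    tv2 = codes ^ 3
    out = np.where(u < p_ts, ts_partner,
                   np.where(u < p_ts + p_tv, tv1,
                            np.where(u < p_ts + 2 * p_tv, tv2, codes)))
    return _decode(out.astype(np.int8))


def make_ltr_pair(
    ancestor: str, k_total: float, kappa: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Two descendants of one ancestral LTR with expected pairwise distance k_total.

    Each copy evolves along an independent branch of expected length
    k_total / 2, mirroring post-insertion divergence of the two LTRs of a
    provirus.
    """
    d_branch = k_total / 2.0
    beta_t = d_branch / (kappa + 2.0)
    alpha_t = kappa * beta_t
    a = evolve_pair_k2p(ancestor, alpha_t, beta_t, 1.0, rng)
    b = evolve_pair_k2p(ancestor, alpha_t, beta_t, 1.0, rng)
    return a, b


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _decode(rng.integers(0, 4, size=length).astype(np.int8))


# ---------------------------------------------------------------------------
# Toy genome

_SOLO_SUBFAMILIES = [
    # (subfamily, class, family, element length)
    ("L1PA3", "LINE", "L1", 1000),
    ("AluY", "SINE", "Alu", 300),
    ("MER41A", "LTR", "ERV1", 600),
    ("LTR12C", "LTR", "ERV1", 600),
]


@dataclass
class ToyGenome:
    """A generated genome with its repeat/gene annotation and ground truth."""

    genome: dict[str, str]
    repeats: pd.DataFrame  # indexed by locus_id
    genes: list[AnnotationRecord]
    units: pd.DataFrame  # indexed by unit_id
    lncrna_unit: dict[str, str]  # lncRNA gene_id -> overlapped unit_id
    config: SimulationConfig

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def repeat_intervals(self, subset: pd.DataFrame | None = None) -> list[GenomicInterval]:
        df = self.repeats if subset is None else subset
        return [GenomicInterval(r.chrom, r.start, r.end, r.strand) for r in df.itertuples()]

    def to_files(self, outdir: Union[str, Path]) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "repeats_bed": outdir / "repeats.bed",
            "repeats_tsv": outdir / "repeats.tsv",
            "genes": outdir / "genes.gtf",
            "chrom_sizes": outdir / "chrom.sizes",
        }
        write_fasta(
            [SequenceRecord(c, s) for c, s in self.genome.items()], paths["genome"]
        )
        write_bed(
            [(GenomicInterval(r.chrom, r.start, r.end, r.strand), r.Index, 0.0)
             for r in self.repeats.itertuples()],
            paths["repeats_bed"],
        )
        self.repeats.to_csv(paths["repeats_tsv"], sep="\t", index_label="locus_id")
        write_gtf(self.genes, paths["genes"])
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        return paths


def make_toy_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ToyGenome:
    """Lay out full-length units, solo repeats and genes on random background.

    Full-length units are LTR7 / HERVH-int / LTR7 on one strand; the two
    LTRs of each unit are copies of one ancestral LTR independently mutated
    so their expected pairwise K2P distance equals ``config.k_true``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = config

    # Build the element roster, then pack chromosomes left to right.
    elements: list[dict] = []
    for u in range(cfg.n_hervh_units):
        k_u = cfg.k_true_per_unit[u] if cfg.k_true_per_unit is not None else cfg.k_true
        elements.append({"kind": "unit", "id": f"unit{u:04d}", "k_true": float(k_u),
                         "length": 2 * cfg.ltr_length + cfg.internal_length})
    for i in range(cfg.n_solo_ltr7):
        elements.append({"kind": "solo_ltr7", "id": f"soloLTR7_{i:04d}",
                         "length": cfg.ltr_length})
    for subfamily, cls, fam, length in _SOLO_SUBFAMILIES:
        for i in range(cfg.n_repeat_loci):
            elements.append({"kind": "solo", "id": f"{subfamily}_{i:04d}",
                             "subfamily": subfamily, "class": cls, "family": fam,
                             "length": length})
    for i in range(cfg.n_lncrna_background):
        elements.append({"kind": "lncrna_bg", "id": f"lncBG{i:04d}", "length": 2000})
    for i in range(cfg.n_coding_genes):
        elements.append({"kind": "coding", "id": f"gene{i:04d}", "length": 3000})

    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]

    chroms = list(cfg.chrom_lengths)
    sizes = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    # deal elements to chromosomes proportionally to length, deterministic
    assignment = rng.choice(len(chroms), size=len(elements), p=weights)

    genome_arrays = {
        c: rng.integers(0, 4, size=cfg.chrom_lengths[c]).astype(np.int8) for c in chroms
    }

    placed: dict[str, list[tuple[int, dict]]] = {c: [] for c in chroms}
    cursors = {c: 0 for c in chroms}
    lo, hi = cfg.gap_range
    for el, ci in zip(elements, assignment):
        chrom = chroms[ci]
        start = cursors[chrom] + int(rng.integers(lo, hi))
        end = start + el["length"]
        if end > cfg.chrom_lengths[chrom]:
            # try remaining chromosomes in order before giving up
            placed_ok = False
            for alt in chroms:
                start = cursors[alt] + int(rng.integers(lo, hi))
                end = start + el["length"]
                if end <= cfg.chrom_lengths[alt]:
                    chrom, placed_ok = alt, True
                    break
            if not placed_ok:
                raise ConfigurationError(
                    "infeasible packing: elements do not fit in chrom_lengths"
                )
        placed[chrom].append((start, el))
        cursors[chrom] = end

    repeat_rows: list[dict] = []
    unit_rows: list[dict] = []
    genes: list[AnnotationRecord] = []
    lncrna_unit: dict[str, str] = {}

    def insert(chrom: str, start: int, seq: str, strand: str) -> None:
        if strand == "-":
            seq = reverse_complement(seq)
        genome_arrays[chrom][start : start + len(seq)] = _encode(seq)

    unit_count = 0
    for chrom in chroms:
        for start, el in placed[chrom]:
            strand = "+" if rng.random() < 0.5 else "-"
            if el["kind"] == "unit":
                uid = el["id"]
                k_u = el["k_true"]
                ancestor = random_sequence(cfg.ltr_length, rng)
                ltr_a, ltr_b = make_ltr_pair(ancestor, k_u, cfg.kappa, rng)
                internal = random_sequence(cfg.internal_length, rng)
                insert(chrom, start, ltr_a + internal + ltr_b, strand)
                s1, e1 = start, start + cfg.ltr_length
                s2, e2 = e1, e1 + cfg.internal_length
                s3, e3 = e2, e2 + cfg.ltr_length
                for seg, s, e, sub in (("ltr5", s1, e1, "LTR7"), ("int", s2, e2, "HERVH-int"),
                                       ("ltr3", s3, e3, "LTR7")):
                    repeat_rows.append(
                        {"locus_id": f"{uid}_{seg}", "chrom": chrom, "start": s, "end": e,
                         "strand": strand, "repeat_class": "LTR", "family": "ERV1",
                         "subfamily": sub, "unit_id": uid, "k_true": k_u}
                    )
                unit_rows.append(
                    {"unit_id": uid, "chrom": chrom, "strand": strand,
                     "start": s1, "end": e3, "ltr5_start": s1, "ltr5_end": e1,
                     "int_start": s2, "int_end": e2, "ltr3_start": s3, "ltr3_end": e3,
                     "k_true": k_u}
                )
                unit_count += 1
            elif el["kind"] == "solo_ltr7":
                insert(chrom, start, random_sequence(cfg.ltr_length, rng), strand)
                repeat_rows.append(
                    {"locus_id": el["id"], "chrom": chrom, "start": start,
                     "end": start + cfg.ltr_length, "strand": strand,
                     "repeat_class": "LTR", "family": "ERV1", "subfamily": "LTR7",
                     "unit_id": None, "k_true": np.nan}
                )
            elif el["kind"] == "solo":
                insert(chrom, start, random_sequence(el["length"], rng), strand)
                repeat_rows.append(
                    {"locus_id": el["id"], "chrom": chrom, "start": start,
                     "end": start + el["length"], "strand": strand,
                     "repeat_class": el["class"], "family": el["family"],
                     "subfamily": el["subfamily"], "unit_id": None, "k_true": np.nan}
                )
            elif el["kind"] == "lncrna_bg":
                iv = GenomicInterval(chrom, start, start + el["length"], strand)
                gid = el["id"]
                genes.append(AnnotationRecord(iv, "gene", gid, "", "lncRNA"))
                genes.append(AnnotationRecord(iv, "transcript", gid, gid + ".t1", "lncRNA"))
                genes.append(AnnotationRecord(iv, "exon", gid, gid + ".t1", "lncRNA"))
            elif el["kind"] == "coding":
                gid = el["id"]
                end = start + el["length"]
                iv = GenomicInterval(chrom, start, end, strand)
                tid = gid + ".t1"
                exon1 = GenomicInterval(chrom, start, start + 600, strand)
                exon2 = GenomicInterval(chrom, end - 900, end, strand)
                utr = (GenomicInterval(chrom, end - 300, end, strand) if strand == "+"
                       else GenomicInterval(chrom, start, start + 300, strand))
                genes.append(AnnotationRecord(iv, "gene", gid, "", "protein_coding"))
                genes.append(AnnotationRecord(iv, "transcript", gid, tid, "protein_coding"))
                genes.append(AnnotationRecord(exon1, "exon", gid, tid, "protein_coding"))
                genes.append(AnnotationRecord(exon2, "exon", gid, tid, "protein_coding"))
                genes.append(AnnotationRecord(utr, "three_prime_utr", gid, tid, "protein_coding"))

    units = pd.DataFrame(unit_rows).set_index("unit_id") if unit_rows else pd.DataFrame(
        columns=["chrom", "strand", "start", "end"]
    )

    # lncRNAs overlapping HERVH units: one per unit for the first n units.
    overlap_unit_ids = list(units.index[: cfg.n_lncrna_overlapping])
    for i, uid in enumerate(overlap_unit_ids):
        u = units.loc[uid]
        ext5 = int(rng.integers(100, 600))
        ext3 = int(rng.integers(100, 600))
        gid = f"lncHERVH{i:04d}"
        g_start = max(0, int(u.start) - ext5)
        g_end = min(cfg.chrom_lengths[u.chrom], int(u.end) + ext3)
        iv = GenomicInterval(u.chrom, g_start, g_end, u.strand)
        genes.append(AnnotationRecord(iv, "gene", gid, "", "lncRNA"))
        genes.append(AnnotationRecord(iv, "transcript", gid, gid + ".t1", "lncRNA"))
        genes.append(AnnotationRecord(iv, "exon", gid, gid + ".t1", "lncRNA"))
        lncrna_unit[gid] = uid

    repeats = pd.DataFrame(repeat_rows).set_index("locus_id") if repeat_rows else pd.DataFrame(
        columns=["chrom", "start", "end", "strand", "repeat_class", "family",
                 "subfamily", "unit_id", "k_true"]
    )
    genome = {c: _decode(arr) for c, arr in genome_arrays.items()}
    return ToyGenome(genome, repeats, genes, units, lncrna_unit, cfg)


# ---------------------------------------------------------------------------
# Counts with planted fold changes


def planted_locus_shifts(
    loci: pd.DataFrame,
    delta_by_subfamily: Mapping[str, float],
    sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Per-locus latent log2FC: subfamily delta plus optional N(0, sd) noise."""
    shifts = loci["subfamily"].map(delta_by_subfamily).fillna(0.0).astype(float)
    if sd > 0:
        if rng is None:
            raise ValueError("rng required when sd > 0")
        shifts = shifts + rng.normal(0.0, sd, size=len(shifts))
    return shifts.rename("planted_log2fc")


def correlated_shifts(
    base: Sequence[float],
    rho: float,
    rng: np.random.Generator,
    mean: float = 0.0,
    sd: float | None = None,
) -> np.ndarray:
    """A vector whose sample correlation with ``base`` equals ``rho`` exactly.

    The Gaussian noise component is orthogonalised against the standardised
    base before mixing, so the planted coupling is realised in-sample rather
    than only in expectation — downstream recovery tests then measure the
    analysis pipeline's attenuation, not the generator's sampling noise.
    """
    base = np.asarray(base, dtype=float)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    if len(base) < 3:
        raise ValueError("need >= 3 values")
    z = (base - base.mean()) / base.std()
    if sd is None:
        sd = float(base.std())
    noise = rng.standard_normal(len(base))
    noise = noise - noise.mean()
    noise = noise - (noise @ z) / (z @ z) * z  # orthogonal to base
    noise = noise / noise.std()
    return mean + sd * (rho * z + np.sqrt(1.0 - rho**2) * noise)


def simulate_counts(
    loci: pd.DataFrame,
    log2fc: Sequence[float],
    rng: np.random.Generator,
    n_replicates: int = 3,
    base_mean: float = 200.0,
    base_log_sd: float = 1.0,
    dispersion: float = 0.05,
    baseline_means: np.ndarray | None = None,
) -> CountTable:
    """Negative-binomial counts for control and knockdown conditions.

    Locus baselines are log-normal across loci (median ``base_mean``,
    ln-scale sd ``base_log_sd``); knockdown means are baseline * 2**log2fc;
    counts have variance mu + dispersion * mu**2.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    log2fc = np.asarray(log2fc, dtype=float)
    if len(log2fc) != len(loci):
        raise ValueError("log2fc length must match loci")
    if baseline_means is None:
        baseline_means = base_mean * np.exp(rng.normal(0.0, base_log_sd, size=len(loci)))
    mu_ctrl = np.asarray(baseline_means, dtype=float)
    mu_kd = mu_ctrl * 2.0**log2fc
    n_param = 1.0 / dispersion

    cols, names, cond = [], [], []
    for rep in range(1, n_replicates + 1):
        cols.append(rng.negative_binomial(n_param, n_param / (n_param + mu_ctrl)))
        names.append(f"{CONTROL}_{rep}")
        cond.append(CONTROL)
    for rep in range(1, n_replicates + 1):
        cols.append(rng.negative_binomial(n_param, n_param / (n_param + mu_kd)))
        names.append(f"{KNOCKDOWN}_{rep}")
        cond.append(KNOCKDOWN)
    counts = pd.DataFrame(np.column_stack(cols), index=loci.index, columns=names)
    samples = pd.DataFrame(
        {"condition": cond, "replicate": list(range(1, n_replicates + 1)) * 2},
        index=pd.Index(names, name="sample"),
    )
    return CountTable(counts, samples, loci)


# ---------------------------------------------------------------------------
# Peaks


def simulate_peaks(
    target_features: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    n_peaks: int,
    peak_length: int,
    enrichment_factor: float,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Fixed-length peaks with start-position density ``enrichment_factor``
    inside the target feature set and 1 elsewhere (rejection sampling)."""
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    chroms = list(chrom_lengths)
    for c in chroms:
        if peak_length > chrom_lengths[c]:
            raise ValueError(f"peak_length {peak_length} exceeds chromosome {c}")
    if n_peaks == 0:
        return []
    cov = MergedCoverage(target_features)
    valid = np.array([chrom_lengths[c] - peak_length + 1 for c in chroms], dtype=float)
    p_chrom = valid / valid.sum()
    max_w = max(enrichment_factor, 1.0)

    peaks: list[GenomicInterval] = []
    while len(peaks) < n_peaks:
        batch = max(256, 2 * (n_peaks - len(peaks)))
        ci = rng.choice(len(chroms), size=batch, p=p_chrom)
        u = rng.random(batch)
        accept_u = rng.random(batch)
        starts = (u * valid[ci]).astype(np.int64)
        weights = np.ones(batch)
        for c_idx, chrom in enumerate(chroms):
            sel = ci == c_idx
            if not sel.any():
                continue
            inside = cov.overlap_bp(chrom, starts[sel], starts[sel] + 1) > 0
            w = np.where(inside, enrichment_factor, 1.0)
            weights[sel] = w
        accepted = accept_u < weights / max_w
        for k in np.flatnonzero(accepted):
            chrom = chroms[ci[k]]
            peaks.append(GenomicInterval(chrom, int(starts[k]), int(starts[k]) + peak_length))
            if len(peaks) == n_peaks:
                break
    return peaks


# ---------------------------------------------------------------------------
# CAGE-like 5' reads


@dataclass(frozen=True)
class TssSpec:
    """One planted TSS: genomic 5' position, strand, read depth and sample."""

    chrom: str
    pos: int
    strand: str
    depth: int
    sample: str


#: Non-genomic read prefix layout: 6-nt barcode + 5-nt spacer = 11 nt, so
#: trimming the first 11 nucleotides leaves pure genomic sequence.
SPACER = "TCGGG"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def simulate_cage_reads(
    genome: Mapping[str, str],
    tss_specs: Sequence[TssSpec],
    barcodes: Mapping[str, str],
    rng: np.random.Generator,
    genomic_length: int = 30,
    barcode_error_rate: float = 0.0,
) -> tuple[list[FastqRead], dict[str, tuple[str, int, str]]]:
    """Barcoded 5'-capture reads starting exactly at planted TSS positions.

    Returns the reads plus a truth table mapping read id to its genomic
    (chrom, 5' position, strand) — the stand-in for alignment, which is out
    of scope here.
    """
    bcs = list(barcodes.values())
    if len(set(bcs)) != len(bcs):
        raise ConfigurationError("duplicate barcodes")
    if len({len(b) for b in bcs}) > 1:
        raise ConfigurationError("barcodes must be equal length")
    for i in range(len(bcs)):
        for j in range(i + 1, len(bcs)):
            if _hamming(bcs[i], bcs[j]) <= 4:
                raise ConfigurationError(
                    f"barcodes {bcs[i]} and {bcs[j]} are within Hamming distance 4; "
                    "<=2-mismatch demultiplexing would be ambiguous"
                )
    reads: list[FastqRead] = []
    truth: dict[str, tuple[str, int, str]] = {}
    for spec in tss_specs:
        if spec.sample not in barcodes:
            raise ConfigurationError(f"no barcode for sample {spec.sample!r}")
        chrom_seq = genome[spec.chrom]
        if spec.strand == "+":
            if spec.pos + genomic_length > len(chrom_seq):
                raise ValueError("TSS too close to chromosome end")
            genomic = chrom_seq[spec.pos : spec.pos + genomic_length]
        else:
            if spec.pos - genomic_length + 1 < 0:
                raise ValueError("TSS too close to chromosome start")
            genomic = reverse_complement(chrom_seq[spec.pos - genomic_length + 1 : spec.pos + 1])
        bc = barcodes[spec.sample]
        for k in range(spec.depth):
            bc_out = bc
            if barcode_error_rate > 0:
                chars = list(bc)
                for b_i in range(len(chars)):
                    if rng.random() < barcode_error_rate:
                        chars[b_i] = "ACGT"[int(rng.integers(0, 4))]
                bc_out = "".join(chars)
            rid = f"{spec.sample}:{spec.chrom}:{spec.pos}:{spec.strand}:{k}"
            seq = bc_out + SPACER + genomic
            reads.append(FastqRead(rid, seq, "I" * len(seq)))
            truth[rid] = (spec.chrom, spec.pos, spec.strand)
    return reads, truth


def write_cage_fixture(
    reads: Sequence[FastqRead],
    truth: Mapping[str, tuple[str, int, str]],
    outdir: Union[str, Path],
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fastq": outdir / "reads.fastq", "positions": outdir / "positions.tsv"}
    write_fastq(reads, paths["fastq"])
    with open(paths["positions"], "w") as fh:
        fh.write("read_id\tchrom\tpos\tstrand\n")
        for rid, (chrom, pos, strand) in truth.items():
            fh.write(f"{rid}\t{chrom}\t{pos}\t{strand}\n")
    return paths
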