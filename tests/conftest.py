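import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_loci_frame(n_per_group: int = 300, n_background_per_group: int | None = None) -> pd.DataFrame:
    """Locus metadata covering the standard subtype partition, no genome needed.

    ``n_background_per_group`` enlarges the four non-HERVH groups; a shifted
    group that is a small fraction of the library keeps the CPM composition
    effect (library-size inflation by the planted shift) negligible, as it
    is at genome scale.
    """
    rows = []
    groups = [
        ("L1PA3", "LINE", "L1"),
        ("AluY", "SINE", "Alu"),
        ("MER41A", "LTR", "ERV1"),
        ("LTR12C", "LTR", "ERV1"),
        ("HERVH-int", "LTR", "ERV1"),
    ]
    pos = 0
    for subfamily, cls, fam in groups:
        n_group = n_per_group if (
            subfamily == "HERVH-int" or n_background_per_group is None
        ) else n_background_per_group
        for i in range(n_group):
            rows.append(
                {"locus_id": f"{subfamily}_{i:04d}", "chrom": "chr1",
                 "start": pos, "end": pos + 400, "strand": "+",
                 "repeat_class": cls, "family": fam, "subfamily": subfamily,
                 "unit_id": None}
            )
            pos += 1000
    return pd.DataFrame(rows).set_index("locus_id")


@pytest.fixture
def loci_frame():
    return make_loci_frame()


@pytest.fixture(scope="session")
def small_toy():
    """A small planted genome shared by read-only tests."""
    from ervkit.simulate import SimulationConfig, make_toy_genome

    cfg = SimulationConfig(
        seed=11,
        chrom_lengths={"chr1": 400_000, "chr2": 400_000},
        n_hervh_units=12,
        n_lncrna_overlapping=10,
        n_solo_ltr7=5,
        n_repeat_loci=60,
        n_lncrna_background=6,
        n_coding_genes=8,
    )
    return make_toy_genome(cfg)
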