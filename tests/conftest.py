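import numpy as np
import pandas as pd
import pytest

from atacstrat.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """30-sample, 3-cluster cohort small enough for fast unit tests."""
    cfg = CohortConfig(
        n_peaks=3000,
        n_genes=400,
        n_motifs=60,
        samples_per_cluster=(10, 10, 10),
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def canonical_partition(labels):
    """Relabel a partition by first appearance, for comparing clusterings."""
    seen, out = {}, []
    for l in labels:
        if l not in seen:
            seen[l] = len(seen)
        out.append(seen[l])
    return tuple(out)


@pytest.fixture()
def toy_genes():
    from atacstrat.matrixio import GeneAnnotation

    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "-"],
                "tss": [100_000, 900_000],
            }
        )
    )
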