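import numpy as np
import pandas as pd
import pytest

from spectranote import CountMatrix, nsaf, pollen_fixture, presence_filter


def make_counts(
    n_proteins: int,
    treatments=("P-C", "P-HS", "P-E-C", "P-E-HS"),
    n_replicates: int = 3,
    seed: int = 0,
    max_count: int = 50,
) -> CountMatrix:
    """Seeded random CountMatrix with the study's 4x3 layout by default."""
    rng = np.random.default_rng(seed)
    accs = [f"Solyc{i:05d}" for i in range(n_proteins)]
    design = pd.DataFrame(
        [
            {"sample_id": f"{t}_r{r}", "treatment": t, "replicate": r}
            for t in treatments
            for r in range(1, n_replicates + 1)
        ]
    )
    counts = pd.DataFrame(
        rng.integers(0, max_count, size=(n_proteins, len(design))),
        index=accs,
        columns=list(design["sample_id"]),
    )
    lengths = pd.Series(rng.integers(100, 1200, size=n_proteins), index=accs)
    return CountMatrix(counts=counts, lengths=lengths, design=design)


@pytest.fixture(scope="session")
def pollen():
    """Canonical synthetic pollen dataset: (counts, truth, annotations)."""
    return pollen_fixture(seed=7)


@pytest.fixture(scope="session")
def pollen_nsaf(pollen):
    cm, _, _ = pollen
    return nsaf(cm)


@pytest.fixture(scope="session")
def pollen_retained(pollen):
    cm, _, _ = pollen
    return presence_filter(cm).retained
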