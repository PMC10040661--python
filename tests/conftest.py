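import numpy as np
import pandas as pd
import pytest

from pomepan import CultivarPanel, GenotypeMatrix, PAVMatrix


@pytest.fixture
def toy_pav() -> PAVMatrix:
    """Six genes by three cultivars covering every PAV category but dispensable."""
    presence = np.array(
        [
            [1, 1, 1],
            [1, 1, 0],
            [1, 0, 0],
            [0, 1, 0],
            [0, 1, 1],
            [1, 1, 1],
        ],
        dtype=bool,
    )
    return PAVMatrix(
        tuple(f"g{i}" for i in range(1, 7)), ("A", "B", "C"), presence
    )


@pytest.fixture
def small_panel() -> CultivarPanel:
    return CultivarPanel.from_mapping(
        {
            "s1": "soft",
            "s2": "soft",
            "s3": "soft",
            "h1": "hard",
            "h2": "hard",
            "h3": "hard",
        }
    )


def make_genotype_matrix(calls, panel, chrom="chr1", start=100, step=1000):
    """GenotypeMatrix from a loci x cultivars code array at evenly spaced
    positions."""
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[0]
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + step * np.arange(n),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(loci, calls, tuple(panel.cultivar_ids))
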