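import numpy as np
import pytest
import scipy.sparse as sp

from stscore import SimConfig, SpotMatrix


def make_spot_matrix(counts, symbols=None, sample_id="toy") -> SpotMatrix:
    """SpotMatrix from a dense genes x spots array with dummy coordinates."""
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    if symbols is None:
        symbols = [f"g{i}" for i in range(n_genes)]
    return SpotMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"id{i}" for i in range(n_genes)],
        gene_symbols=symbols,
        barcodes=[f"BC{j:04d}-1" for j in range(n_spots)],
        array_row=np.arange(n_spots) // 10,
        array_col=2 * (np.arange(n_spots) % 10) + (np.arange(n_spots) // 10) % 2,
        pxl_row=np.arange(n_spots, dtype=float),
        pxl_col=np.arange(n_spots, dtype=float),
        in_tissue=np.ones(n_spots, dtype=bool),
        sample_id=sample_id,
    )


@pytest.fixture
def small_config() -> SimConfig:
    """A fast generator configuration for structural tests."""
    return SimConfig(
        n_samples=2,
        groups=("control", "lesion"),
        grid_rows=10,
        grid_cols=12,
        epidermis_band_rows=3,
        inflamed_fraction=(0.05, 0.6),
        n_background_genes=400,
        seed=11,
    )


@pytest.fixture
def small_dataset(small_config):
    from stscore import generate_dataset

    return generate_dataset(small_config)
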