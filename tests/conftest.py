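import numpy as np
import pytest

from wmrs.extract import ModulatedSpectrum, SpectraDataset
from wmrs.simulate import (
    AcquisitionConfig,
    CellClassModel,
    DonorEffect,
    RamanPeak,
)


@pytest.fixture
def acq():
    return AcquisitionConfig()


@pytest.fixture
def donor():
    return DonorEffect("donor-1")


@pytest.fixture
def single_peak_model():
    """One Lorentzian at the phenylalanine ring-breathing band, no background."""
    return CellClassModel("one-peak", (RamanPeak(1007.0),))


def spectra_from_matrix(matrix, axis=None, prefix="cell", labels=None):
    """Build unit-norm ModulatedSpectrum objects from the rows of a matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if axis is None:
        axis = np.arange(matrix.shape[1], dtype=float)
    if labels is None:
        labels = ["?"] * len(matrix)
    out = []
    for i, row in enumerate(matrix):
        row = row / np.linalg.norm(row)
        out.append(
            ModulatedSpectrum(
                cell_id=f"{prefix}-{i:04d}",
                class_label=labels[i],
                donor_id="donor-1",
                axis=axis,
                values=row,
                explained_variance_ratio=1.0,
            )
        )
    return out


@pytest.fixture
def random_unit_spectra():
    def make(n_cells, n_bins, seed=0, labels=None):
        rng = np.random.default_rng(seed)
        return spectra_from_matrix(
            rng.normal(size=(n_cells, n_bins)), labels=labels
        )

    return make
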