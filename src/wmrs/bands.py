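"""Per-wavenumber two-sample testing between cell subsets.

A Student t test is run independently at every spectral bin between the
modulated spectra of two groups of cells; bins with p below a stringent
threshold (default 1e-7) form the significance mask, and maximal runs of
consecutive significant bins are reported as band regions.  No additional
multiple-testing correction is applied — the very small alpha is the
control, kept deliberately so that a significant band survives roughly a
Bonferroni-level scrutiny across ~1e3 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .extract import ModulatedSpectrum, SpectraDataset

__all__ = ["SignificanceMap", "BandRegion", "compare_groups", "significant_regions"]


@dataclass
class SignificanceMap:
    """Per-bin t statistics, two-sided p values and the significance mask."""

    axis: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    alpha: float = 1e-7
    mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if not (self.axis.shape == self.t_values.shape == self.p_values.shape):
            raise ValueError("axis, t_values and p_values must share one length")
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p values must lie in [0, 1]")
        self.mask = self.p_values < self.alpha


@dataclass(frozen=True)
class BandRegion:
    """A maximal run of consecutively significant bins, as an axis interval."""

    start: float
    end: float
    n_bins: int
    min_p: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def _group_matrix(group: Sequence[ModulatedSpectrum] | SpectraDataset) -> tuple[np.ndarray, np.ndarray]:
    spectra = list(group)
    if len(spectra) < 2:
        raise ValueError("each group needs at least 2 spectra")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if s.axis.shape != axis.shape or not np.allclose(s.axis, axis):
            raise ValueError(f"spectrum {s.cell_id!r} is not on the group's axis")
    return axis, np.vstack([s.values for s in spectra])


def compare_groups(
    group_a: Sequence[ModulatedSpectrum] | SpectraDataset,
    group_b: Sequence[ModulatedSpectrum] | SpectraDataset,
    alpha: float = 1e-7,
    equal_var: bool = True,
) -> SignificanceMap:
    """Two-sample Student t test at every spectral bin.

    By default the pooled-variance Student statistic with ``nA + nB - 2``
    degrees of freedom is used; ``equal_var=False`` switches to Welch.
    Bins where both groups are constant and equal (0/0) are reported as
    t = 0, p = 1.
    """
    axis_a, A = _group_matrix(group_a)
    axis_b, B = _group_matrix(group_b)
    if axis_a.shape != axis_b.shape or not np.allclose(axis_a, axis_b):
        raise ValueError("the two groups are not on the same axis")
    res = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    t = np.where(np.isnan(res.statistic), 0.0, res.statistic)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return SignificanceMap(axis=axis_a, t_values=t, p_values=p, alpha=alpha)


def significant_regions(sigmap: SignificanceMap, min_run: int = 3) -> list[BandRegion]:
    """Maximal runs of consecutive significant bins of length >= ``min_run``.

    The default of 3 bins favours band-like contiguous regions over isolated
    significant bins.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    mask = sigmap.mask
    regions: list[BandRegion] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            length = j - i + 1
            if length >= min_run:
                regions.append(
                    BandRegion(
                        start=float(sigmap.axis[i]),
                        end=float(sigmap.axis[j]),
                        n_bins=length,
                        min_p=float(np.min(sigmap.p_values[i : j + 1])),
                    )
                )
            i = j + 1
        else:
            i += 1
    return regions
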