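"""Modulated-spectrum extraction: per-cell modulation PCA and zero crossings.

Each of a cell's modulation-step spectra is first normalised by its own total
intensity (compensating laser-power fluctuation between steps).  Treating the
steps as observations over the spectral bins, the first principal component
of the step-centred matrix is the cell's *modulated Raman spectrum*: the
static autofluorescence background cancels in the centring, and what remains
resembles the derivative of the conventional spectrum, with conventional
Raman peaks at its zero crossings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulate import ModulationStack

__all__ = [
    "ModulatedSpectrum",
    "PeakCall",
    "SpectraDataset",
    "normalize_stack",
    "extract_modulated_spectrum",
    "find_zero_crossings",
]


@dataclass
class ModulatedSpectrum:
    """A cell's fluorescence-suppressed modulated Raman spectrum.

    ``values`` is the unit-norm first-principal-axis loading over bins;
    ``explained_variance_ratio`` is the fraction of modulation-stack variance
    it captures.  Sign convention: non-negative inner product with the
    bin-wise derivative of the mean step spectrum (so peaks read like a
    derivative spectrum), with the largest-|value| element made positive on
    ties.
    """

    cell_id: str
    class_label: str
    donor_id: str
    axis: np.ndarray
    values: np.ndarray
    explained_variance_ratio: float

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.shape != self.values.shape:
            raise ValueError("axis and values must have the same length")
        norm = float(np.linalg.norm(self.values))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError(f"values must have unit Euclidean norm (got {norm:.6g})")
        if not 0.0 <= self.explained_variance_ratio <= 1.0 + 1e-12:
            raise ValueError("explained_variance_ratio must lie in [0, 1]")


@dataclass(frozen=True)
class PeakCall:
    """A zero crossing of the modulated spectrum: one conventional Raman peak.

    ``slope_sign`` is +1 for an upward crossing, -1 for downward;
    ``local_amplitude`` is the maximum |value| within the search window
    around the crossing.
    """

    position: float
    slope_sign: int
    local_amplitude: float


class SpectraDataset:
    """Modulated spectra of many cells on a shared axis, with labels."""

    def __init__(self, spectra: Sequence[ModulatedSpectrum]):
        spectra = list(spectra)
        if not spectra:
            raise ValueError("dataset must contain at least one spectrum")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if s.axis.shape != axis.shape or not np.allclose(s.axis, axis):
                raise ValueError(f"spectrum {s.cell_id!r} is not on the shared axis")
        self.spectra = spectra

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def axis(self) -> np.ndarray:
        return self.spectra[0].axis

    def matrix(self) -> np.ndarray:
        """(n_cells, n_bins) matrix of modulated-spectrum values."""
        return np.vstack([s.values for s in self.spectra])

    def class_labels(self) -> list[str]:
        return [s.class_label for s in self.spectra]

    def cell_ids(self) -> list[str]:
        return [s.cell_id for s in self.spectra]

    def donor_ids(self) -> list[str]:
        return [s.donor_id for s in self.spectra]

    def select_classes(self, *labels: str) -> "SpectraDataset":
        keep = [s for s in self.spectra if s.class_label in labels]
        if not keep:
            raise ValueError(f"no spectra with class labels {labels}")
        return SpectraDataset(keep)

    @classmethod
    def from_stacks(
        cls, stacks: Iterable[ModulationStack], normalize: bool = True
    ) -> "SpectraDataset":
        """Extract the modulated spectrum of every stack."""
        return cls([extract_modulated_spectrum(s, normalize=normalize) for s in stacks])


def normalize_stack(stack: ModulationStack) -> ModulationStack:
    """Divide each step spectrum by its own total intensity.

    Total intensity is the plain sum over bins (the grid is uniform, so an
    integration rule would differ only by a constant factor).  Each output
    row sums to 1, which removes per-step gain such as laser-power drift.
    """
    totals = stack.intensities.sum(axis=1)
    bad = np.where(~(totals > 0) | ~np.isfinite(totals))[0]
    if bad.size:
        raise ValueError(
            f"step {bad[0]} of cell {stack.cell_id!r} has non-positive total intensity"
        )
    return ModulationStack(
        cell_id=stack.cell_id,
        class_label=stack.class_label,
        donor_id=stack.donor_id,
        axis=stack.axis,
        intensities=stack.intensities / totals[:, None],
        excitations=stack.excitations,
    )


def extract_modulated_spectrum(
    stack: ModulationStack, normalize: bool = True
) -> ModulatedSpectrum:
    """First principal component of the (normalised) modulation stack.

    The ``n_steps`` rows are treated as observations over ``n_bins``
    variables; after per-bin mean centring the leading right singular vector
    of the centred matrix is the unit-norm modulated spectrum.  A stack whose
    steps are identical (no modulated component — e.g. pure background)
    raises a ``ValueError``.
    """
    work = normalize_stack(stack) if normalize else stack
    X = work.intensities
    mean = X.mean(axis=0)
    Xc = X - mean
    # relative threshold: mean-of-identical-rows roundoff is ~1e-16 of X
    if np.max(np.abs(Xc)) <= 1e-12 * np.max(np.abs(X)):
        raise ValueError(
            f"no modulated component in cell {stack.cell_id!r}: "
            "all steps identical after centring"
        )
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    values = Vt[0]
    evr = float(s[0] ** 2 / np.sum(s**2))

    # Sign convention: align with the derivative of the mean spectrum so the
    # output reads like a differential spectrum; deterministic tie-break.
    grad = np.gradient(mean, work.axis)
    dot = float(values @ grad)
    if abs(dot) <= 1e-12 * np.linalg.norm(grad):
        if values[np.argmax(np.abs(values))] < 0:
            values = -values
    elif dot < 0:
        values = -values

    return ModulatedSpectrum(
        cell_id=stack.cell_id,
        class_label=stack.class_label,
        donor_id=stack.donor_id,
        axis=work.axis,
        values=values,
        explained_variance_ratio=evr,
    )


def find_zero_crossings(
    modspec: ModulatedSpectrum,
    min_amplitude: float | None = None,
    window: float = 20.0,
) -> list[PeakCall]:
    """Locate conventional Raman peaks as zero crossings of the modulated spectrum.

    Every sign change between adjacent bins yields a candidate at the
    linearly interpolated root.  A candidate is retained only if the maximum
    |value| within ``+-window`` cm^-1 of it exceeds ``min_amplitude``, which
    suppresses noise-driven crossings in flat regions.  The default threshold
    is three times the median absolute value of the spectrum.  Results are
    sorted by position; an empty list is valid.
    """
    if min_amplitude is None:
        min_amplitude = 3.0 * float(np.median(np.abs(modspec.values)))
    if min_amplitude < 0:
        raise ValueError("min_amplitude must be >= 0")
    v = modspec.values
    x = modspec.axis
    calls: list[PeakCall] = []
    for i in range(len(v) - 1):
        a, b = v[i], v[i + 1]
        if a == 0.0:
            # an exact zero counts as a crossing only when flanked by
            # opposite signs
            if i > 0 and v[i - 1] * b < 0:
                pos = x[i]
                slope = 1 if b > v[i - 1] else -1
            else:
                continue
        elif a * b < 0:
            pos = x[i] - a * (x[i + 1] - x[i]) / (b - a)
            slope = 1 if b > a else -1
        else:
            continue
        nearby = np.abs(x - pos) <= window
        local = float(np.max(np.abs(v[nearby])))
        if local > min_amplitude:
            calls.append(PeakCall(position=float(pos), slope_sign=slope, local_amplitude=local))
    calls.sort(key=lambda c: c.position)
    return calls
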