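# Methods

## The measurement model

Wavelength-modulated Raman spectroscopy (WMRS) acquires several spectra from
one cell at slightly different excitation wavelengths — here five steps
spanning a total modulation of Δλ = 1 nm around a nominal 785 nm excitation.
All spectra are tabulated on one Raman-shift axis computed relative to the
nominal wavelength (600–1800 cm⁻¹ over 1200 bins by default). In that frame
a band at true Raman shift ν appears at

    ν + 10⁷ · (1/λ₀ − 1/λ_exc)   [cm⁻¹],

so Raman features translate by ~16 cm⁻¹ per nm of excitation detuning, while
the broad cellular autofluorescence — tied to the emission wavelength range
seen by the detector, not to the excitation step — stays static. The
simulator builds exactly this structure: Lorentzian bands (HWHM 8 cm⁻¹, the
standard condensed-phase Raman line shape) that translate per step, a smooth
strictly positive background (broad Gaussian or low-order polynomial,
constrained to be ≥10× wider than the Raman lines) that does not, per-cell
log-normal amplitude jitter with a chosen coefficient of variation, additive
i.i.d. Gaussian noise, and donor-level multiplicative nuisances on
background level and overall gain. Noise is added before the gain
multiplication, so scaling a donor's gain scales every recorded intensity
exactly — the simplest convention that keeps the gain a pure instrument
factor. Bands shifted partially outside the analysis window are truncated by
the window, as a real detector would.

Not emulated (and therefore not probed by any passing test): cosmic-ray
spikes, detector etaloning, wavenumber-calibration drift, and Poisson
(shot-noise) statistics. Real spectra also carry correlated baseline
structure that the single smooth background family does not reproduce, so
passing tests demonstrate the mechanics and calibration of the method, not
instrument-grade performance on real cells.

## Modulated-spectrum extraction

Each step spectrum is divided by its own summed intensity (plain sum — the
grid is uniform, so any quadrature differs by a constant factor), removing
per-step laser-power fluctuation. The five normalised spectra are treated as
observations over the bins; after per-bin mean centring, the leading right
singular vector of the 5 × n_bins matrix is the cell's *modulated Raman
spectrum*, reported with its explained-variance ratio. The static background
cancels in the centring; the result resembles the derivative of the
conventional spectrum, and conventional peak positions are its zero
crossings. Because a principal axis has arbitrary sign, the loading is
oriented to have a non-negative inner product with the central-difference
derivative of the mean spectrum (tie broken by making the largest-magnitude
element positive). A stack whose steps are identical after centring (to
within 10⁻¹² of the matrix scale, covering the roundoff of averaging
identical rows) has no modulated component and raises an error rather than
returning a silent zero vector that would poison downstream PCA.

Zero crossings are located by linear interpolation between adjacent bins of
opposite sign; a crossing is retained only if the maximum |loading| within
±20 cm⁻¹ exceeds a threshold, by default 3× the median absolute loading —
flat noisy regions wiggle around zero and would otherwise flood the peak
list. Both window and threshold are parameters.

One consequence of the unit-norm loading convention is worth noting: a
change confined to one band's amplitude still perturbs every other band's
loading weight through renormalisation. The leakage is proportional to the
changed band's share of the squared norm, so in rich spectra (the 16-band
default fixture) it stays well below realistic within-class spread, but in
sparse spectra with near-zero within-class variance the per-bin t test will
legitimately flag distant bands. The band-power property test uses the full
backbone for this reason.

## Band statistics

For any two cell subsets, a two-sample t statistic is computed independently
at every bin of the modulated spectra — pooled-variance Student with
n_A + n_B − 2 degrees of freedom by default (Welch available), two-sided p.
No multiple-testing correction is applied; the stringent default threshold
α = 10⁻⁷ is the control (roughly a Bonferroni-level bar across ~10³ bins).
Bins where both groups are constant and equal are reported as t = 0, p = 1.
Maximal runs of ≥ `min_run` consecutive significant bins (default 3, to
favour band-like regions over isolated bins) are reported as intervals.

## Classification

The modulated spectra are reduced by mean-centred PCA to the leading 7
components (the default follows common practice for this assay scale; it is
a parameter). Cells are classified by leave-one-out cross-validation: for
each held-out cell the principal axes are refit on the remaining cells, all
cells are projected, and the held-out cell takes the label of its nearest
training neighbour by Euclidean distance in score space (k = 1; no score
whitening; equidistant neighbours resolved by smallest cell id for
determinism). Refit-per-fold is the honest protocol — the held-out cell
influences neither the axes nor the neighbour pool; a single-shared-PCA
approximation is available behind a flag but is not the default. Pairwise
sensitivity/specificity comes from a dedicated two-class LOOCV run, not from
collapsing the multi-class confusion matrix, and the positive class defaults
to the first-listed but is a parameter, since the two conventions swap the
two metrics.

## Study conditions and problem sizes

The default synthetic study is three classes × 60 cells × three donors
(donor multipliers: background ×{0.7, 1.0, 1.3}, gain ×{0.8, 1.0, 1.2}),
chosen to mirror a multi-donor immune-cytometry acquisition at the small end
of its stated range. Class effects are a 0.6 fractional boost of each
class's emphasised bands over a shared 16-band backbone; cell-to-cell
amplitude CV is 0.15; additive noise σ is 0.02 of the strongest band;
background is 10× the strongest band. The null-calibration experiment uses
two *identical* class models at 60 + 60 cells over 20 replicate seeds; the
chance level for LOOCV 1-NN there is 59/119 ≈ 0.496, comfortably inside the
3-standard-error bracket the test applies around 0.5. The oracle-agreement
checks run on 50 random 5 × 150 stacks; the brute-force LOOCV cross-check on
8-cell datasets where exhaustive per-fold recomputation is cheap.

## Numerical choices

- SVD-based PCA throughout (`numpy.linalg.svd` for the per-cell 5 × n_bins
  extraction, scikit-learn's full-SVD PCA for the dataset-level fit); the
  test suite's independent oracle route uses `scipy.linalg.svd`.
- Component-sign ambiguity never affects results: distances are invariant to
  per-component sign flips, and the extraction sign is pinned by the
  derivative convention above.
- Degenerate inputs raise informative errors naming the offending step,
  cell or stage: non-positive step totals, zero-variance stacks, mismatched
  axes, single-member classes, out-of-range component counts.
- Everything is deterministic given the seed; dataset generation spawns
  per-cell seeds from one `numpy` generator so cell order does not perturb
  other cells' draws.

## Known limitations

- Equal stepping of the excitation grid is an assumption; the modulation
  waveform of a real instrument may differ.
- The per-bin t test ignores inter-bin correlation; its calibration test
  uses independent-noise fixtures for that reason.
- Sensitivity/specificity values measured on the synthetic defaults
  characterise the synthetic separability, not any real cell population.
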