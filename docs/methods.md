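# Methods

## The model

A processed (frequency-domain) multidimensional NMR spectrum is, to a good
approximation, a sum of direct products of one-dimensional lineshapes: each
resonance contributes an (approximately separable) non-negative peak. For a
2D spectrum stored as a matrix `Y` (m × T) this is the non-negative matrix
factorization (NMF) model

    Y = A X + N,      A ≥ 0 (m × r),  X ≥ 0 (r × T),

where the columns of the basis matrix `A` hold the lineshapes along the
first axis, the rows of the source matrix `X` hold the matching lineshapes
along the second axis (carrying the intensity), `r` is the number of
resonances, and `N` is noise. Because each resonance becomes its own rank-1
term, overlap between peaks is deconvoluted by the factorization itself —
the central advantage over local-maximum or single-peak lineshape pickers.

The factors minimize the squared Euclidean divergence
`D(A, X) = ‖Y − A X‖²_F` under non-negativity, via the ISRA-type
multiplicative updates

    A ← A ⊙ (Y Xᵀ) ⊘ (A X Xᵀ),     X ← X ⊙ (Aᵀ Y) ⊘ (Aᵀ A X),

which preserve non-negativity from any positive starting point and never
increase the divergence. A small `eps = 1e-12` is added to every
denominator entry to avoid 0/0 (standard ISRA stabilization).

### 3D spectra: the shared-basis slice model

A 3D tensor `Y` (I × T × Q) is treated slice-wise: every frontal slice
`Y_q` shares one basis matrix `A` and has its own source matrix,

    Y_q = A D_q X'_q + N_q = A X_q + N_q,    q = 1..Q,

with `D_q` diagonal weights and `X'_q` row-normalized source shapes.
Column-stacking the slices reduces this exactly to one 2D NMF problem
`[Y_1 … Y_Q] = A [X_1 … X_Q]`, which is how the default `shared_basis`
mode solves it. An alternative `independent_slices` mode factorizes every
slice separately and chains matching components across adjacent slices by
the cosine similarity of their basis columns (floor 0.9 by default); both
readings of the slice model are exposed because the method description
admits either. The per-slice weights `D_q[j]` of a component, read across
`q`, are its lineshape along the slab axis and yield the third peak
coordinate. The slab axis defaults to the last stored (directly detected)
dimension.

### Uniqueness handling

The quadratic cost has scaling/rotational ambiguities. As is conventional:
the input is clipped at zero (negative baseline values carry no signal
under the non-negativity premise; they are clipped, not shifted) and
normalized to unit Frobenius length, keeping the scale to restore
intensities; every column of `A` is normalized to unit l1-norm with the
scale moved into the matching row of `X`.

## Solver

* **Initialization.** The first restart is the deterministic SVD-based
  NNDSVD start (each leading singular triplet split into its dominant
  non-negative part, zeros floored to a small positive value). Random
  strictly positive uniform(0.1, 1.1) starts fill the remaining restarts
  (default 5 total), and the lowest final divergence wins. The NNDSVD
  start matters: from purely random starts the updates frequently settle
  into a local minimum that spends two components on one strong line and
  starves the weakest one.
* **Stopping.** Iteration stops when the relative residual improvement has
  stayed below `plateau_tol = 1e-8` for 10 consecutive iterations (the
  window follows the published stop rule; the numeric threshold is this
  package's choice), at the absolute floor `tol = 1e-14` on the normalized
  scale, or at `max_iter = 5000`. The cap is generous because
  multiplicative updates converge slowly on strongly overlapped clean
  spectra (the cost surface is nearly flat along directions that mix
  overlapping components); noisy problems plateau-stop far earlier.
* **Model order.** The number of components is chosen by a residual-decay
  sweep over candidate ranks (default 2–7): each candidate is factorized
  with the plateau stop and the smallest rank within
  `max(1e-5, 2% relative)` of the minimum final residual wins. The
  absolute tie tolerance equals the solver's measured convergence
  precision on strongly overlapped data — a residual gap smaller than
  that is not evidence for a larger model.

## Peak picking

Each component contributes one non-negative 1D profile per axis (basis
column, source row, and for 3D the slab-weight profile). Per profile:

1. **Shape match.** An ideal Gaussian of the average linewidth
   (`avg_width`, default sd 2.0 points; bounds 0.5–10 points) is slid
   across the grid and the centre maximizing the normalized scalar
   product (cosine) with the profile is kept.
2. **Linewidth adaptation.** The width is refined at fixed centre by a
   bounded least-squares fit (with the amplitude profiled out, this
   reduces to maximizing the scalar product over the width).
3. **Interpolation.** The sub-grid position and apex height come from the
   three-point parabola through the profile around the matched centre.
   A median-of-profile baseline is subtracted from the apex height:
   zero-clipped noise gives factorized shapes a positive pedestal, and
   the median of a localized lineshape on a long axis is a robust
   estimate of it (zero for clean data).

The provisional peak intensity is the intensity scale times the product of
the per-axis apex heights — the reconstruction amplitude at the apex —
which matches a single-intensity-per-peak list.

**Joint refinement.** Between strongly overlapping components the
factorization's 1D shapes remain slightly mixed even at small residual
(the flat directions noted above), and under noise they carry a share of
the noise floor; both bias apex products by several percent. The final
stage therefore fits the explicit peak model — all component amplitudes,
centres and per-axis Gaussian widths plus one constant background level —
to the observed spectrum by bounded least squares, initialized at the
shape-derived estimates, with centres allowed to move at most 3 points
(the factorization localizes; the fit polishes) and widths confined to
0.5–2× the average linewidth so noise-broadened shapes cannot degenerate
into background blobs. The background column absorbs the positive pedestal
left by zero-clipping. The fit runs on the union of ±6σ boxes around the
components. An optional `share_widths` mode ties all components to one
linewidth per axis. With the refinement, noiseless four-peak recovery is
exact to better than 10⁻³ points and 10⁻³ relative intensity down to
3-point separations; without it, errors of 3–8% persist at any practical
iteration count. `refine_passes=0` disables the stage.

A user-defined intensity threshold (default 0.02 of the strongest peak)
prunes weak components, and positions are converted to ppm through the
axis calibrations (index 0 = downfield edge; carrier at the centre index).

### Constrained mode (known positions)

When peak positions along one or two axes are known from a consistently
referenced companion experiment, the basis matrix is built from Gaussians
of the average linewidth at the known positions (their Kronecker product,
row-unfolded, when two axes are constrained) and held fixed while only the
source matrix is updated — the original ISRA setting. Output peaks carry
the known coordinates verbatim on constrained axes; free-axis coordinates
come from the fitted source shapes. An empty known list falls back to the
unconstrained pipeline with a warning.

## The synthetic benchmark

`synthetic.make_hsqc` emulates the four-signal HSQC study: four 2D
Gaussian peaks of distinct amplitudes (1.0, 0.8, 0.6, 0.4; sd 2.0 points
per axis) on a 128 × 128 grid, placed on the grid diagonal with a common
per-axis separation between adjacent centres and the group centred in the
grid. The diagonal arrangement keeps the clean matrix at non-negative rank
4 (a 2 × 2 square arrangement would collapse to rank 2 and make a
four-component factorization ill-posed). Each 2D line is evaluated on a
±4σ box — tails beyond that are below 3.4 × 10⁻⁴ of the apex — so
well-separated configurations are exactly additive and the noiseless
maximum equals the strongest amplitude exactly.

**Noise convention.** "Percent noise" is the peak-to-peak amplitude of the
added Gaussian noise relative to the maximum peak amplitude, the way noise
is conventionally read off a spectrum trace; with the textbook relation
pp ≈ 5 × rms this makes the rms equal `fraction × max / 5`. The rms
reading (`rms = fraction × max`) was rejected on estimation-theoretic
grounds: under it, at 60% noise the matched-filter bound on the weakest
peak's intensity error alone is 0.17 absolute — more than twice the 20%
correctness tolerance — so the benchmark's own pass conditions would be
unreachable for any estimator. The noisy spectrum is clipped at zero.

**Study pipeline** (`synthetic.run_cell`): when noise is present, the
grand-mean pedestal is subtracted (and re-clipped); the factorized copy is
additionally matched-filter smoothed (Gaussian, σ = the average linewidth)
and thresholded at median + 1 robust sd (1.4826 × MAD). Both steps act on
the *detection* copy only — the joint lineshape fit always runs on the
unsmoothed spectrum, so positions, widths and intensities are unaffected.
Without them the clipped-noise pedestal, whose Frobenius energy exceeds
the weakest line's, steals a component from it. Factorization rank is
fixed at r = 4 with the study threshold 0.1.

**Scoring** (`synthetic.score_picks`): each true peak is matched to its
nearest picked peak; a run is correct iff every position error is within 1
point on every axis (boundary inclusive), every intensity is within 20%
relative error, and exactly four peaks were picked. The tolerance sweep
(`synthetic.tolerance_sweep`) covers separations 10…1 points × noise
0…100% in 10% steps with 11 seeds per cell, takes majority verdicts, and
enforces a monotone frontier per separation (once a noise level fails, all
higher levels are marked failed). For the strongest line it additionally
records whether its position is within 1 point *while it remains
distinguishable* (expected peak count and the strongest truth mapping onto
the most intense pick) and whether its intensity is within 20%.

**What the generator does not emulate:** Lorentzian or mixed lineshapes,
t1-noise ridges, solvent stripes, baseline roll, correlated (colored)
noise, and non-uniform-sampling artifacts. Passing the study therefore
demonstrates correct deconvolution of idealized separable Gaussian peaks
under white noise, not robustness to every artifact of real spectra.

`scripts/acceptance.py` reruns the two relevant slices of the sweep
(separation 7 over the full noise range; separation 1 over 0–30%) and
reports the four frontier thresholds. Problem sizes — 128 × 128 grids,
11 noise levels × 11 seeds at separation 7 and 6 levels × 11 seeds at
separation 1 — are the package's study configuration.

## Numerical and design notes

* Internal indexing is 0-based fractional grid points; ppm appears only at
  I/O boundaries. Index 0 is the downfield (highest-ppm) edge; the ppm
  step between adjacent points is `sw / n / f` and the carrier sits at the
  centre index `(n − 1)/2`.
* The npy_container (`.npz`) dialect is the canonical lossless format; the
  NMRPipe and UCSF readers/writers implement the standard single-file
  layouts directly (512-float header; 180 + 128·n byte header with tiled
  big-endian data) and store real float32 data.
* Exact zeros are invariant under multiplicative updates ("zero locking");
  the strictly positive initializations avoid spurious locking.
* Degenerate inputs: an all-zero or all-negative spectrum raises a
  degenerate-input error at preprocessing; an all-zero component profile
  yields a no-peak sentinel and the component is dropped with a log entry;
  a flat three-point triple interpolates to offset 0 at its centre value.
* Ties in the Gaussian shape match resolve to the lower grid index; model
  order ties resolve to the smaller rank (parsimony).
* Known limitations: peak intensities assume separable Gaussian shapes;
  heavily non-separable (tilted) peaks are split across components; the
  3D `independent_slices` mode depends on the similarity floor when
  components drift quickly across slices; sub-point separations below ~2
  grid points are not reliably deconvoluted, which is itself part of the
  benchmarked behaviour.
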