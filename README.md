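# nmfpeaks

Peak picking of 2D/3D NMR spectra by non-negative matrix factorization.

Automated peak pickers that look for local maxima, or fit one lineshape at
a time, break down exactly where peak lists matter most: in overlapped
regions of crowded spectra (NOESY cross-peak clusters, backbone amide
regions of larger proteins), where they merge neighbours and report wrong
frequencies and intensities. `nmfpeaks` instead *decomposes* the spectrum:
a frequency-domain spectrum `Y` is approximated by a sum of direct
products of non-negative 1D lineshapes,

    Y = A X + N,        A ≥ 0,  X ≥ 0,

where each column of the basis matrix `A` and the matching row of the
source matrix `X` hold one resonance's lineshape along each axis, so
overlap is deconvoluted by the factorization itself. The factors minimize
the squared Euclidean divergence `D(A, X) = ‖Y − AX‖²` by ISRA-type
multiplicative updates

    A ← A ⊙ (Y Xᵀ) ⊘ (A X Xᵀ),     X ← X ⊙ (Aᵀ Y) ⊘ (Aᵀ A X),

which keep every entry non-negative and never increase the divergence.
3D spectra use the slice (NTF2) model `Y_q = A D_q X'_q + N_q`: one basis
matrix shared across all frontal slices, per-slice diagonal weights —
solved exactly as a 2D problem on the column-stacked slices. Peaks are
then read off the factorized 1D shapes by Gaussian shape matching,
linewidth adaptation and three-point parabolic interpolation, polished by
a joint bounded lineshape fit, and written as Sparky/XEASY/TSV peak lists.
The number of components can be selected automatically by a residual-decay
sweep, and known peak positions from a consistently referenced companion
experiment can be held fixed (classic ISRA) to pin down the remaining
axes. The audience is NMR spectroscopists and methods developers who need
reliable peak lists from overlapped regions, plus a ground-truthed
synthetic benchmark for pickers.

## Worked example

Generate the four-peak synthetic HSQC benchmark (peaks of amplitude
1.0/0.8/0.6/0.4, Gaussian sd 2 points, 8 points apart on a 128×128 grid)
with 20% peak-to-peak noise, and pick it at four components:

```sh
$ nmfpeaks synth --separation 8 --noise 0.2 --seed 3 --out s.npz --truth t.json
spectrum -> s.npz, truth -> t.json
$ nmfpeaks pick2d s.npz -r 4 --threshold 0.1 --out p.tsv --report r.json --seed 5
4 peaks -> p.tsv
$ head -3 p.tsv
ppm_15N	ppm_1H	intensity	points_15N	points_1H	fwhm_15N	fwhm_1H	component	assignment
121.5732	8.6577	9.951e-01	52.0546	52.0520	4.5325	4.6181	0	-
119.0801	8.4095	7.762e-01	60.0403	59.9954	4.7041	4.6163	1	-
```

The strongest true peak (amplitude 1.0 at grid point 52) is reported at
(52.05, 52.05) with intensity 0.995 — within 0.06 points and 0.5% despite
the noise — and the ppm columns follow the axis calibrations stored in the
container. Omitting `-r` runs the residual-decay sweep over r = 2…7
(`select-r` shows the decay directly); on noisy spectra the sweep counts
noise structure as extra components, so inspect the decay rather than
trusting the minimum blindly. The same workflow applies to measured
spectra:

```sh
nmfpeaks pick3d spectrum.ft3 --auto-components --out peaks.list --peak-format sparky
nmfpeaks pick-constrained hsqc.ucsf --known-peaks hnco.list --known-axes 0,1
nmfpeaks select-r spectrum.ft2        # residual decay over candidate ranks
```

From Python, the same pipeline is
`preprocess` → `factorize` / `factorize_ntf2` → `assemble_peaks`, all
exported from the top-level package.

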