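# Methods

This note documents the model, the numerical choices, and what the
synthetic-data generator does and does not establish. It is the package's
own account of its science; every empirical statement here is computed by
the test suite or the examples, not asserted from elsewhere.

## Pipeline model and assumptions

The pipeline estimates, per sliding window of width δ, an all-to-all
amplitude-envelope correlation (AEC) matrix between parcellated source
timecourses, and then decomposes the resulting connection × time matrix
with temporal ICA. The underlying assumptions are:

* **Connectivity is band-limited envelope co-modulation.** The carrier band
  is a user choice (e.g. 13–30 Hz beta); the AEC between Hilbert envelopes
  within a window is the connectivity measure. Phase metrics (coherence,
  PLV) are deliberately out of scope — they probe a different coupling mode.
* **Leakage is zero-lag and linear.** Source-reconstruction leakage appears
  as an instantaneous linear mixture, so orthogonalising the windowed region
  timecourses removes it — at the cost of genuine zero-lag correlation,
  which this method therefore cannot see. Orthogonalisation is applied *per
  window*, because leakage depends on the local signal-to-noise ratio.
* **Networks are connections sharing one temporal profile.** A component of
  the temporal ICA is a set of connections whose strengths co-vary; its
  mixing column is the network's spatial signature, and its timecourse is
  tested for task locking.

## Symmetric orthogonalisation

For each windowed matrix `Q` (regions × samples, rows mean-centred), we
solve `min ‖Q − Λ U‖_F` over diagonal positive `Λ` and orthonormal-row `U`:

* init: `U₀ = polar(Q)` — the analytic closest-orthonormal (Procrustes)
  solution `(Q Qᵀ)^(−1/2) Q`;
* alternate: `λ_k = ⟨q_k, u_k⟩` given `U`; `U = polar(Λ Q)` given `Λ`.

Each half-step is the exact minimiser of its subproblem, so the objective is
non-increasing; iteration stops when its relative change falls below
`tol = 1e-9` (max 60 iterations, both surfaced in config). A negative `λ_k`
is folded to `|λ_k|` with the row of `U` sign-flipped — envelopes and
correlation magnitudes downstream are sign-invariant. Mean-centring first
makes row orthogonality coincide with zero Pearson correlation (centred
rows stay centred under the polar map, which acts within the row space).
Full rank of `Q` is required and checked operationally as
`cond(Q Qᵀ) < 1e10`. Step order within an iteration (lengths after
orientations) is a free choice; both orders converge to the same stationary
points on all tested instances, where the converged objective agrees with an
independent numerical minimiser to < 1e-6.

## Windowing and filtering

Filtering is a zero-phase forward–backward Butterworth band-pass (order 4
per pass), applied to the continuous recording *before* segmentation so that
windows carry no filter transients and envelope timing is preserved. Window
centres enumerate `t_start, t_start+shift, …, t_end`
(count `⌊(t_end−t_start)/shift⌋ + 1`); samples are 0-based half-open ranges
`[round((onset+centre−δ/2)·f), +f·δ)`. Partial windows at recording edges
raise rather than zero-pad, since correlation on padded data is biased.
The long-epoch plan (−13 s to 25 s at 0.5 s shift) enumerates to 77 windows
under this rule.

## Temporal ICA

Each adjacency slab's strict upper triangle (row-major) becomes one row of
`P`; the connection dimension is reduced by SVD prewhitening of the
mean-centred connection × time matrix (so a connection's *static* level is
removed; only its dynamics enter the decomposition), then deflation-mode
FastICA with the cubic contrast (max 1000 iterations, tol 1e-6, up to 5
seeded restarts on non-convergence) extracts `nic` temporally independent
signatures. Whitening is computed once on the concatenation of all windows,
trials and subjects — a group-level decomposition. The default `nic = 10` is
configurable; on planted-network simulations, varying `nic` between 8 and 12
leaves every planted network recoverable (spatial match |r| > 0.9), so the
choice is not critical.

ICA sign and scale are fixed by convention: each mixing column has unit norm
with its largest-magnitude entry positive, and `X` is rescaled so `A X` is
unchanged. All tests match components to ground truth by maximal absolute
correlation, making assertions order- and sign-invariant.

## Permutation inference

* **Sign-flip null**: flip the sign of `⌊Ns/2⌋` subjects' contributions
  before trial averaging; exhaustive mode enumerates all `C(Ns, ⌊Ns/2⌋)`
  subsets (complementary subsets are distinct realisations — 6435 for 15
  subjects, 92 378 for 19), with a sampled mode above a configurable cap.
  Destroys signals that are consistent across subjects; preserves the
  magnitude of subject-idiosyncratic fluctuation.
* **Sham-onset null**: re-epoch the component timecourses at random onsets
  and re-average. Because the component timecourses exist only on the
  concatenated window timeline (windows are computed inside genuine trial
  epochs), sham epochs are drawn as uniformly random stretches of
  `N_trial` consecutive window slabs on each subject's timeline,
  independently per subject and sham trial. This treats the concatenated
  timeline as continuous across trial boundaries — an approximation that is
  exact for the dynamics the null must destroy (onset locking) and
  conservative about window-to-window autocorrelation.
* **Correction**: two tails × `nic` components × temporal DOF, where one DOF
  accrues per accumulated shift exceeding δ/2: `⌊N·shift/(δ/2)⌋` (8 for the
  49-window plan, 12 for the 75-window plan). A component is significant iff
  some timepoint escapes the order-statistic bounds of *both* nulls. When
  the corrected tail is finer than `1/n_realisations`, the bound clamps to
  the sample extreme and a warning is logged (the exhaustive flip null of a
  15-subject study sits exactly in this regime); erroring instead would
  reject legitimate study sizes.

The window-noise figure `σ(r) = 1/√(Bw·δ)` (with `η = Bw·δ` effective DOF)
is exposed as `sigma_r`; empirically, the across-window standard deviation
of null envelope correlations sits slightly below this bound (≈ 0.8×, within
the 20 % band checked in the tests) — `η` is an upper limit on envelope DOF,
and the band-pass transition bands make the effective bandwidth differ
slightly from the nominal `Bw`.

## Synthetic data: what it emulates, and what a green test establishes

Per region, the generator band-pass filters white Gaussian noise (the
oscillatory carrier). A planted network shares one positive low-frequency
modulator `g(t)` (lognormal-transformed < 1 Hz noise, unit mean, log-sd
0.75) among its member regions; region amplitude is `1 + c(t)(g(t) − 1)`
with coupling weight `c(t)` following the task-locked modulation profile
around each trial onset (or a constant tonic level for non-task controls),
scaled per subject by a truncated-normal factor (sd 0.2) to emulate
between-subject variability. The modulated signal is re-filtered to the band
(keeping ≥ 95 % of power in band), optionally mixed by a known full-rank
zero-lag leakage operator (unit diagonal, off-diagonals `s·0.3^(|j−k|−1)`),
and broadband measurement noise (sd 0.1) is added.

Because coupling is a *shared modulator among member regions*, every pair of
member regions is coupled: planted networks are effectively cliques, and
test ground truth uses 3-region cliques so the declared and realised edge
sets coincide.

Default coupling amplitude in the acceptance worlds is 0.4, which puts
trial-locked AEC modulations on the order of the window noise σ(r) ≈ 0.1 —
the regime real task data occupies. (At full-strength coupling the planted
effects are so large that the permutation test correctly flags even the
faint ICA cross-talk they leave in every other component; that is a property
of an unrealistically clean world, not of the inference.)

What the generator does **not** emulate: realistic sensor-level MEG noise,
forward-model errors, spatially heterogeneous leakage, 1/f background
spectra, region-size effects of real parcellations, or evoked (phase-locked)
responses. A green end-to-end test therefore establishes the *statistical
machinery* — leakage removal, envelope correlation, group ICA, permutation
calibration — not performance on real recordings.

## Reduced-scale acceptance worlds

End-to-end statistical checks run dozens of full pipeline fits, so they use
a reduced world chosen once: 10 regions, 14 subjects, 10 trials spaced 20 s,
100 Hz sampling, band 8–25 Hz (preserving the beta bandwidth Bw = 17 Hz and
hence σ(r) ≈ 0.1 at δ = 6 s), windows of 6 s shifted 2 s over −8…+8 s
(9 windows, 6 temporal DOF). The sign-flip null is exhaustive
(C(14,7) = 3432); the sham-onset null uses 4800 realisations. Each fit takes
a few seconds, keeping the 20-repetition recovery and type-I checks within
minutes on one CPU.

## Degenerate inputs and numerical conventions

* Rank-deficient windows (duplicated or collinear regions) raise with the
  full-rank requirement named; zero-variance envelopes name the region.
* Correlation slabs are symmetrised (`(R+Rᵀ)/2`, unit diagonal) before
  vectorisation; asymmetry beyond 1e-8 raises.
* `nic` above the data rank raises; whitened covariance is checked to 1e-8.
* All randomness flows from explicit integer seeds (per-subject generator
  streams are spawned from the dataset seed); identical seeds give
  bit-identical datasets, decompositions and reports.

## Known limitations

* The 6 s window imposes ±3 s temporal uncertainty on network timecourses;
  events closer than the window width blur together.
* Orthogonalisation removes genuine zero-lag coupling along with leakage,
  and slightly redistributes correlation across the remaining edges.
* Group-level whitening means components describe the cohort; single-subject
  reliability of windowed AEC is known to be poor, and no subject-level
  inference is offered.
* The sham-onset null's continuous-timeline approximation is only exact when
  trial epochs tile the recording; with sparse trials it slightly widens the
  null (conservative).
* Bonferroni over components × DOF is rigorous but conservative;
  maximal-statistic correction would be a natural refinement.
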