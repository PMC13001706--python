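# Methods

## The model

Within a short window of a multichannel iEEG recording, the voltage vector
x(t) ∈ ℝ^M (one entry per electrode, in µV) is modelled as a discrete-time
linear dynamical system

    x(t+1) = A x(t),

with a separate state-transition matrix A ∈ ℝ^{M×M} per window.  The window
must be short enough that the dynamics are approximately stationary and long
enough that the regression is well posed; the defaults are a 250-sample
window advanced in 125-sample steps (250 ms / 125 ms at 1 kHz, 500 ms /
250 ms at 500 Hz), the common choice in the fragility literature.  A trailing
partial window is dropped rather than padded.

### Estimating A

A is the ridge estimator over the window's n−1 transition pairs,

    A = Y Xᵀ (X Xᵀ + λI)⁻¹,   X = [x(0) … x(n−2)],  Y = [x(1) … x(n−1)],

computed by a positive-definite solve of the normal equations.  λ is an
absolute additive term, not scaled by window length, so the same λ bounds
are meaningful across window sizes.  The data are fitted in raw (filtered)
microvolts without per-channel variance normalization.

A fragility value is only well defined when the estimated dynamics are
stable (spectral radius ρ(A) < 1; numerical slack 1e-12).  When the caller
does not fix λ, it is selected adaptively:

1. fit at λ = 1e-4; if stable, done (zero bisection steps);
2. otherwise fit at the upper bound λ = 10; if even that is unstable, no λ
   in range helps — return the λ=10 fit flagged unstable (downstream code
   carries the flag; such windows are computed but marked ill-defined);
3. otherwise bisect in log₁₀λ between 1e-4 and 10 for up to 20 steps,
   keeping the smallest λ whose fit is stable.

Bisection runs in log space because the bounds span five orders of
magnitude, and it seeks the *smallest* stabilizing λ so the estimate stays
as close as possible to the lightly-regularized fit.

### Fragility of an electrode

Fragility asks: how small a structured change to A suffices to make the
dynamics marginally unstable?  The perturbation is rank one and confined to
a single column of A (default) — the outgoing coupling of electrode k —
or a single row (incoming coupling) via the `structure` flag:

    Δ = γ e_kᵀ  (column)    or    Δ = e_k γᵀ  (row).

For a target eigenvalue λ* = σ + iω with |λ*| = 1, λ* is an eigenvalue of
A + γ e_kᵀ exactly when 1 + e_kᵀ(A − λ*I)⁻¹ γ = 0.  Writing r for the
relevant row (column structure) or column (row structure) of the resolvent
(A − λ*I)⁻¹, this is the pair of real linear constraints

    Re(r)ᵀ γ = −1,    Im(r)ᵀ γ = 0,

whose minimum-two-norm solution is closed form, γ = Bᵀ(BBᵀ)⁻¹[−1, 0]ᵀ with
B stacking Re(r)ᵀ over Im(r)ᵀ.  Because Δ is rank one, its spectral norm
equals ‖γ‖₂.  The electrode's raw fragility is the minimum of ‖γ‖₂ over a
grid of target eigenvalues; the grid parametrizes the upper unit semicircle
λ* = e^{iθ}, θ uniform on [0, π], 51 points by default.  The upper half
suffices because A is real (conjugate targets give conjugate γ with equal
norm), and the endpoints are the real targets ±1.

Numerical details that matter:

- **Real targets are a genuinely different problem.**  For real λ* the
  placement condition is a single constraint, and its minimum is *not* the
  ω → 0 limit of the two-constraint problem.  Grid angles within 1e-12 of
  the real axis are therefore snapped to exactly ±1 and solved with the
  one-constraint formula γ = −Re(r)/‖Re(r)‖².  Without the snap, floating-
  point residue (sin π ≈ 1e-16) produces wildly non-minimal solutions.
- If λ* is already an eigenvalue of A (within 1e-10), the minimum is the
  zero perturbation.
- If Re(r) and Im(r) are nearly collinear (relative determinant below
  1e-12), the two-constraint system is degenerate and the one-constraint
  solution is used with a warning.
- A numerically singular resolvent without an exact eigenvalue match falls
  back to a pseudo-inverse solve with a warning.

### Normalization and the fragility matrix

Within each window the M raw norms are reverse-scaled,

    f_i = (max_j raw_j − raw_i) / max_j raw_j,

so the hardest-to-destabilize electrode maps to exactly 0 and easier ones
toward 1.  Stacking windows gives the M×W fragility matrix in [0, 1].
Normalization is per window by default (each window's values are relative
to that window's own maximum); a global-maximum variant is available via
`normalize="global"`.  Raw norms are always retained alongside the
normalized matrix, because per-window normalization discards the absolute
scale that analyses such as penalty-sensitivity comparisons need.
An all-zero raw column (every electrode trivially destabilizing) is
degenerate and maps to all zeros with a warning.

### SOZ ranking

`estimate_soz` aggregates each electrode's fragility across windows (mean
by default; median/max/min available), ranks electrodes by the aggregate,
and selects the top N = max(1, round(proportion × M)) with
round-half-away-from-zero and a default proportion of 10%.  Ties keep input
electrode order.  An optional window-index range restricts aggregation,
e.g. to post-onset windows; the synthetic validation uses that restriction
because (as in clinical fragility maps) the SOZ/non-SOZ separation emerges
only after onset, while pre-onset windows reflect baseline network
structure.

## Preprocessing

Butterworth bandpass (default 0.5–150 Hz, order 4) and an IIR notch
(default 60 Hz, Q = 30; set 50 Hz for European line noise), both applied
forward-backward (zero phase) so clinically annotated onset times are not
smeared by group delay.  Filtering is always an explicit step; the
fragility computation never filters implicitly.  Resampling is polyphase
with an anti-aliasing low-pass at the new Nyquist; cropping uses half-open
intervals [start, end) on the sample grid so adjacent crops tile without
duplication.  Time is anchored to seizure onset = 0 s.

## The synthetic seizure generator

The generator exists so that every pipeline stage can be validated against
a known ground truth without clinical data.  It simulates piecewise-
stationary linear network dynamics

    x(t+1) = A x(t) + ε,   ε ~ N(0, noise_sd² I),

switching from a baseline network A_pre (random dense, spectral radius
0.85) to an ictal network A_ictal (spectral radius 0.99) at onset.
Defaults: 12 electrodes, 500 Hz, 2 s before + 2 s after onset, 20 µV
process noise, planted fragile nodes {3, 7}.  Amplitudes are clipped at
±2000 µV, and a trajectory pinned at the clip for >10% of samples is
rejected as explosive.

A_ictal is derived from A_pre by injecting a rank-one excitatory mode
(coupling_boost − 1)·ρ(A_pre)·wwᵀ, where w is the unit vector spread
uniformly over the planted nodes, then rescaling to the ictal radius —
seizure onset as runaway recurrent excitation within the onset zone.  For
boost well above 1 the dominant near-unit mode of A_ictal is w itself, so
*every* planted node loads on it and the planted set is exactly the
ground-truth fragile set.  (A simpler scheme that only rescales the planted
nodes' rows was evaluated and rejected: whenever the planted block is
near-triangular, one planted node hogs the dominant mode and the ground
truth is only partially valid, no matter how large the boost.)  The default
boost of 5 sits comfortably in the regime where the planted mode dominates
in every draw tested.

The generator is deliberately *inside* the model class the method assumes,
so parameter recovery tests the pipeline rather than model mismatch; an
optional tanh saturation provides a mild mismatch variant.  It does not
emulate 1/f spectra, line noise, artifacts, electrode geometry, or
biophysical seizure dynamics — passing recovery tests therefore shows the
chain "window fits → perturbation minima → normalization → ranking" is
correct and identifiable under its own assumptions, not that the method
localizes clinical SOZs.

## Validation battery and problem sizes

The test suite and `scripts/acceptance.py` recompute, from scratch:

- closed-form perturbation minima against an independent SLSQP minimizer of
  ‖γ‖² under the determinant constraint det(A + Δ − λ*I) = 0 (built first
  as the oracle; the constraint set is affine, so the problem is convex and
  any feasible optimum is global) — to 1e-4 relative, on random stable
  systems of size 4–8 over 11 targets, every electrode;
- eigenvalue placement of every returned perturbation (within 1e-8);
- ridge fits against the explicit normal-equation inverse (1e-10 relative);
- the adaptive-λ contract on constructed windows that are unstable at 1e-4
  but small enough in amplitude for λ ≤ 10 to stabilize;
- planted-SOZ recovery over 50 generator seeds (both planted nodes in the
  post-onset top-2, and at least one);
- the penalty-sensitivity trend (mean raw perturbation norm non-decreasing
  over λ ∈ {1e-4, 1e-3, 1e-2}, top-2 set unchanged);
- determinism (parallel ≡ serial bitwise; manifest re-runs byte-identical);
- container properties over ≥500 randomized cases (subsetting consistency,
  half-open crop arithmetic, duration-preserving resampling, HDF5
  round-trips).

Problem sizes (25 oracle systems in the script, 100 in the test suite; 50
recovery seeds) are the package's chosen validation scale; the whole
battery runs in well under a minute apart from the oracle sweep.

## Known limitations

- The ω discretization, perturbation structure (row vs column), and
  per-window vs global normalization vary across fragility implementations
  in the literature; all three are exposed as parameters, and the defaults
  (51-point upper-semicircle grid, column structure, per-window
  normalization) are one defensible choice, not a canonical one.
- Fragility of a window whose fit is unstable even at λ = 10 is
  ill-defined; such windows are computed and flagged, not dropped.
- λ is not cross-validated and no sparse (L1) estimator is provided.
- No re-referencing/montage logic, artifact rejection, or channel-quality
  scoring; recordings are assumed cleaned upstream.
- The EDF reader requires a uniform sampling rate unless the caller opts
  into resample-on-import.
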