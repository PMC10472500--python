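# Methods

This note records the models implemented in `engramfield`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the design decisions taken where the methodology left the
implementation genuinely open.

## Neural field model

The state variable is the mean transmembrane potential `V(x, t)` of an
ensemble occupying a 1-D cortical patch, sampled at the electrode
positions (default: equally spaced on a 2 mm span). Dynamics:

    dV/dt = -V/tau_X + K (f(V + V0e) - f(0)) + U

- `tau_X` (ms): postsynaptic time constant; default 20 ms.
- `f(h) = 1/(1 + exp(delta (eta - h)))`: sigmoid transfer function with
  gain `delta` (default 1) and half-activation `eta` (default 0).
- `K`: connectivity matrix generated from an isotropic Gaussian profile
  `K[i,j] = A exp(-(x_i - x_j)^2 / 2 w^2)`.
- `U`: deterministic cue input plus white Gaussian noise
  (Euler–Maruyama at the sampling step, default 1 ms).

The baseline rate `f(0)` is subtracted so `V = 0` is the resting fixed
point: the model describes transient fluctuations around baseline, and a
brief input pulse decays back to it (non-Turing regime). Stability is
checked by linearization: all eigenvalues of `-I/tau + f'(0) K` must have
negative real part; the simulator refuses unstable parameterizations and
reports the leading eigenvalue.

**Ephaptic extension.** The boundary potential `V0e = g * B V` is added
inside the transfer function, where `B` is the (linear) bidomain forward
operator evaluated at the electrode positions and `g >= 0` the ephaptic
gain. `g = 0` reproduces the non-ephaptic trajectories bit for bit under
the same seed.

## Field forward models

**Bidomain model.** Intra- and extracellular space are coaxial conductive
cylinders (radius `a`, conductivities `sigma_i`, `sigma_e`); the
extracellular potential at perpendicular distance `y >= a` is computed in
the wavenumber domain through the modified-Bessel kernel `W(k)` and an
FFT pair. `W(0)` is set to 0 by its series limit, so membrane DC offsets
do not radiate — a documented property, not a numerical accident. Only
the inverse-transform-of-forward-transform product enters any result, so
the FFT convention cancels (asserted by a round-trip test). Non-uniform
electrode grids are linearly resampled before the transform. Defaults
`sigma_i/sigma_e = 1`, `a = 0.05 x` patch length: the methodology fixes no
tissue values, and every quantity that matters downstream is either
scale-free or compared within a fixed parameterization.

**Far-field reduction.** At observation distances much larger than `a`,
the potential obeys a relaxation equation with rate `1/tau_EP` and drive
`Z * Lap(V^m)`, `Z = gamma (1/r - L^2/12 r^3 + L^4/80 r^5)`. `gamma`, `r`,
`L` are exposed as free parameters; the expansion is flagged unreliable
for `L/r > 0.5`. The fixed point under constant drive `D` is
`tau_EP * Z * D` (tested to machine precision).

Spatial derivatives use minimal central stencils: `[1, -2, 1]` for the
second derivative, its square for the fourth, central first differences
for odd orders, second-order one-sided formulas at the boundaries. This
choice matters: the span of the even-order stencils over channels equals
the space of symmetric banded connectivity profiles, which is what makes
the model comparison below well-posed.

## GLM reformulation and ReML

The recording is demeaned across trials at matched (channel, time)
samples; the principal axes `H_j` are the spatial derivatives (orders 0..J,
default J = 4) of the across-trial mean potential, and each trial's
deviation is expressed as `Y = sum_j H_j w_j + eps` with per-(channel,
trial) connectivity components `w_j`. Fitting maximizes the Free Energy

    F = -1/2 [ (Y - Hw)' (Y - Hw)/s^2 + n ln s^2 + ln det(I + H'H/s^2) + Z'Z ],
    Z = (s^2 I + H'H)^-1 H' Y

by an EM-style alternation: ridge update `w = Z` given `s^2`, closed-form
residual-variance update of `s^2` given `w`, with step-halving toward the
previous iterate whenever a joint update would decrease `F` — so `F` is
non-decreasing by construction. The ln-determinant Occam factor is
oriented to *penalize* added regressors; with the opposite orientation the
"complexity" term would reward larger models and the model comparison
below would be systematically biased (this was verified empirically during
design). The additive constant is fixed to 0; it cancels in all
comparisons. In the noiseless limit the ridge collapses onto ordinary
least squares and recovers planted weights to < 1e-6.

## Ephaptic vs non-ephaptic model comparison

The two generative models differ only in whether the recurrent drive sees
the boundary potential. `compare_models` therefore regresses, per trial,
the estimated recurrent drive

    D[c, t] = (V[c, t+1] - V[c, t]) / dt + V[c, t] / tau

on the trial's own spatial-derivative axes (non-ephaptic design) versus
the same axes plus the bidomain prediction `B V` as one additional
regressor (ephaptic design). Design choices, each load-bearing:

- **Shared weights across channels** (default): the generating
  connectivity profile is homogeneous and the field-coupling gain is a
  single physical constant, so one weight per regressor is the truth and
  concentrates statistical power; a per-channel mode is available.
- **Interior channels only** (trim = ceil(J/2)): at the patch edges the
  one-sided stencils no longer correspond to a symmetric connectivity row,
  and the residual mismatch would leak into whichever regressor set is
  smoother.
- **Within-trial time demeaning** of target and regressors: removes the
  static cue-input profile, which belongs to neither model.
- **Train/held-out split**: weights and the noise scale are fitted by ReML
  on a seeded half of each angle's trials; each held-out trial is scored
  by its out-of-sample Gaussian log-likelihood minus the per-trial share
  of the training fit's complexity penalty. The per-trial Bayes factor is
  the non-ephaptic minus the ephaptic score (positive = non-ephaptic
  wins); per-angle means with |BF| > 3 decide the winner, and the sign of
  the overall mean defines the `signed_winner` used in recovery
  experiments. The complexity difference is reported separately.

A demeaned-`Y`-on-mean-axes design cannot discriminate the generators —
the across-trial mean, and any regressor computed from it, is removed
from `Y` by construction, while a field regressor computed from the
trial's own data correlates with `Y` under *both* generators — which is
why the comparison targets the increment drive.

## Frozen study conditions

`synthetic.bmc_study_config` defines the recovery experiment: 16 channels
on 2 mm, 200 ms at 1 kHz, 16 trials over two opposite cue angles, kernel
amplitude 0.08 with width 0.12 mm (just inside the stability margin, and
narrow enough that the symmetric-stencil span captures the kernel rows),
noise 0.02, cue amplitude 0.01, ephaptic gain 6 (a ~50% relative
modulation of the trajectories — a modest effect, in keeping with the
small-perturbation character of ephaptic currents). The pipeline defaults
use the same ensemble with 36 trials over six angles, 400 ms, and gain 8
so that per-trial evidence clears the |BF| > 3 decisiveness threshold.
These sizes are deliberately desk-scale (a full in vivo session would be
32 channels x 750 ms x hundreds of trials); all analyses are size-generic.

What the generator does *not* emulate: broadband 1/f background,
measurement/electrode noise distinct from process noise, conduction
delays, spiking, behavioral covariates, or 2-D electrode geometry.
Passing recovery tests therefore show the chain is correct and calibrated
under its own assumptions, not that real LFPs satisfy them.

## Mode dynamics and slaving

The coupled field/activity system in planar-wave coordinates:

    d xi_n/dt  = -xi_n/tau_EP + Z n^2 psi_n
    d psi_n/dt = -psi_n/tau_NA + delta sum_q K_hat[n,q] (psi_q + xi0_q) + U

with `xi0` identified with `xi` (boundary values follow the field modes).
The quasi-steady solution solves `(I - c K_hat) psi = c K_hat xi0` with
`c = delta * tau_NA` — the fixed point of the psi equation as written; a
sometimes-quoted `delta/tau_NA` coefficient coincides with it exactly at
`tau_NA = 1`, the normalization used by all diagnostics here.

The adiabatic diagnostic fixes `tau_NA = 1`, sets `tau_EP` to the
timescale ratio, drives the field by relaxation toward a smooth
Ornstein–Uhlenbeck source with ratio-independent stationary scale
(`sd = 0.05`) — the field must be smooth on the fast timescale for the
quasi-static picture to apply; white kicks on `xi` would impose a
`sqrt(tau_NA/tau_EP)` error floor — plus a small white input on the
activity modes (`sd = 5e-4`) and weak feedback `Z = 1e-3` (kept below the
loop-stability bound at ratio 100). Tracking error falls from ~100% at
ratio 1 to ~3% at ratio 100, strictly monotonically.

**Two-area analysis.** Truncating at two modes per area gives an 8x8
coefficient matrix `M = [[A, B], [C, D]]`, `D = [[E, L], [G, J]]`, with
the mode-2 corner of each area exactly
`[[beta + 1/tau_EP, 4Z], [delta K_hat_22, beta + 1/tau_NA + delta K_hat_22]]`.
The builder's defaults are a template (area-1 analogue of `J`, feedforward
`W` entering the area-2 activity rows); every block is overridable so that
refined cross-coupling entries can be supplied without code changes. The Schur identity `det(M) = det(A - B D^-1 C) det(D)`
holds for any blocks; the three-factor form
`det(M) = det(A) det(E - L J^-1 G) det(J)` additionally requires
one-directional inter-area coupling (`B = 0` or `C = 0`) — exactly the
feedforward engram pair modelled — since only then does the Schur
complement collapse to `A`. The implication "det(M) != 0 and det(J) != 0
imply det(A) != 0" is checked on determinants normalized by the spectral
norm raised to the dimension, threshold 1e-10.

## Spatial Granger causality

Each time point contributes one spatial profile; the spatial "past" runs
left to right by default (orientation is a nuisance choice; a
both-orientations mode averages the two). Strength is
`ln(RSS_restricted/RSS_full)` from nested least squares with an intercept;
the F statistic `(exp(S) - 1)(n - 2p - 1)/p` with `(p, n - 2p - 1)`
degrees of freedom is exact under the Gaussian null, giving calibrated
p-values by construction (verified: type-I error 0.05 +/- 0.02 and KS
uniformity over 1000 replicates). Default lag order `p = 1` — 32 spatial
samples per snapshot leave little room for more — with AIC/BIC/CV
selection available. No multiple-testing correction across snapshots by
default (per-time-point significance is reported raw); Benjamini–Hochberg
can be applied downstream. CVs use the sample standard deviation in
percent of the mean.

## RSA

A condition's pattern is the vectorized upper triangle of the
channels-by-channels correlation matrix over time, averaged over the
condition's trials (the alternative trials-by-trials reading of "time
correlations" is a documented switch away; the channels-over-time choice
is the default because it yields one pattern per condition independent of
trial count). RDMs use 1 − Pearson between condition patterns; deviation
between areas uses 1 − Spearman of the RDMs' upper triangles (no linear
correspondence assumed). The randomization test permutes condition labels
of one RDM — rows and columns together, since permuting rows alone would
break symmetry — with default 10,000 relabelings and the +1-corrected
p-value `(1 + #{null >= observed}) / (1 + n)`, so p is never exactly 0.
With 6 conditions there are 720 distinct relabelings; fewer than 4
conditions triggers a warning in the result. Bootstrap standard errors of
the deviation resample trials within condition (default 100 replicates).

## Numerical choices and edge cases

- Integration is explicit Euler / Euler–Maruyama at the sampling step
  (1 ms against a 20 ms time constant; halving dt changes trajectories
  within the linearization tolerance).
- `Pi = s^2 I + H'H` blocks are solved directly; a non-positive
  determinant raises with a conditioning diagnostic.
- Degenerate inputs fail loudly and early: constant channels in RSA
  patterns, constant masks in window correlations, zero-mean CVs,
  rank-deficient GC designs, unstable ensembles, singular slaved systems
  (resonance `c K_hat` eigenvalue at 1).
- ReML non-convergence is flagged (`converged=False`), not raised.

## Known limitations

- The mapping from fitted connectivity components back to a continuous
  kernel involves an under-determined moment relation; the package stores
  fitted components and the generating kernel separately and does not
  invert it.
- The quantitative link between the bidomain kernel's `y`-dependence and
  the far-field coefficients (`gamma`, `r`, `L`) is not re-derived; they
  are independent parameterizations of near- and far-field regimes.
- The two-area analysis is implemented for two areas; the extension to
  more areas is a direct block generalization but is not provided.
- Equal-prior posterior probabilities are reported alongside Bayes
  factors; |BF| = ln 3 corresponds to ~75%, and no stronger equivalence is
  assumed.
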