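# Methods

## Model and procedure

The package implements a classical density-modification (DM) loop on a
P1 crystal. One cycle is:

1. **Synthesize** a map from the current combined coefficients. The
   first cycle uses the initial experimental map, the centroid synthesis
   m·|F_o|·exp(iφ) of the experimental phase distribution; later cycles
   use the previous cycle's combined coefficients in the selected mode
   (2mF_o−DF_c by default, centroid optionally). F(000) is excluded
   everywhere, so all maps are mean-zero.
2. **Modify** in real space: a Wang-style solvent mask (local mean of
   |ρ| over a sphere, lowest-scoring fraction flagged solvent,
   recomputed every cycle), solvent flattening (solvent voxels set to
   the solvent mean), and histogram matching (monotone rank-preserving
   transform of protein voxels onto a target histogram), in that fixed
   order. A "null" operator that returns the map unchanged is provided
   as a bias stress test.
3. **Invert** the modified map on the same Miller set to obtain model
   structure factors F_c.
4. **Refine the error model.** Within each resolution bin the observed
   amplitude is modelled as acentric Rice: F_o = D·F_c plus complex
   Gaussian noise of variance σ_Δ², and (D, σ_Δ²) maximize the Rice
   likelihood of |F_o| given |F_c|.
5. **Apply β**: D_eff = β·D, with σ_Δ² recomputed so the per-bin second
   moment D²⟨|F_c|²⟩ + σ_Δ² is preserved. β = 1 is the uncorrected
   engine, bit for bit.
6. **Combine phases** (MLHL): the model likelihood contributes
   X·cos(φ−φ_c) with X = 2·D_eff·|F_o||F_c|/σ_Δ², i.e. the vector
   (X cos φ_c, X sin φ_c, 0, 0) is added to the experimental
   Hendrickson–Lattman (HL) coefficients. Centroid phase and figure of
   merit come from quadrature of the HL density.

β itself is estimated by cross-validation before the production run: a
free set (default 5%, random or thin resolution shells) is given zero
map coefficient and excluded from D refinement for a few cycles
(default 5), after which β = cov_free(|F_o|,|F_c|) / cov_work. The
covariances are computed after per-bin linear scaling of |F_c| to
|F_o| (one scale per bin, fit on the working set — the ratio is
invariant to any common scale) with cross moments mean-centred per bin
within each set and then pooled, which removes resolution trends.
Production DM then restarts from the initial experimental map with all
reflections and β held fixed, applied after each cycle's D refinement.

Calibration of the whole pipeline is assessed against ground truth by
the statistical bias ⟨m⟩ − CPEM averaged over data sets (CPEM = mean
cosine of the true phase error), the Pearson correlation of ⟨m⟩ with
CPEM across data sets, and the rms errors of estimating CPEM by ⟨m⟩
directly and through a leave-one-out Nadaraya–Watson kernel regression
(Gaussian kernel, Silverman bandwidth unless set).

## Synthetic data

The generator produces toy crystals whose ground truth is exact:

- **Structure**: point atoms placed uniformly in an orthogonal P1 cell,
  occupancy 1, scattering weights from a light-atom palette
  (6/7/8/16 electrons), isotropic B in 10–30 Å². Structure factors are
  computed by direct summation
  F(h) = Σ w·occ·exp(−B s²/4)·exp(2πi h·x), which doubles as the
  independent oracle for the FFT path.
- **Amplitudes**: |F_o| = |F_true|·(1+ε), ε ~ N(0, 0.05) by default.
- **Experimental phases**: centroid phase = true phase + δ with
  δ ~ von Mises(0, κ). The HL coefficients encode exactly that
  distribution (A = κ cos φ, B = κ sin φ, C = D = 0), so the stored FOM
  I₁(κ)/I₀(κ) equals the expected cosine of the phase error — the
  simulated experimental phasing is *calibrated by construction*. A real
  phasing program's FOMs are typically themselves overestimates; that
  residual source of bias is deliberately absent here, so the residual
  bias after corrected DM measures only what DM itself introduces.

The study ensemble pairs 20 such data sets (200 atoms, 30 Å cube,
d_min = 2.5 Å, ≈3600 reflections, κ evenly spaced in [0.5, 3], i.e.
initial CPEM ≈ 0.24–0.81) run uncorrected and β-corrected (5% random
free set, 5 estimation + 20 production cycles, flatten + histogram
match, solvent fraction 0.5). Sizes were chosen so a full paired
ensemble completes in about two minutes on one CPU while keeping the
free set near 180 reflections, enough for a usable covariance ratio.

What the toy does **not** emulate: crystallographic symmetry and
centric reflections (everything is P1 acentric; the formulas used are
acentric-only, and a centric branch is the natural extension point),
compact protein regions (atoms are scattered uniformly, so the solvent
constraint is weaker than in a real crystal), tabulated form factors,
bulk solvent, anomalous signal, and miscalibrated input FOMs. Passing
tests therefore demonstrate the bias mechanism and its correction, not
performance on real data.

## Parameters that matter

| parameter | default | meaning / rationale |
| --- | --- | --- |
| free fraction | 0.05 | reflections withheld for β estimation |
| estimation cycles | 5 | working-set-only DM cycles before taking the ratio |
| production cycles | 20 | restarted from the initial experimental map |
| solvent fraction | 0.5 | Wang-mask quantile; a user parameter, common practice |
| mask radius | 8 Å | sphere for the local-|ρ| solvent score |
| resolution bins | 8 | equal-count in 1/d², ≥50 reflections each |
| grid spacing | d_min/3 | synthesis sampling, standard practice |
| coefficient mode | 2mF_o−DF_c | suppresses model-error peaks vs centroid |

## Numerical choices

- D is parameterized directly rather than through σ_A (the two are
  interchangeable; direct refinement has fewer moving parts) and is
  clamped to [0, 1.2].
- The per-bin (D, σ_Δ²) fit is a *profiled* likelihood: an EM-style
  fixed point gives the ML σ_Δ² for fixed D (iterating
  σ² ← ⟨|F_o|² + D²|F_c|² − 2D|F_o||F_c|·I₁/I₀(x)⟩), and a bounded 1-D
  search over D minimizes the profile to tolerance 1e−6. D = 0 is
  always a stationary point of the Rice likelihood, so the profile is
  also evaluated there and kept only if it beats the interior optimum;
  flat ridges are tie-broken toward smaller D by a negligible penalty.
  Bins where |F_o| is proportional to |F_c| to machine precision (null
  modification) short-circuit to the closed-form slope.
- Phase quadrature uses a fixed 360-point uniform grid; the periodic
  trapezoid rule is exponentially accurate for HL densities, and the
  model concentration X is clamped at 200 (FOM 0.9975 there), below
  which the 360-point grid agrees with a 10⁵-point grid to well under
  1e−6. σ_Δ² carries a relative floor of 1e−6 per bin.
- The imaginary part of the observed/model covariance is omitted (small
  against the real part and averaging out over many reflections).
- The map transforms use the convention ρ(x) = Σ_hemi Re[F e^{2πi h·x}]
  with inversion normalized so synthesize∘invert is the identity on
  band-limited maps; Miller indices must stay inside the grid Nyquist
  limit and grids finer than d_min/3 are enforced.
- A non-positive estimated covariance ratio (possible under null
  modification, where the free-set model signal is exactly zero) is
  floored at β = 1e−6 rather than raised as an error: the meaning — the
  model carries no independent information — is well defined, and the
  raw covariances are preserved in the estimate.
- The target histogram for matching is taken from the true map's
  protein region when ground truth is available; otherwise a
  constructed standardized-gamma default stands in for a library
  histogram (it is synthetic, not derived from deposited structures).

## Design decisions taken where the design was open

- Whether the stage-1 estimation uses centroid or 2mF_o−DF_c
  coefficients: the same mode as production, for strict comparability.
- Covariances in the β ratio are mean-centred (per bin, per set) rather
  than raw second moments; raw moments would be dominated by the mean
  amplitude profile rather than by co-fluctuation.
- A single global β, not per-bin: the free set is too small to support
  per-bin ratios, and the correction is used as a scalar.
- The solvent mask is recomputed every cycle from the current map.
- Map correlations are computed over the full cell without masking.
- Free reflections are excluded *completely* during estimation (zero
  coefficient); filling them with experimental-phase values would
  re-couple the sets and defeat the cross-validation.

## Known limitations

- P1 acentric-only; no NCS averaging, no γ correction (the uncorrected
  baseline is therefore more model-biased than production programs that
  layer γ correction under 2mF_o−DF_c synthesis — in particular,
  high-quality starting maps benefit visibly from β correction here,
  where a γ-corrected program would be near-neutral).
- β estimates from free sets much below ~100 reflections are noisy and
  can collapse to the floor; the selector warns.
- The Rice D estimate from amplitudes alone has a null sampling scale
  of order n^(−1/4) per bin, so per-bin D values in weak-signal bins
  scatter accordingly.
- Real-data input paths (text/MTZ) carry only what the format stores;
  the reconstructed "true" structure factor uses the observed amplitude
  with the stored true phase and is meant for synthetic round trips,
  not for real data.
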