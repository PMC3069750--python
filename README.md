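# betadm

Cross-validated **β correction** for bias reduction in classical
density modification of crystallographic electron-density maps, built
around a compact, fully self-contained density-modification engine with
maximum-likelihood phase combination and toy P1 crystals with known
ground truth.

## The problem

Classical density modification (DM) improves an experimentally phased
electron-density map by imposing real-space expectations — a flat
solvent region, a protein-like density histogram — and then recombining
the modified map's phases with the original experimental phase
probabilities. The likelihood machinery that weights the modified model
needs the covariance between the observed and model structure-factor
amplitudes, ⟨|F_o||F_c|⟩, scaled by a Luzzati error parameter *D*. But
the modified map is *derived from* the observations, so that covariance
is artificially inflated: *D* refines too high, the modified phases are
over-trusted, and the resulting figures of merit (FOM, *m*) badly
overestimate the true phase quality. In the extreme "null" modification
(the map is returned unchanged), FOMs race toward 1 while the phases
never improve at all.

The β correction estimates the inflation by cross-validation. A small
free set (5% of reflections) is completely excluded from a few cycles
of DM; because the model has never seen those reflections, their
covariance with the observations is honest. The correction factor is

    β = cov_free(|F_o|, |F_c|) / cov_work(|F_o|, |F_c|),

and production DM then runs on **all** data with the per-bin effective
Luzzati parameter D_eff = β·D (applied after each cycle's *D*
refinement, with the variance term σ_Δ² recomputed to preserve the
per-bin second moments). Phase combination is MLHL: the model
contributes exp(X cos(φ − φ_c)) with X = 2·D_eff·|F_o||F_c|/σ_Δ², added
to the experimental Hendrickson–Lattman coefficients.

Calibration is measured against ground truth by the **statistical
bias**, the ensemble average of ⟨m⟩ − CPEM, where CPEM is the mean
cosine of the true phase error of a data set.

## Who this is for

Methods developers and students of crystallographic phase improvement
who want a transparent, dependency-light reimplementation of β-corrected
classical DM with exact synthetic ground truth — not a replacement for
production programs on real data (no symmetry beyond P1, no NCS
averaging, no γ correction, no anomalous-data likelihoods).

## Worked example

Simulate a 200-atom toy crystal in a 30 Å P1 cube at 2.5 Å with von
Mises phase errors (κ = 1.5, so the true mean cosine of the phase error
is I₁(1.5)/I₀(1.5) ≈ 0.60), then run 20 cycles of solvent flattening and
histogram matching without correction:

```sh
$ betadm simulate --atoms 200 --cell 30,30,30 --dmin 2.5 \
    --kappa 1.5 --noise 0.05 --seed 42 -o toy.txt
wrote 3576 reflections to toy.txt

$ betadm dm --in toy.txt --cycles 20
 cycle  mean_fom     cpem   map_cc   D_mean  beta_used
     1  0.733809 0.635929 0.689882 1.199999        1.0
     2  0.827745 0.648998 0.727300 0.917928        1.0
   ...
    20  0.927224 0.542759 0.682183 1.026324        1.0
```

The FOM climbs to 0.93 while the true phase quality (CPEM) *drops* to
0.54 — a statistical bias of 0.38, plus genuine map degradation from
over-trusting the model. With β correction:

```sh
$ betadm correct --in toy.txt --free-fraction 0.05 --est-cycles 5 \
    --cycles 20 --report report.json
beta = 0.1533 (cov_free=222, cov_work=1449); final <m> = 0.6335
```

The free set reveals that only ~15% of the working-set covariance is
real. The corrected run finishes at ⟨m⟩ = 0.634 against CPEM = 0.611 —
the FOM is now an honest estimate of phase quality (bias 0.02), and the
final map correlation with the true map is 0.653 versus 0.682 for the
uncorrected run, which peaked at 0.727 in cycle 2 and then decayed as
model bias accumulated.

The same machinery is available as a library:

```python
import betadm as bd

config = bd.EnsembleConfig()                # the 20-data-set study ensemble
plain, corrected = bd.paired_dm_ensemble(config, seed=1)
print(bd.ensemble_summary(plain)["bias"])       # 0.407
print(bd.ensemble_summary(corrected)["bias"])   # 0.015
```

## Layout

| module                 | contents                                                        |
| ---------------------- | --------------------------------------------------------------- |
| `synthetic_crystal`    | toy P1 structures, direct-summation SFs, von Mises phases, I/O  |
| `map_space`            | FFT map synthesis/inversion, map correlation                    |
| `density_modification` | Wang mask, flattening, histogram matching, null op, DM engine   |
| `phase_combination`    | resolution bins, Rice-likelihood *D* refinement, β scaling, MLHL |
| `beta_correction`      | free sets, covariance-ratio β estimation, two-stage protocol    |
| `evaluation`           | bias statistics, Nadaraya–Watson calibration, paired ensembles  |

See `docs/methods.md` for the model, numerical choices and limitations.
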