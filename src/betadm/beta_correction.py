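"""Cross-validated beta estimation and the two-stage corrected protocol.

The model amplitudes produced by density modification are derived from the
observations, so their covariance with |Fo| over the working set is
artificially inflated.  A small free set of reflections, completely
excluded from the modification (zero map coefficient, no part in Luzzati
refinement), provides an honest measurement: beta is the ratio of the
free-set to the working-set covariance between |Fo| and |Fc|,

    beta = cov_free(|Fo|, |Fc|) / cov_work(|Fo|, |Fc|),

estimated after a few working-set-only cycles.  Production density
modification then restarts from the initial experimental map using all
observations, with the effective Luzzati parameter scaled by the fixed
beta each cycle (applied after D refinement against all data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .density_modification import DMOptions, DMTrace, run_dm
from .synthetic_crystal import PhaseDistribution, ReflectionSet

__all__ = [
    "FreeFlags",
    "BetaEstimate",
    "BetaEstimationError",
    "select_free_set",
    "amplitude_covariances",
    "estimate_beta",
    "run_beta_corrected_dm",
]

#: floor applied to a vanishing estimate so downstream likelihoods stay
#: defined; an estimate at the floor means the model carries essentially
#: no independent information about the observations
BETA_FLOOR = 1e-6


class BetaEstimationError(RuntimeError):
    """Raised when the covariance ratio is undefined (cov_work <= 0)."""


@dataclass
class FreeFlags:
    """Cross-validation free-set flags for a reflection set."""

    flags: np.ndarray  # (n,) bool, True = free
    scheme: str  # random | thin_shells
    fraction: float
    seed: int

    @property
    def n_free(self) -> int:
        return int(self.flags.sum())


@dataclass
class BetaEstimate:
    """beta with the free- and working-set covariances it is a ratio of."""

    beta: float
    cov_free: float
    cov_work: float
    n_free: int
    n_work: int
    n_estimation_cycles: int
    estimation_trace: DMTrace | None = None


def select_free_set(
    refl: ReflectionSet,
    fraction: float = 0.05,
    scheme: str = "random",
    seed: int = 0,
    n_shells: int = 100,
) -> FreeFlags:
    """Select cross-validation free reflections.

    random: a fixed-size uniform draw without replacement.  thin_shells:
    the reflections are ordered by 1/d^2 and cut into ``n_shells``
    equal-count shells; whole shells are flagged free at a regular stride
    (seed-dependent offset) until the requested fraction is reached —
    useful when relationships between neighbouring reflections (e.g. NCS)
    would otherwise couple the free and working sets.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = refl.n
    k = int(round(fraction * n))
    if k < 100:
        warnings.warn(
            f"free set has only {k} reflections; beta estimates may be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    flags = np.zeros(n, dtype=bool)
    if scheme == "random":
        flags[rng.choice(n, size=k, replace=False)] = True
    elif scheme == "thin_shells":
        order = np.argsort(1.0 / refl.d**2, kind="stable")
        shells = np.array_split(order, min(n_shells, n))
        n_sh = len(shells)
        k_sh = max(1, int(round(fraction * n_sh)))
        stride = n_sh / k_sh
        offset = rng.integers(0, max(int(np.floor(stride)), 1))
        picks = (offset + np.floor(np.arange(k_sh) * stride).astype(int)) % n_sh
        for s in picks:
            flags[shells[s]] = True
    else:
        raise ValueError(f"unknown free-set scheme: {scheme!r}")
    return FreeFlags(flags=flags, scheme=scheme, fraction=fraction, seed=seed)


def amplitude_covariances(
    fo: np.ndarray,
    fc_amp: np.ndarray,
    free: np.ndarray,
    bin_id: np.ndarray,
) -> tuple[float, float, int, int]:
    """Free- and working-set covariances of (|Fo|, |Fc|).

    |Fc| is first linearly scaled to |Fo| per resolution bin (one scale per
    bin, fit on the working set, applied to both sets — the ratio of the
    covariances is invariant to this common scale).  Within each set the
    cross moments are mean-centred per bin and then pooled, which removes
    resolution trends from the covariance.
    """
    fo = np.asarray(fo, dtype=float)
    fc_amp = np.asarray(fc_amp, dtype=float)
    free = np.asarray(free, dtype=bool)
    work = ~free
    prods: dict[bool, list[np.ndarray]] = {True: [], False: []}
    for b in np.unique(bin_id):
        in_bin = bin_id == b
        wrk = in_bin & work
        denom = float((fc_amp[wrk] ** 2).sum())
        scale = float((fo[wrk] * fc_amp[wrk]).sum()) / denom if denom > 0 else 1.0
        for is_free in (True, False):
            sel = in_bin & (free if is_free else work)
            if sel.sum() < 2:
                continue
            x = fo[sel]
            y = fc_amp[sel] * scale
            prods[is_free].append((x - x.mean()) * (y - y.mean()))
    if not prods[False]:
        raise BetaEstimationError("no working-set reflections for covariance")
    cov_work = float(np.concatenate(prods[False]).mean())
    cov_free = float(np.concatenate(prods[True]).mean()) if prods[True] else 0.0
    return cov_free, cov_work, int(free.sum()), int(work.sum())


def estimate_beta(
    refl: ReflectionSet,
    phases: PhaseDistribution,
    flags: FreeFlags,
    options: DMOptions,
    n_cycles: int = 5,
) -> BetaEstimate:
    """Estimate beta by working-set-only density modification.

    Runs ``n_cycles`` cycles with free reflections excluded from map
    synthesis and Luzzati refinement, then takes the ratio of the free- to
    working-set covariance between |Fo| and the final-cycle |Fc|.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    work_refl = refl.copy()
    work_refl.free = flags.flags.copy()
    est_options = replace(
        options, n_cycles=n_cycles, exclude_free=True, beta=None
    )
    trace = run_dm(work_refl, phases, est_options)
    cov_free, cov_work, n_free, n_work = amplitude_covariances(
        work_refl.fo, np.abs(trace.final_fc), flags.flags, trace.binning.bin_id
    )
    if cov_work <= 0:
        raise BetaEstimationError(
            f"working-set covariance is not positive ({cov_work:.3g})"
        )
    beta = max(cov_free, 0.0) / cov_work
    beta = max(beta, BETA_FLOOR)
    return BetaEstimate(
        beta=beta,
        cov_free=cov_free,
        cov_work=cov_work,
        n_free=n_free,
        n_work=n_work,
        n_estimation_cycles=n_cycles,
        estimation_trace=trace,
    )


def run_beta_corrected_dm(
    refl: ReflectionSet,
    phases: PhaseDistribution,
    options: DMOptions,
    free_fraction: float = 0.05,
    free_scheme: str = "random",
    seed: int = 0,
    est_cycles: int = 5,
    flags: FreeFlags | None = None,
    beta_override: float | None = None,
) -> tuple[DMTrace, BetaEstimate]:
    """Two-stage beta-corrected density modification.

    Stage 1 selects a free set and estimates beta from ``est_cycles``
    working-set-only cycles starting at the initial experimental map.
    Stage 2 restarts from the same initial experimental map and runs
    ``options.n_cycles`` production cycles using all reflections with beta
    fixed at its estimate (applied after Luzzati refinement each cycle).
    ``beta_override`` replaces the estimate in stage 2 (override 1.0
    reproduces the uncorrected engine exactly).
    """
    if flags is None:
        flags = select_free_set(refl, free_fraction, free_scheme, seed)
    estimate = estimate_beta(refl, phases, flags, options, est_cycles)
    beta = estimate.beta if beta_override is None else float(beta_override)
    prod_options = replace(options, beta=beta, exclude_free=False)
    trace = run_dm(refl, phases, prod_options)
    return trace, estimate
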