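"""Toy-crystal generator with known ground truth.

Produces small P1 point-atom structures, their exact structure factors by
direct summation, simulated experimental phase information (von Mises phase
errors encoded as unimodal Hendrickson-Lattman coefficients with a
calibrated figure of merit), and Gaussian amplitude noise.  These stand in
for real experimentally phased data sets: every quantity a bias study needs
(true phases, true amplitudes) is available exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "UnitCell",
    "AtomModel",
    "ReflectionSet",
    "PhaseDistribution",
    "generate_toy_structure",
    "direct_structure_factors",
    "simulate_experimental_phases",
    "add_amplitude_noise",
    "expected_fom",
    "wrap_phase",
    "write_reflections",
    "read_reflections",
    "write_mtz",
]

# Scattering-weight palette: roughly C, N, O, S electron counts.
_WEIGHT_PALETTE = np.array([6.0, 7.0, 8.0, 16.0])


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-pi, pi]."""
    out = np.angle(np.exp(1j * np.asarray(phi, dtype=float)))
    return np.where(out == -np.pi, np.pi, out) if np.ndim(out) else (
        np.pi if out == -np.pi else float(out)
    )


def expected_fom(kappa: np.ndarray | float) -> np.ndarray | float:
    """Figure of merit of a von Mises phase distribution, I1(kappa)/I0(kappa).

    Uses exponentially scaled Bessel functions so large concentrations do
    not overflow.
    """
    k = np.asarray(kappa, dtype=float)
    out = special.i1e(k) / special.i0e(k)
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class UnitCell:
    """Orthogonal P1 unit cell (angles fixed at 90 degrees in v1)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    spacegroup: str = "P1"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if (self.alpha, self.beta, self.gamma) != (90.0, 90.0, 90.0):
            raise ValueError("only orthogonal cells are supported")

    @property
    def volume(self) -> float:
        return self.a * self.b * self.c

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Angstrom) of Miller indices for an orthogonal cell."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = (hkl / self.lengths) ** 2
        return 1.0 / np.sqrt(inv_d2.sum(axis=1))


@dataclass
class AtomModel:
    """Point atoms with Gaussian B-factor falloff in a P1 cell."""

    xyz: np.ndarray  # (n, 3) fractional coordinates in [0, 1)
    b_iso: np.ndarray  # (n,) isotropic B in A^2
    occupancy: np.ndarray  # (n,) in (0, 1]
    weight: np.ndarray  # (n,) scattering weight >= 0
    cell: UnitCell

    def __post_init__(self) -> None:
        self.xyz = np.mod(np.asarray(self.xyz, dtype=float), 1.0)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3 or len(self.xyz) == 0:
            raise ValueError("model needs at least one atom with 3 coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)


@dataclass
class ReflectionSet:
    """One hemisphere of unique reflections for a P1 toy crystal.

    Friedel mates are implied: only indices with h > 0, or h = 0 and k > 0,
    or h = k = 0 and l > 0 are stored.
    """

    hkl: np.ndarray  # (n, 3) int
    d: np.ndarray  # (n,) resolution in Angstrom
    fo: np.ndarray  # (n,) observed amplitude
    sigfo: np.ndarray  # (n,) amplitude sigma
    cell: UnitCell
    f_true: np.ndarray | None = None  # (n,) complex ground-truth SF
    f_c: np.ndarray | None = None  # (n,) complex model SF
    free: np.ndarray = field(default=None)  # type: ignore[assignment]
    bin_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int)
        n = len(self.hkl)
        if self.free is None:
            self.free = np.zeros(n, dtype=bool)
        if self.bin_id is None:
            self.bin_id = np.zeros(n, dtype=int)

    @property
    def n(self) -> int:
        return len(self.hkl)

    @property
    def phi_true(self) -> np.ndarray:
        if self.f_true is None:
            raise ValueError("no ground-truth structure factors present")
        return wrap_phase(np.angle(self.f_true))

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            hkl=self.hkl.copy(),
            d=self.d.copy(),
            fo=self.fo.copy(),
            sigfo=self.sigfo.copy(),
            cell=self.cell,
            f_true=None if self.f_true is None else self.f_true.copy(),
            f_c=None if self.f_c is None else self.f_c.copy(),
            free=self.free.copy(),
            bin_id=self.bin_id.copy(),
        )


@dataclass
class PhaseDistribution:
    """Per-reflection unimodal phase probability information.

    The density over the phase phi is proportional to
    exp(A cos phi + B sin phi + C cos 2phi + D sin 2phi); ``phase`` is the
    centroid phase and ``fom`` the modulus of the expected unit phasor.
    """

    hl: np.ndarray  # (n, 4) coefficients A, B, C, D
    phase: np.ndarray  # (n,) centroid phase in (-pi, pi]
    fom: np.ndarray  # (n,) figure of merit in [0, 1]

    @property
    def n(self) -> int:
        return len(self.hl)

    def copy(self) -> "PhaseDistribution":
        return PhaseDistribution(self.hl.copy(), self.phase.copy(), self.fom.copy())


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_toy_structure(
    n_atoms: int,
    cell: UnitCell,
    b_range: tuple[float, float] = (10.0, 30.0),
    seed: int = 0,
) -> AtomModel:
    """Place ``n_atoms`` point atoms uniformly in the cell.

    Occupancies are 1.0; scattering weights are drawn from a small fixed
    palette of light-atom electron counts; B factors are uniform in
    ``b_range``.  Deterministic for a fixed seed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    xyz = rng.random((n_atoms, 3))
    b_iso = rng.uniform(b_range[0], b_range[1], size=n_atoms)
    weight = rng.choice(_WEIGHT_PALETTE, size=n_atoms)
    occ = np.ones(n_atoms)
    return AtomModel(xyz=xyz, b_iso=b_iso, occupancy=occ, weight=weight, cell=cell)


def _hemisphere_indices(cell: UnitCell, d_min: float) -> np.ndarray:
    """All unique-hemisphere Miller indices with d >= d_min, excluding 000."""
    hmax = int(np.floor(cell.a / d_min))
    kmax = int(np.floor(cell.b / d_min))
    lmax = int(np.floor(cell.c / d_min))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    # hemisphere: first nonzero index positive
    hemi = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)
    )
    hkl = hkl[hemi]
    d = cell.d_spacing(hkl)
    keep = d >= d_min
    hkl, d = hkl[keep], d[keep]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def direct_structure_factors(model: AtomModel, d_min: float) -> ReflectionSet:
    """Exact structure factors by direct summation over all atoms.

    F(h) = sum_j w_j occ_j exp(-B_j s^2 / 4) exp(2 pi i h.x_j), s = 1/d.
    Serves as the ground truth (and as the oracle for the FFT path).
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if model.n_atoms == 0:
        raise ValueError("empty atom model")
    cell = model.cell
    hkl = _hemisphere_indices(cell, d_min)
    d = cell.d_spacing(hkl)
    s2 = 1.0 / d**2
    # (n_refl, n_atoms) phase matrix; chunk to bound memory on big sets
    f = np.zeros(len(hkl), dtype=complex)
    amp_atom = model.weight * model.occupancy  # (n_atoms,)
    chunk = max(1, 2_000_000 // max(model.n_atoms, 1))
    for start in range(0, len(hkl), chunk):
        sl = slice(start, start + chunk)
        phase = 2.0 * np.pi * hkl[sl] @ model.xyz.T
        falloff = np.exp(-np.outer(s2[sl], model.b_iso) / 4.0)
        f[sl] = (amp_atom * falloff * np.exp(1j * phase)).sum(axis=1)
    fo = np.abs(f)
    sigfo = np.full_like(fo, 1e-6 * max(fo.mean(), 1.0))
    return ReflectionSet(hkl=hkl, d=d, fo=fo, sigfo=sigfo, cell=cell, f_true=f)


def simulate_experimental_phases(
    refl: ReflectionSet, kappa: float, seed: int = 0
) -> PhaseDistribution:
    """Simulate experimental phasing with von Mises phase errors.

    Each centroid phase is the true phase plus an error drawn from a
    von Mises distribution with concentration ``kappa``.  The HL
    coefficients encode exactly that distribution (A = kappa cos phi_cen,
    B = kappa sin phi_cen, C = D = 0) so the stored figure of merit
    I1(kappa)/I0(kappa) is calibrated by construction: it equals the
    expected cosine of the phase error.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if refl.f_true is None:
        raise ValueError("reflection set has no ground-truth structure factors")
    rng = np.random.default_rng(seed)
    delta = rng.vonmises(0.0, kappa, size=refl.n) if kappa > 0 else rng.uniform(
        -np.pi, np.pi, size=refl.n
    )
    phase = wrap_phase(refl.phi_true + delta)
    hl = np.zeros((refl.n, 4))
    hl[:, 0] = kappa * np.cos(phase)
    hl[:, 1] = kappa * np.sin(phase)
    fom = np.full(refl.n, expected_fom(kappa))
    return PhaseDistribution(hl=hl, phase=phase, fom=fom)


def add_amplitude_noise(
    refl: ReflectionSet, relative_sigma: float, seed: int = 0
) -> ReflectionSet:
    """Multiplicative Gaussian amplitude noise: |Fo| = |F_true| (1 + eps)."""
    if relative_sigma < 0:
        raise ValueError("relative_sigma must be >= 0")
    if refl.f_true is None:
        raise ValueError("reflection set has no ground-truth structure factors")
    out = refl.copy()
    f_true_amp = np.abs(out.f_true)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, relative_sigma, size=out.n) if relative_sigma > 0 else 0.0
    out.fo = f_true_amp * np.maximum(1.0 + eps, 0.01)
    out.sigfo = np.maximum(relative_sigma, 1e-6) * np.maximum(f_true_amp, 1e-12)
    return out


# ---------------------------------------------------------------------------
# Reflection-file I/O
# ---------------------------------------------------------------------------

_COLUMNS = "H K L D FO SIGFO HLA HLB HLC HLD PHITRUE FREE"


def write_reflections(
    path, refl: ReflectionSet, phases: PhaseDistribution
) -> None:
    """Write the columnar text format (one reflection per row).

    PHITRUE is in degrees; it is NaN when no ground truth is present.  The
    cell is recorded on a comment line so the file is self-contained.
    """
    phi_true = (
        np.degrees(refl.phi_true) if refl.f_true is not None
        else np.full(refl.n, np.nan)
    )
    data = np.column_stack(
        [
            refl.hkl,
            refl.d,
            refl.fo,
            refl.sigfo,
            phases.hl,
            phi_true,
            refl.free.astype(int),
        ]
    )
    cell = refl.cell
    header = f"# CELL {cell.a:.6g} {cell.b:.6g} {cell.c:.6g}\n{_COLUMNS}"
    np.savetxt(path, data, header=header, comments="", fmt="%d %d %d" + " %.8g" * 8 + " %d")


def read_reflections(path) -> tuple[ReflectionSet, PhaseDistribution]:
    """Read the columnar text format written by :func:`write_reflections`.

    The true amplitude is not stored in the format, so when PHITRUE is
    present the ground-truth structure factor is reconstructed with the
    observed amplitude: F_true ~= |Fo| exp(i phi_true).
    """
    with open(path) as fh:
        first = fh.readline().split()
    if first[:2] != ["#", "CELL"]:
        raise ValueError("missing '# CELL a b c' header line")
    cell = UnitCell(float(first[2]), float(first[3]), float(first[4]))
    data = np.loadtxt(path, skiprows=2, ndmin=2)
    hkl = data[:, 0:3].astype(int)
    d = data[:, 3]
    fo, sigfo = data[:, 4], data[:, 5]
    hl = data[:, 6:10]
    phi_true = np.radians(data[:, 10])
    free = data[:, 11].astype(bool)
    f_true = None
    if np.isfinite(phi_true).all():
        f_true = fo * np.exp(1j * phi_true)
    refl = ReflectionSet(
        hkl=hkl, d=d, fo=fo, sigfo=sigfo, cell=cell, f_true=f_true, free=free
    )
    # centroid phase and FOM are recomputed from the HL coefficients
    from .phase_combination import hl_centroid_fom

    phase, fom = hl_centroid_fom(hl)
    return refl, PhaseDistribution(hl=hl, phase=phase, fom=fom)


def write_mtz(path, refl: ReflectionSet, phases: PhaseDistribution) -> None:
    """Export to MTZ with FP/SIGFP, HLA..HLD and FreeR_flag columns."""
    import gemmi

    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup("P1")
    cell = refl.cell
    mtz.set_cell_for_all(gemmi.UnitCell(cell.a, cell.b, cell.c, 90, 90, 90))
    mtz.add_dataset("toy")
    mtz.add_column("FP", "F")
    mtz.add_column("SIGFP", "Q")
    for name in ("HLA", "HLB", "HLC", "HLD"):
        mtz.add_column(name, "A")
    mtz.add_column("FreeR_flag", "I")
    data = np.column_stack(
        [refl.hkl, refl.fo, refl.sigfo, phases.hl, refl.free.astype(float)]
    )
    mtz.set_data(data)
    mtz.write_to_file(str(path))
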