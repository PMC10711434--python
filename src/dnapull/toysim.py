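"""Ground-truth generators for testing the estimators end to end.

Three families of synthetic data, all with analytic expectations:

* steered overdamped Langevin dynamics of a single coordinate in a
  harmonic trap dragged at constant rate over a model landscape (flat,
  harmonic or double well), in reduced units with k_B*T = 1 — the
  free-energy difference between trap positions is known in closed form,
  so the Jarzynski estimate can be checked exactly;
* Gaussian terminal-work ensembles, for which the Jarzynski estimate has
  the closed form mu - beta*s^2/2;
* point-group "complexes" and ideal B-DNA duplexes with prescribed
  geometry, as fixtures for the contact-map and groove operations.

The Langevin integrator is plain Euler–Maruyama, which is adequate for
overdamped scalar dynamics provided dt * stiffness / gamma stays well
below one (enforced). Every generator takes an explicit seed and is
bit-for-bit reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .atoms import AtomId
from .colvar import write_colvar
from .contacts import CONTACT_PARAMS, ContactMapSpec, ContactPair, SwitchingParams
from .curves import WorkCurve
from .errors import ToySimError
from .steering import CVSeries
from .structure import Structure, Trajectory

logger = logging.getLogger(__name__)

_STABILITY_LIMIT = 0.1
_DIVERGENCE_BOUND = 1e6

POTENTIALS = ("flat", "harmonic", "double_well")


@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped dynamics on a 1-D model landscape, reduced units.

    potential: 'flat', 'harmonic' (stiffness kappa) or 'double_well'
    (V = barrier * ((x/a)^2 - 1)^2 with well separation 2a). gamma is
    the friction, kt the thermal energy (1 by default), dt the time step
    and seed the generator seed recorded in every output header.
    """

    potential: str = "harmonic"
    kappa: float = 1.0
    barrier: float = 2.0
    well_sep: float = 2.0
    gamma: float = 1.0
    kt: float = 1.0
    dt: float = 1e-3
    n_steps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.potential not in POTENTIALS:
            raise ToySimError(
                f"unknown potential {self.potential!r}; choose from {POTENTIALS}"
            )
        if self.gamma <= 0 or self.kt <= 0 or self.dt <= 0 or self.n_steps < 1:
            raise ToySimError("gamma, kt, dt must be positive; n_steps >= 1")
        if self.potential == "harmonic" and self.kappa <= 0:
            raise ToySimError("harmonic potential needs kappa > 0")
        if self.potential == "double_well" and (
            self.barrier <= 0 or self.well_sep <= 0
        ):
            raise ToySimError("double well needs positive barrier and separation")

    @property
    def curvature(self) -> float:
        """Characteristic stiffness of the landscape (stability check)."""
        if self.potential == "flat":
            return 0.0
        if self.potential == "harmonic":
            return self.kappa
        a = self.well_sep / 2.0
        return 8.0 * self.barrier / a**2  # |V''| at the well bottoms

    def force(self, x: np.ndarray) -> np.ndarray:
        if self.potential == "flat":
            return np.zeros_like(x)
        if self.potential == "harmonic":
            return -self.kappa * x
        a = self.well_sep / 2.0
        return -4.0 * self.barrier * x * ((x / a) ** 2 - 1.0) / a**2


@dataclass(frozen=True)
class ToySchedule:
    """Harmonic trap of stiffness k_trap dragged linearly x0 -> x1."""

    k_trap: float = 10.0
    x0: float = 1.0
    x1: float = -1.0
    n_runs: int = 20

    def __post_init__(self) -> None:
        if self.k_trap <= 0:
            raise ToySimError("trap stiffness must be positive")
        if self.n_runs < 1:
            raise ToySimError("need at least one run")


def _check_stability(spec: LangevinSpec, sched: ToySchedule) -> None:
    stiffness = spec.curvature + sched.k_trap
    if spec.dt * stiffness / spec.gamma >= _STABILITY_LIMIT:
        raise ToySimError(
            f"unstable integration: dt*(kappa+k_trap)/gamma = "
            f"{spec.dt * stiffness / spec.gamma:.3g} must stay below "
            f"{_STABILITY_LIMIT}"
        )


def _equilibrium_start(
    spec: LangevinSpec, sched: ToySchedule, rng: np.random.Generator
) -> np.ndarray:
    """Sample initial positions from equilibrium under V + trap at x0.

    Exact for flat and harmonic landscapes (Gaussian); for the double
    well a short equilibration run from the trap center is used.
    """
    n = sched.n_runs
    if spec.potential == "flat":
        var = spec.kt / sched.k_trap
        return rng.normal(sched.x0, np.sqrt(var), size=n)
    if spec.potential == "harmonic":
        k_tot = spec.kappa + sched.k_trap
        mean = sched.k_trap * sched.x0 / k_tot
        return rng.normal(mean, np.sqrt(spec.kt / k_tot), size=n)
    x = np.full(n, sched.x0)
    sig = np.sqrt(2.0 * spec.kt * spec.dt / spec.gamma)
    for _ in range(2000):
        f = spec.force(x) + sched.k_trap * (sched.x0 - x)
        x = x + spec.dt * f / spec.gamma + sig * rng.normal(size=n)
    return x


def simulate_steered_langevin(
    spec: LangevinSpec,
    sched: ToySchedule,
    record_stride: int = 10,
) -> list[tuple[CVSeries, WorkCurve]]:
    """Drag an ensemble through the landscape; return per-run series + work.

    Euler–Maruyama update x <- x + dt*F/gamma + sqrt(2*kt*dt/gamma)*eta
    with the trap force k_trap*(c(t) - x); the restraint work is
    accumulated per step with exactly the discrete rule the steering
    layer uses, so engine-style and post-hoc accumulation agree up to the
    recording stride. Work curves are in 'kT' units on the normalized
    schedule-progress lambda grid (1 at the start, 0 at the end).
    """
    _check_stability(spec, sched)
    if record_stride < 1:
        raise ToySimError("record stride must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n = sched.n_runs
    x = _equilibrium_start(spec, sched, rng)
    w = np.zeros(n)
    sig = np.sqrt(2.0 * spec.kt * spec.dt / spec.gamma)
    rec_steps = list(range(0, spec.n_steps + 1, record_stride))
    if rec_steps[-1] != spec.n_steps:
        rec_steps.append(spec.n_steps)
    rec_t = np.array([s * spec.dt for s in rec_steps])
    rec_c = np.array(
        [sched.x0 + (sched.x1 - sched.x0) * s / spec.n_steps for s in rec_steps]
    )
    rec_x = np.empty((len(rec_steps), n))
    rec_w = np.empty((len(rec_steps), n))
    rec_x[0] = x
    rec_w[0] = w
    c_prev = sched.x0
    rec_i = 1
    for step in range(1, spec.n_steps + 1):
        f = spec.force(x) + sched.k_trap * (c_prev - x)
        x = x + spec.dt * f / spec.gamma + sig * rng.normal(size=n)
        c_new = sched.x0 + (sched.x1 - sched.x0) * step / spec.n_steps
        w = w + sched.k_trap * (c_new - x) * (c_new - c_prev)
        c_prev = c_new
        if step == rec_steps[rec_i]:
            rec_x[rec_i] = x
            rec_w[rec_i] = w
            rec_i += 1
    if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > _DIVERGENCE_BOUND:
        raise ToySimError(
            "trajectory diverged; reduce dt so that dt*(kappa+k_trap)/gamma "
            f"< {_STABILITY_LIMIT}"
        )
    duration = spec.n_steps * spec.dt
    lam = 1.0 - rec_t / duration
    out = []
    for i in range(n):
        series = CVSeries(times=rec_t, contacts=rec_x[:, i], center=rec_c)
        curve = WorkCurve(
            run_id=f"toy-{spec.potential}-{i:03d}",
            lambda_grid=lam,
            work=rec_w[:, i],
            units="kT",
        )
        out.append((series, curve))
    return out


def sample_equilibrium(
    spec: LangevinSpec,
    n_samples: int,
    n_walkers: int = 100,
    burn_in_steps: int = 2000,
    sample_stride: int = 50,
) -> np.ndarray:
    """Decorrelated equilibrium positions under the bare landscape.

    Runs `n_walkers` unsteered walkers, discards the burn-in, then keeps
    one sample every `sample_stride` steps from each walker until
    `n_samples` positions are collected.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.zeros(n_walkers)
    sig = np.sqrt(2.0 * spec.kt * spec.dt / spec.gamma)
    for _ in range(burn_in_steps):
        x = x + spec.dt * spec.force(x) / spec.gamma + sig * rng.normal(size=n_walkers)
    samples = []
    needed = int(np.ceil(n_samples / n_walkers))
    for _ in range(needed):
        for _ in range(sample_stride):
            x = (
                x
                + spec.dt * spec.force(x) / spec.gamma
                + sig * rng.normal(size=n_walkers)
            )
        samples.append(x.copy())
    return np.concatenate(samples)[:n_samples]


def gaussian_work_ensemble(
    mu: float,
    sd: float,
    n: int,
    grid_points: int = 51,
    seed: int | None = None,
    units: str = "kcal/mol",
) -> list[WorkCurve]:
    """Work curves with Gaussian terminal work N(mu, sd^2).

    Intermediate points rise monotonically along the descending lambda
    grid as w_i(lambda) = W_i * (1 - lambda), so w(1) = 0 and
    w(0) = W_i. The closed-form Jarzynski expectation at the terminal
    point is mu - beta*sd^2/2.
    """
    if sd < 0 or n < 1:
        raise ToySimError("need sd >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    terminal = rng.normal(mu, sd, size=n) if sd > 0 else np.full(n, float(mu))
    lam = np.linspace(1.0, 0.0, grid_points)
    shape = 1.0 - lam
    return [
        WorkCurve(
            run_id=f"gauss-{i:05d}",
            lambda_grid=lam,
            work=terminal[i] * shape,
            units=units,
        )
        for i in range(n)
    ]


def write_toy_colvar(path, series: CVSeries, curve: WorkCurve, seed: int) -> None:
    """Dump one toy run as the COLVAR table the real pipeline reads."""
    write_colvar(
        path,
        {
            "time": series.times,
            "cv": series.contacts,
            "center": series.center,
            "work": curve.work,
        },
        meta={"seed": seed, "units": curve.units},
    )


# ---------------------------------------------------------------------------
# geometric fixtures
# ---------------------------------------------------------------------------


def synthetic_complex(
    n_donors: int = 7,
    n_acceptors: int = 4,
    separation: float = 0.0,
    pair_distance: float = 0.2,
    switching: SwitchingParams = CONTACT_PARAMS,
) -> tuple[Structure, Structure, ContactMapSpec]:
    """Two rigid point groups with every pair at a prescribed distance.

    A deliberately degenerate geometry: all donors sit at one point and
    all acceptors at another, `pair_distance + separation` apart, so the
    total contact count is exactly n_pairs * c(pair_distance +
    separation) — an analytic oracle for the contact-map operations.
    Each acceptor occupies its own synthetic nucleobase (one contact
    point per base holds by construction).
    """
    if n_donors < 1 or n_acceptors < 1:
        raise ToySimError("need at least one donor and one acceptor")
    if pair_distance + separation <= 0:
        raise ToySimError("pair distance plus separation must be positive")
    d = pair_distance + separation
    donor_atoms = tuple(
        AtomId(chain="P", resname="DON", resnum=k + 1, name="ND", serial=k + 1)
        for k in range(n_donors)
    )
    acceptor_atoms = tuple(
        AtomId(
            chain="D",
            resname="DA",
            resnum=i + 1,
            name="N3",
            serial=n_donors + i + 1,
        )
        for i in range(n_acceptors)
    )
    donors = Structure(donor_atoms, np.tile([d, 0.0, 0.0], (n_donors, 1)))
    acceptors = Structure(acceptor_atoms, np.zeros((n_acceptors, 3)))
    pairs = tuple(
        ContactPair(donor=da, acceptor=aa, group=f"D{k + 1}")
        for k, da in enumerate(donor_atoms)
        for aa in acceptor_atoms
    )
    spec = ContactMapSpec(pairs=pairs, switching=switching)
    return donors, acceptors, spec


_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_RESNAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
_MINOR = {"DA": "N3", "DG": "N3", "DT": "O2", "DC": "O2"}
_MAJOR = {"DG": "O6", "DA": "N7", "DT": "O4"}


def ideal_bdna(
    sequence: str = "GCAATATATTGC",
    rise: float = 0.34,
    twist_deg: float = 36.0,
    p_radius: float = 0.94,
    backbone_phase_deg: float = -144.0,
    chains: tuple[str, str] = ("A", "B"),
) -> Structure:
    """A rigid idealized B-DNA duplex built on a cylinder.

    Strand 1 carries `sequence` 5'->3'; strand 2 carries the complement,
    with residue i on strand 1 paired to residue N+1-i on strand 2.
    Phosphates sit on a helix of radius `p_radius` with the given rise
    and twist; the second backbone is rotated by `backbone_phase_deg`
    about the axis, which sets the minor-groove width. Each residue
    carries P (absent on the 5'-terminal residue of each strand, as in
    real DNA), C1' and its per-groove acceptor atoms. Geometry only — no
    stereochemistry beyond what the groove and contact operations need.
    """
    sequence = sequence.upper()
    if any(b not in _COMPLEMENT for b in sequence):
        raise ToySimError(f"non-ACGT base in sequence {sequence!r}")
    n = len(sequence)
    omega = np.deg2rad(twist_deg)
    phase = np.deg2rad(backbone_phase_deg)
    c1, c2 = chains
    atoms: list[AtomId] = []
    coords: list[list[float]] = []
    serial = 1

    def _add(chain, resname, resnum, name, radius, angle, z, element):
        nonlocal serial
        atoms.append(
            AtomId(
                chain=chain,
                resname=resname,
                resnum=resnum,
                name=name,
                serial=serial,
                element=element,
            )
        )
        coords.append(
            [radius * np.cos(angle), radius * np.sin(angle), z]
        )
        serial += 1

    def _residue(chain, resnum, base, angle, z, five_prime):
        resname = _RESNAME[base]
        if not five_prime:
            _add(chain, resname, resnum, "P", p_radius, angle, z, "P")
        _add(chain, resname, resnum, "C1'", 0.58, angle, z, "C")
        _add(chain, resname, resnum, _MINOR[resname], 0.25, angle, z, _MINOR[resname][0])
        major = _MAJOR.get(resname)
        if major:
            _add(chain, resname, resnum, major, 0.30, angle + 0.5, z, major[0])

    for a in range(n):  # strand 1, 5'->3'
        _residue(c1, a + 1, sequence[a], omega * a, rise * a, five_prime=(a == 0))
    for b in range(n):  # strand 2, its own 5'->3'; pairs strand-1 index n-1-b
        a = n - 1 - b
        base = _COMPLEMENT[sequence[a]]
        _residue(c2, b + 1, base, omega * a + phase, rise * a, five_prime=(b == 0))
    return Structure(tuple(atoms), np.asarray(coords))


def make_trajectory(
    structure: Structure,
    n_frames: int = 1,
    jitter: float = 0.0,
    seed: int | None = None,
    frame_spacing_ps: float = 20.0,
) -> Trajectory:
    """Stack copies of a structure into a trajectory, optionally jittered."""
    rng = np.random.default_rng(seed)
    frames = np.repeat(structure.coords[None, :, :], n_frames, axis=0)
    if jitter > 0:
        frames = frames + rng.normal(0.0, jitter, size=frames.shape)
    times = np.arange(n_frames, dtype=float) * frame_spacing_ps
    return Trajectory(structure, frames, times)


def synthetic_dbd_fragment() -> Structure:
    """Synthetic stand-in for an H-NS DNA-binding-domain fragment.

    Not a real protein structure: four residues (R93, Q112, G113, R114)
    with backbone and donor side-chain atoms at arbitrary but distinct
    coordinates, sufficient to exercise the donor-selection conventions
    and contact-map construction.
    """
    residues = [
        (93, "ARG", ["N", "CA", "C", "O", "NE", "NH1", "NH2"]),
        (112, "GLN", ["N", "CA", "C", "O", "NE2"]),
        (113, "GLY", ["N", "CA", "C", "O"]),
        (114, "ARG", ["N", "CA", "C", "O", "NE", "NH1", "NH2"]),
    ]
    atoms: list[AtomId] = []
    coords: list[list[float]] = []
    serial = 1
    for r, (resnum, resname, names) in enumerate(residues):
        for k, name in enumerate(names):
            atoms.append(
                AtomId(
                    chain="P",
                    resname=resname,
                    resnum=resnum,
                    name=name,
                    serial=serial,
                    element=name[0],
                )
            )
            coords.append([2.0 + 0.5 * r, 0.12 * k, 0.1 * (k % 3)])
            serial += 1
    return Structure(tuple(atoms), np.asarray(coords))
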