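"""Steering schedules, start-frame selection, engine input and work.

The dissociation protocol steers the contact count C with a harmonic
restraint whose center moves linearly from the bound reference count to
the dissociated one over the pull duration. This module selects
equilibrium start frames for an ensemble of pulls, emits the steering
input for the engine, and accumulates the restraint work from a recorded
CV time series.

Units: the restraint force constant is given in kJ/mol per squared
contact count; the contact count itself is dimensionless, so accumulated
work comes out in kJ/mol (engine convention). Free energies downstream
are reported in kcal/mol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .contacts import ContactMapSpec, LambdaMap, lambda_of_contacts
from .curves import WorkCurve, accumulate_from_series
from .errors import SteeringError

logger = logging.getLogger(__name__)

ENGINE_DIALECTS = ("plumed",)


@dataclass(frozen=True)
class SteeringSchedule:
    """A linear pull from lambda = 1 to lambda = 0.

    duration_ns: pull length; force_constant: restraint stiffness in
    kJ/mol per squared contact count; n_runs: ensemble size; dt_fs and
    stride control how the emitted engine input converts the schedule to
    steps and how often the CV table is written.
    """

    lambda_map: LambdaMap
    duration_ns: float
    force_constant: float
    n_runs: int = 20
    dt_fs: float = 2.0
    stride: int = 1000

    def __post_init__(self) -> None:
        if not self.duration_ns > 0:
            raise SteeringError(f"duration must be positive, got {self.duration_ns}")
        if not self.force_constant > 0:
            raise SteeringError(
                f"force constant must be positive, got {self.force_constant}"
            )
        if self.n_runs < 1:
            raise SteeringError("need at least one run")
        if not self.dt_fs > 0 or self.stride < 1:
            raise SteeringError("invalid dt or stride")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ns * 1e6 / self.dt_fs))


@dataclass
class CVSeries:
    """Recorded collective-variable history of one steered run."""

    times: np.ndarray  # ps (engine) or reduced time (toy)
    contacts: np.ndarray  # instantaneous total contact count C(t)
    center: np.ndarray  # restraint center c_ref(t)
    groups: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if not (
            self.times.shape == self.contacts.shape == self.center.shape
        ) or self.times.ndim != 1:
            raise SteeringError("times, contacts and center must be equal-length 1-D")
        if self.times.size < 2:
            raise SteeringError("a CV series needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise SteeringError("times must be strictly increasing")
        if self.groups is not None:
            self.groups = {
                g: np.asarray(v, dtype=float) for g, v in self.groups.items()
            }
            for g, v in self.groups.items():
                if v.shape != self.times.shape:
                    raise SteeringError(f"group series {g!r} misaligned")

    def __len__(self) -> int:
        return self.times.size


def select_start_frames(
    series,
    windows: Mapping[str, tuple[float, float]],
    n: int,
    seed: int,
) -> np.ndarray:
    """Randomly pick `n` equilibrium frames inside per-group contact windows.

    `series` maps group label -> per-frame contact counts (a dict of
    arrays or a DataFrame). A frame qualifies only if EVERY window
    condition |C_g - center| <= halfwidth holds simultaneously. The
    sample is uniform without replacement and reproducible under `seed`;
    indices are returned sorted.
    """
    if not windows:
        raise SteeringError("no selection windows given")
    try:
        columns = {g: np.asarray(series[g], dtype=float) for g in windows}
    except KeyError as exc:
        raise SteeringError(f"series lacks group {exc}") from None
    lengths = {v.size for v in columns.values()}
    if len(lengths) != 1:
        raise SteeringError("per-group series have different lengths")
    mask = np.ones(lengths.pop(), dtype=bool)
    for g, (center, halfwidth) in windows.items():
        mask &= np.abs(columns[g] - center) <= halfwidth
    qualifying = np.flatnonzero(mask)
    if qualifying.size < n:
        raise SteeringError(
            f"only {qualifying.size} frames satisfy all windows "
            f"(need {n}); widen the windows or extend the trajectory"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(qualifying, size=n, replace=False))


def emit_steering_input(
    spec: ContactMapSpec,
    schedule: SteeringSchedule,
    dialect: str = "plumed",
) -> str:
    """Deterministic steering-engine input text for `spec` and `schedule`.

    The contact-map CV block reproduces the switching parameters as
    decimal literals exactly as specified, the moving restraint walks the
    center from c_start to c_end over the pull, and a CV table with
    time/CV/center/work columns is printed every `schedule.stride` steps.
    Identical inputs yield byte-identical text.
    """
    if dialect not in ENGINE_DIALECTS:
        raise SteeringError(
            f"unsupported engine dialect {dialect!r}; supported: {ENGINE_DIALECTS}"
        )
    unresolved = [
        str(a)
        for p in spec.pairs
        for a in (p.donor, p.acceptor)
        if a.serial is None
    ]
    if unresolved:
        raise SteeringError(
            "cannot emit engine input: atoms without serial numbers: "
            + ", ".join(sorted(set(unresolved)))
        )
    sw = spec.switching
    switch = (
        f"{{RATIONAL R_0={_lit(sw.r0)} D_0={_lit(sw.d0)} "
        f"NN={sw.nn} MM={sw.mm}}}"
    )
    lines = [
        "# dnapull steering input (dialect: plumed, format v1)",
        f"# lambda map: C={_lit(schedule.lambda_map.c_start)} -> lambda=1.0, "
        f"C={_lit(schedule.lambda_map.c_end)} -> lambda=0.0",
        "cmap: CONTACTMAP ...",
    ]
    for i, pair in enumerate(spec.pairs, start=1):
        lines.append(
            f"   ATOMS{i}={pair.donor.serial},{pair.acceptor.serial} "
            f"SWITCH{i}={switch}"
        )
    lines.append("   SUM")
    lines.append("...")
    k = _lit(schedule.force_constant)
    lines.append("smd: MOVINGRESTRAINT ...")
    lines.append(f"   ARG=cmap")
    lines.append(
        f"   STEP0=0 AT0={_lit(schedule.lambda_map.c_start)} KAPPA0={k}"
    )
    lines.append(
        f"   STEP1={schedule.n_steps} "
        f"AT1={_lit(schedule.lambda_map.c_end)} KAPPA1={k}"
    )
    lines.append("...")
    lines.append(
        f"PRINT ARG=cmap,smd.cntr,smd.work STRIDE={schedule.stride} FILE=COLVAR"
    )
    return "\n".join(lines) + "\n"


def _lit(value: float) -> str:
    """Shortest decimal literal that round-trips the float exactly."""
    return repr(float(value))


def accumulate_work(
    cv: CVSeries,
    schedule: SteeringSchedule | None = None,
    *,
    force_constant: float | None = None,
    lambda_map: LambdaMap | None = None,
    run_id: str = "run",
    units: str = "kJ/mol",
) -> WorkCurve:
    """Accumulate restraint work from a CV series onto the lambda grid.

    Work is attributed to the restraint-center grid (lambda of c_ref),
    not to the instantaneous contact count, so every run in an ensemble
    shares the same lambda axis by construction. The center must move
    strictly monotonically; a stalled or reversing schedule is an error.
    """
    if schedule is not None:
        force_constant = schedule.force_constant
        lambda_map = schedule.lambda_map
    if force_constant is None:
        raise SteeringError("a force constant is required to accumulate work")
    dc = np.diff(cv.center)
    if not (np.all(dc < 0) or np.all(dc > 0)):
        raise SteeringError(
            "restraint center is not strictly monotone; cannot attribute "
            "work to a lambda grid"
        )
    work = accumulate_from_series(cv.contacts, cv.center, force_constant)
    if lambda_map is not None:
        lam = lambda_of_contacts(cv.center, lambda_map)
        if lam[0] < lam[-1]:
            raise SteeringError(
                "restraint center moves from low to high lambda; steering is "
                "defined from the bound (lambda=1) toward the dissociated state"
            )
    else:
        # normalized progress: first center -> 1, last center -> 0
        lam = (cv.center - cv.center[-1]) / (cv.center[0] - cv.center[-1])
    groups = None
    if cv.groups is not None:
        groups = {g: v.copy() for g, v in cv.groups.items()}
    return WorkCurve(
        run_id=run_id,
        lambda_grid=lam,
        work=work,
        units=units,
        groups=groups,
    )
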