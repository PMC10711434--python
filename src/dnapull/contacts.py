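"""Contact-map collective variables and the normalized steering coordinate.

The central descriptor of protein-DNA binding used here is a smoothed
contact count between hydrogen-bond donors on the protein and one
hydrogen-bond acceptor per DNA nucleobase. Each donor-acceptor pair at
distance r contributes a weight

    c(r) = 1                                     if r < d0
    c(r) = (1 - x**nn) / (1 - x**mm),  x = (r - d0)/r0,   otherwise

which is 1 at hydrogen-bond distance and decays to 0 for mm > nn. Two
parameter sets matter in practice: a rational-decay set (r0=0.4 nm,
d0=0.25 nm, nn=2, mm=4) that discriminates binding modes, and a
near-linear set (r0=3.0 nm, d0=0.3 nm, nn=1, mm=12) used while pulling so
that every contact is displaced at a constant rate.

Summing the weights over all pairs gives the contact count C; restricting
the sum to the pairs of one donor group (e.g. the Q112 side chain) gives
per-donor counts whose decomposition is exact. The steering coordinate
lambda is an affine renormalization of C between two reference counts
(fully-inserted state -> 1, backbone-bound state -> 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .atoms import AtomId
from .errors import ContactMapError

if TYPE_CHECKING:  # pragma: no cover
    from .structure import Structure, Trajectory

logger = logging.getLogger(__name__)

# Relative half-width around x = 1 inside which the analytic limit nn/mm is
# substituted for the 0/0 rational form (catastrophic cancellation guard).
_X_LIMIT_TOL = 1e-6


@dataclass(frozen=True)
class SwitchingParams:
    """Parameters of the rational switching function.

    r0, d0 in nm; integer exponents with mm > nn >= 1 so that the weight
    decays to zero at large separation.
    """

    r0: float
    d0: float
    nn: int
    mm: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r0) and self.r0 > 0):
            raise ContactMapError(f"r0 must be a positive length, got {self.r0}")
        if not (np.isfinite(self.d0) and self.d0 >= 0):
            raise ContactMapError(f"d0 must be a non-negative length, got {self.d0}")
        if int(self.nn) != self.nn or int(self.mm) != self.mm:
            raise ContactMapError("nn and mm must be integers")
        if not self.mm > self.nn >= 1:
            raise ContactMapError(
                f"need mm > nn >= 1 for decay to zero, got nn={self.nn}, mm={self.mm}"
            )


#: Rational-decay parameters used to *count* contacts and tell binding
#: modes apart (hydrogen-bond distances weigh 1, 0.7 nm weighs 0.5).
CONTACT_PARAMS = SwitchingParams(r0=0.4, d0=0.25, nn=2, mm=4)

#: Near-linear parameters used while *steering*, so each contact is
#: displaced at an approximately constant rate along the pull.
STEER_PARAMS = SwitchingParams(r0=3.0, d0=0.3, nn=1, mm=12)


@dataclass(frozen=True)
class ContactPair:
    """One donor-acceptor atom pair belonging to a donor group."""

    donor: AtomId
    acceptor: AtomId
    group: str

    def __post_init__(self) -> None:
        if self.donor.same_atom(self.acceptor):
            raise ContactMapError(f"donor and acceptor are the same atom: {self.donor}")


@dataclass(frozen=True)
class LambdaMap:
    """Affine map from contact counts to the steering coordinate lambda.

    `c_start` maps to lambda = 1 (bound, fully inserted); `c_end` maps to
    lambda = 0 (dissociated from the groove, backbone-bound).
    """

    c_start: float
    c_end: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c_start) and np.isfinite(self.c_end)):
            raise ContactMapError("lambda map endpoints must be finite")
        if not self.c_start > self.c_end:
            raise ContactMapError(
                f"need c_start > c_end, got {self.c_start} and {self.c_end}"
            )


#: The steering window used for the H-NS systems: pull from 108 to 65
#: contacts of the near-linear map.
HNS_LAMBDA = LambdaMap(c_start=108.0, c_end=65.0)


@dataclass(frozen=True)
class ContactMapSpec:
    """A full contact-map definition: pairs, grouping and switching."""

    pairs: tuple[ContactPair, ...]
    switching: SwitchingParams
    _groups: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pairs = tuple(self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if not pairs:
            raise ContactMapError("contact map must contain at least one pair")
        groups: dict[str, list[ContactPair]] = {}
        for p in pairs:
            groups.setdefault(p.group, []).append(p)
        # one acceptor atom per nucleobase: no two pairs may address the
        # same base through different atoms
        base_atom: dict[tuple[str, int], str] = {}
        for p in pairs:
            base = (p.acceptor.chain, p.acceptor.resnum)
            prev = base_atom.setdefault(base, p.acceptor.name)
            if prev != p.acceptor.name:
                raise ContactMapError(
                    f"base {base[0]}/{base[1]} appears with two acceptor atoms "
                    f"({prev} and {p.acceptor.name}); one contact point per "
                    "nucleobase is required for sequence comparison"
                )
        object.__setattr__(
            self, "_groups", {g: tuple(ps) for g, ps in groups.items()}
        )

    @property
    def groups(self) -> Mapping[str, tuple[ContactPair, ...]]:
        return dict(self._groups)

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(self._groups)

    def __len__(self) -> int:
        return len(self.pairs)


def switching_value(r, p: SwitchingParams):
    """Contact weight of a pair at distance `r` (nm); scalar or array.

    Continuous everywhere: returns 1 below d0, the rational form above,
    and the analytic limit nn/mm at the removable singularity x = 1.
    """
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ContactMapError("distances must be finite")
    if np.any(arr < 0):
        raise ContactMapError("distances must be non-negative")
    x = (arr - p.d0) / p.r0
    out = np.empty_like(x)
    below = x < 0
    near = np.abs(x - 1.0) < _X_LIMIT_TOL
    other = ~(below | near)
    out[below] = 1.0
    out[near] = p.nn / p.mm
    xo = x[other]
    out[other] = (1.0 - xo**p.nn) / (1.0 - xo**p.mm)
    if arr.ndim == 0:
        return float(out)
    return out


def contact_total(
    distances: Mapping[ContactPair, float], spec: ContactMapSpec
) -> float:
    """Total contact count: sum of switching weights over all pairs."""
    total = 0.0
    for pair in spec.pairs:
        try:
            r = distances[pair]
        except KeyError:
            raise ContactMapError(
                f"no distance supplied for pair {pair.donor} -> {pair.acceptor} "
                f"(group {pair.group})"
            ) from None
        total += switching_value(r, spec.switching)
    return total


def contact_per_donor(
    distances: Mapping[ContactPair, float],
    spec: ContactMapSpec,
    group_label: str,
) -> float:
    """Contact count restricted to one donor group.

    Summing over all groups reproduces :func:`contact_total` exactly.
    """
    groups = spec.groups
    if group_label not in groups:
        raise ContactMapError(
            f"unknown donor group {group_label!r}; valid groups: "
            f"{sorted(groups)}"
        )
    total = 0.0
    for pair in groups[group_label]:
        try:
            r = distances[pair]
        except KeyError:
            raise ContactMapError(
                f"no distance supplied for pair {pair.donor} -> {pair.acceptor} "
                f"(group {pair.group})"
            ) from None
        total += switching_value(r, spec.switching)
    return total


def lambda_of_contacts(C, m: LambdaMap):
    """Normalized steering coordinate lambda = (C - c_end)/(c_start - c_end).

    Not clamped: values outside [0, 1] are returned as-is and logged, since
    thermal fluctuations legitimately overshoot the endpoints.
    """
    arr = np.asarray(C, dtype=float)
    lam = (arr - m.c_end) / (m.c_start - m.c_end)
    if np.any(lam < 0) or np.any(lam > 1):
        logger.info(
            "lambda values outside [0, 1] encountered (range %.4g..%.4g)",
            float(np.min(lam)),
            float(np.max(lam)),
        )
    if arr.ndim == 0:
        return float(lam)
    return lam


def linearity_score(
    p: SwitchingParams, r_lo: float, r_hi: float, n_points: int = 201
) -> float:
    """R^2 of the switching function against its least-squares line.

    Used to verify that a steering parameter set decays near-linearly over
    the working distance range, which keeps the displacement per contact
    approximately constant during the pull.
    """
    if not r_lo < r_hi:
        raise ContactMapError(f"need r_lo < r_hi, got {r_lo} and {r_hi}")
    if n_points < 100:
        raise ContactMapError("use at least 100 grid points")
    r = np.linspace(r_lo, r_hi, n_points)
    y = switching_value(r, p)
    slope, intercept = np.polyfit(r, y, 1)
    resid = y - (slope * r + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return 1.0 - ss_res / ss_tot


def pair_distances(
    structure: "Structure",
    pairs: Iterable[ContactPair],
    *,
    minimum_image: bool = False,
) -> dict[ContactPair, float]:
    """Donor-acceptor distances (nm) for `pairs` in one structure.

    By default distances are computed WITHOUT periodic-boundary wrapping:
    during a pull the nearest periodic image of a separating partner must
    not be silently substituted for the real one. `minimum_image=True`
    enables orthorhombic minimum-image wrapping for other use cases.
    """
    out: dict[ContactPair, float] = {}
    coords = structure.coords
    for pair in pairs:
        di = structure.index_of(pair.donor)
        ai = structure.index_of(pair.acceptor)
        delta = coords[di] - coords[ai]
        if minimum_image:
            if structure.box is None:
                raise ContactMapError(
                    "minimum-image distances requested but structure has no box"
                )
            delta = delta - structure.box * np.round(delta / structure.box)
        out[pair] = float(np.linalg.norm(delta))
    return out


def contact_timeseries(
    trajectory: "Trajectory",
    spec: ContactMapSpec,
    *,
    minimum_image: bool = False,
):
    """Per-frame contact counts: total and one column per donor group.

    Returns a pandas DataFrame indexed by frame time (ps) with columns
    'total' plus each group label. Fully vectorized over frames.
    """
    import pandas as pd

    top = trajectory.topology
    di = np.array([top.index_of(p.donor) for p in spec.pairs])
    ai = np.array([top.index_of(p.acceptor) for p in spec.pairs])
    frames = trajectory.frames  # (F, N, 3)
    delta = frames[:, di, :] - frames[:, ai, :]  # (F, P, 3)
    if minimum_image:
        if top.box is None:
            raise ContactMapError(
                "minimum-image distances requested but topology has no box"
            )
        delta = delta - top.box * np.round(delta / top.box)
    dist = np.linalg.norm(delta, axis=-1)  # (F, P)
    weights = switching_value(dist, spec.switching)
    data = {"total": weights.sum(axis=1)}
    labels = [p.group for p in spec.pairs]
    for g in spec.group_labels:
        mask = np.array([lab == g for lab in labels])
        data[g] = weights[:, mask].sum(axis=1)
    return pd.DataFrame(data, index=pd.Index(trajectory.times, name="time_ps"))
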