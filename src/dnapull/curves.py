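"""The work-curve container shared by the steering and estimator layers.

One steered run produces a cumulative work profile w(lambda) along the
restraint-center grid. Ensembles of these curves are the raw material of
the Jarzynski free-energy estimate, so the container enforces the
invariants the estimators rely on: a strictly descending lambda grid,
zero work at the start, and aligned optional per-group contact and RMSD
series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import WORK_UNITS, to_kcal
from .errors import AnalysisError

logger = logging.getLogger(__name__)

_W0_TOL = 1e-8


@dataclass
class WorkCurve:
    """Cumulative work along the steering coordinate for one run.

    lambda_grid is strictly descending (1 = bound start, 0 = dissociated
    end); work[0] must be zero (the gauge every estimator assumes).
    `groups` optionally carries per-donor contact counts aligned to the
    grid, `rmsd` an aligned per-frame RMSD (nm).
    """

    run_id: str
    lambda_grid: np.ndarray
    work: np.ndarray
    units: str = "kJ/mol"
    groups: dict[str, np.ndarray] | None = None
    rmsd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.work = np.asarray(self.work, dtype=float)
        if self.units not in WORK_UNITS:
            raise AnalysisError(
                f"unknown work units {self.units!r}; expected one of {WORK_UNITS}"
            )
        if self.lambda_grid.ndim != 1 or self.lambda_grid.size < 2:
            raise AnalysisError("lambda grid must be 1-D with at least 2 points")
        if self.work.shape != self.lambda_grid.shape:
            raise AnalysisError(
                f"work and lambda grid lengths differ in run {self.run_id!r}"
            )
        if not np.all(np.isfinite(self.lambda_grid)) or not np.all(
            np.isfinite(self.work)
        ):
            raise AnalysisError(f"non-finite values in work curve {self.run_id!r}")
        d = np.diff(self.lambda_grid)
        if not np.all(d < 0):
            raise AnalysisError(
                f"lambda grid of run {self.run_id!r} is not strictly descending"
            )
        if abs(self.work[0]) > _W0_TOL:
            raise AnalysisError(
                f"work curve {self.run_id!r} does not start at zero "
                f"(w[0] = {self.work[0]:.3g}); shift the gauge before constructing"
            )
        if self.groups is not None:
            self.groups = {
                g: np.asarray(v, dtype=float) for g, v in self.groups.items()
            }
            for g, v in self.groups.items():
                if v.shape != self.lambda_grid.shape:
                    raise AnalysisError(
                        f"group series {g!r} misaligned in run {self.run_id!r}"
                    )
        if self.rmsd is not None:
            self.rmsd = np.asarray(self.rmsd, dtype=float)
            if self.rmsd.shape != self.lambda_grid.shape:
                raise AnalysisError(f"RMSD series misaligned in run {self.run_id!r}")

    def __len__(self) -> int:
        return self.lambda_grid.size

    def work_kcal(self, temperature: float = 298.0) -> np.ndarray:
        """Work profile converted to kcal/mol."""
        return to_kcal(self.work, self.units, temperature)

    def resample(self, lambda_grid: Sequence[float]) -> "WorkCurve":
        """Linear interpolation of this curve onto another descending grid."""
        grid = np.asarray(lambda_grid, dtype=float)
        # np.interp needs ascending abscissae
        asc = self.lambda_grid[::-1]

        def _interp(y: np.ndarray) -> np.ndarray:
            return np.interp(grid[::-1], asc, y[::-1])[::-1]

        work = _interp(self.work)
        work = work - work[0]
        return WorkCurve(
            run_id=self.run_id,
            lambda_grid=grid,
            work=work,
            units=self.units,
            groups=None
            if self.groups is None
            else {g: _interp(v) for g, v in self.groups.items()},
            rmsd=None if self.rmsd is None else _interp(self.rmsd),
        )


def accumulate_from_series(
    contacts: np.ndarray, center: np.ndarray, force_constant: float
) -> np.ndarray:
    """Discrete work done by a moving harmonic restraint.

    w(t_k) = sum_{j<=k} k_f * (c_ref(t_j) - C(t_j)) * (c_ref(t_j) - c_ref(t_{j-1}))

    with w(t_0) = 0. This is the right-endpoint Riemann sum of the
    thermodynamic work integral dW = dU/dc_ref dc_ref for the restraint
    U = (k_f/2) (C - c_ref)^2.
    """
    contacts = np.asarray(contacts, dtype=float)
    center = np.asarray(center, dtype=float)
    if contacts.shape != center.shape or contacts.ndim != 1:
        raise AnalysisError("contacts and center series must be equal-length 1-D")
    dc = np.diff(center)
    inc = force_constant * (center[1:] - contacts[1:]) * dc
    return np.concatenate([[0.0], np.cumsum(inc)])


def common_grid(curves: Iterable[WorkCurve]) -> np.ndarray:
    """The densest lambda grid among `curves` (used as the shared axis)."""
    curves = list(curves)
    if not curves:
        raise AnalysisError("no curves given")
    return max(curves, key=len).lambda_grid.copy()


def on_common_grid(curves: Sequence[WorkCurve]) -> list[WorkCurve]:
    """Resample an ensemble onto its densest member's grid if grids differ."""
    curves = list(curves)
    grid = common_grid(curves)
    out = []
    for c in curves:
        if c.lambda_grid.shape == grid.shape and np.allclose(
            c.lambda_grid, grid
        ):
            out.append(c)
        else:
            out.append(c.resample(grid))
    return out
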