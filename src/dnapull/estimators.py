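"""Non-equilibrium work estimators: Jarzynski PMF, error bands, surfaces.

Given an ensemble of work-lambda curves w_i(lambda) from repeated steered
dissociations, the potential of mean force is estimated pointwise through
the Jarzynski equality

    Phi(lambda) = -(1/beta) * ln < exp(-beta * w_i(lambda)) >_i

evaluated with log-sum-exp stabilization; beta = 1/(k_B T). By Jensen's
inequality Phi never exceeds the arithmetic mean work, with equality only
when all curves coincide. The error band is the standard deviation over
the curves, reported both in the dimensionless (beta/2)*SD form and as a
plain SD in kcal/mol. The PMF range DeltaW = max(Phi) - min(Phi)
estimates the dissociation free-energy difference of one complex, and
DeltaDeltaW = |DeltaW_A - DeltaW_B| the sequence specificity between two.

Mechanistic read-outs: a Boltzmann-weighted 2D work surface over two
per-donor contact coordinates, a first-crossing pathway classifier
(which donor leaves the groove first), and the Pearson correlation of
per-run maximum work with maximum DNA deformation (RMSD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import pearsonr

from .colvar import read_colvar
from .constants import beta_kcal, to_kcal
from .contacts import LambdaMap, lambda_of_contacts
from .curves import WorkCurve, accumulate_from_series, on_common_grid
from .errors import AnalysisError

logger = logging.getLogger(__name__)

PATH_RGQ = "R-G-Q"
PATH_QGR = "Q-G-R"


@dataclass
class PMFProfile:
    """Jarzynski PMF Phi(lambda) in kcal/mol, anchored at the bound state.

    `sigma` is the dimensionless (beta/2)*SD error band of the work
    ensemble; `sd_kcal` the plain standard deviation in kcal/mol.
    """

    lambda_grid: np.ndarray
    phi: np.ndarray
    sigma: np.ndarray
    sd_kcal: np.ndarray
    n_runs: int
    temperature: float

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.sd_kcal = np.asarray(self.sd_kcal, dtype=float)
        if not (
            self.lambda_grid.shape
            == self.phi.shape
            == self.sigma.shape
            == self.sd_kcal.shape
        ):
            raise AnalysisError("PMF profile arrays must align")
        if abs(self.phi[0]) > 1e-9:
            raise AnalysisError("PMF must be anchored at zero in the bound state")
        if np.any(self.sigma < 0):
            raise AnalysisError("negative error band")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "phi_kcal": self.phi,
                "sigma_beta_half": self.sigma,
                "sd_kcal": self.sd_kcal,
            }
        )


@dataclass
class Surface2D:
    """Binned Boltzmann-weighted work surface over two contact coordinates.

    z[i, j] is the Boltzmann-weighted mean work (kcal/mol) of the samples
    falling in x-bin i, y-bin j; empty bins carry `fill`, strictly above
    the maximum observed work so that unexplored regions read as barriers.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    z: np.ndarray
    counts: np.ndarray
    fill: float
    temperature: float

    def __post_init__(self) -> None:
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.z.shape != (self.x_edges.size - 1, self.y_edges.size - 1):
            raise AnalysisError("surface shape does not match bin edges")
        if self.counts.shape != self.z.shape:
            raise AnalysisError("counts shape does not match surface")
        occupied = self.counts > 0
        if occupied.any() and self.fill <= self.z[occupied].max():
            raise AnalysisError("fill value must exceed the maximum observed work")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def occupied_bins(self) -> int:
        return int((self.counts > 0).sum())


@dataclass(frozen=True)
class PathClass:
    """Pathway label of one run with its diagnostic contact value."""

    run_id: str
    label: str
    c_q: float
    tied: bool = False


def read_work_curves(
    paths: Iterable,
    lambda_map: LambdaMap,
    *,
    force_constant: float | None = None,
    units: str = "kJ/mol",
) -> list[WorkCurve]:
    """Load an ensemble of COLVAR work tables onto a shared lambda grid.

    Expected columns: time, cv, center and optionally work (recomputed
    from cv/center when absent, which requires `force_constant`). Extra
    columns are kept as per-group contact series; an `rmsd` column is
    attached as the deformation series. Curves on different grids are
    resampled onto the densest one; a nonzero initial work value is
    shifted to zero with a warning (gauge fix).
    """
    paths = [p for p in paths]
    if not paths:
        raise AnalysisError("no work-table paths given")
    curves = []
    for path in paths:
        table, _meta = read_colvar(path)
        for col in ("time", "cv", "center"):
            if col not in table.columns:
                raise AnalysisError(f"{path}: missing required column {col!r}")
        if table.isna().any().any():
            raise AnalysisError(f"{path}: NaN values in work table")
        center = table["center"].to_numpy()
        lam = lambda_of_contacts(center, lambda_map)
        if not np.all(np.diff(lam) < 0):
            raise AnalysisError(
                f"{path}: restraint center does not descend monotonically in "
                "lambda; inconsistent steering direction"
            )
        if "work" in table.columns:
            work = table["work"].to_numpy(dtype=float)
        else:
            if force_constant is None:
                raise AnalysisError(
                    f"{path}: no work column and no force constant to recompute it"
                )
            work = accumulate_from_series(
                table["cv"].to_numpy(), center, force_constant
            )
        if abs(work[0]) > 1e-8:
            logger.warning(
                "%s: work starts at %.4g, shifting gauge to zero", path, work[0]
            )
            work = work - work[0]
        extra = [
            c
            for c in table.columns
            if c not in ("time", "cv", "center", "work", "rmsd")
        ]
        groups = (
            {c: table[c].to_numpy(dtype=float) for c in extra} if extra else None
        )
        rmsd = table["rmsd"].to_numpy(dtype=float) if "rmsd" in table.columns else None
        curves.append(
            WorkCurve(
                run_id=str(path),
                lambda_grid=lam,
                work=work,
                units=units,
                groups=groups,
                rmsd=rmsd,
            )
        )
    curves = on_common_grid(curves)
    logger.info(
        "loaded %d work curves on a %d-point lambda grid",
        len(curves),
        len(curves[0]),
    )
    return curves


def _work_matrix(
    curves: Sequence[WorkCurve], temperature: float
) -> tuple[np.ndarray, np.ndarray]:
    curves = list(curves)
    if not curves:
        raise AnalysisError("empty curve ensemble")
    grid = curves[0].lambda_grid
    for c in curves[1:]:
        if c.lambda_grid.shape != grid.shape or not np.allclose(
            c.lambda_grid, grid
        ):
            raise AnalysisError(
                "curves are not on a shared lambda grid; resample first "
                "(read_work_curves does this automatically)"
            )
    W = np.stack([c.work_kcal(temperature) for c in curves])
    return grid, W


def jarzynski_pmf(
    curves: Sequence[WorkCurve], temperature: float = 298.0
) -> PMFProfile:
    """Pointwise Jarzynski PMF of a work-curve ensemble, in kcal/mol."""
    grid, W = _work_matrix(curves, temperature)
    beta = beta_kcal(temperature)
    n = W.shape[0]
    if n == 1:
        logger.warning(
            "single work curve: the Jarzynski average degenerates to Phi = w"
        )
        phi = W[0].copy()
    else:
        phi = -(logsumexp(-beta * W, axis=0) - np.log(n)) / beta
    phi = phi - phi[0]
    sigma, sd = _sigma_profiles(W, beta)
    return PMFProfile(
        lambda_grid=grid.copy(),
        phi=phi,
        sigma=sigma,
        sd_kcal=sd,
        n_runs=n,
        temperature=temperature,
    )


def _sigma_profiles(W: np.ndarray, beta: float) -> tuple[np.ndarray, np.ndarray]:
    # population variance, as the error-band formula is written
    sd = W.std(axis=0, ddof=0)
    return (beta / 2.0) * sd, sd


def work_std(
    curves: Sequence[WorkCurve], temperature: float = 298.0
) -> tuple[np.ndarray, np.ndarray]:
    """Error band of the ensemble: ((beta/2)*SD dimensionless, SD kcal/mol)."""
    if len(curves) < 2:
        raise AnalysisError("need at least two curves for a spread")
    _, W = _work_matrix(curves, temperature)
    return _sigma_profiles(W, beta_kcal(temperature))


def delta_w(pmf: PMFProfile) -> float:
    """PMF range max(Phi) - min(Phi): the dissociation free-energy estimate."""
    return float(pmf.phi.max() - pmf.phi.min())


def delta_delta_w(pmf_a: PMFProfile, pmf_b: PMFProfile) -> float:
    """Sequence specificity |DeltaW_A - DeltaW_B| between two complexes."""
    return abs(delta_w(pmf_a) - delta_w(pmf_b))


def boltzmann_surface_2d(
    curves: Sequence[WorkCurve],
    x_group: str,
    y_group: str,
    bins: int = 100,
    temperature: float = 298.0,
    fill_multiplier: float = 1.05,
) -> Surface2D:
    """Boltzmann-weighted mean work binned over two contact coordinates.

    Every (C_x, C_y, w) sample of every curve lands in exactly one bin;
    per occupied bin z = sum(w * exp(-beta w)) / sum(exp(-beta w)) is
    evaluated with a per-bin shift for stability. Empty bins get
    `fill_multiplier` times the maximum observed work.
    """
    xs, ys, ws = [], [], []
    for c in curves:
        if c.groups is None or x_group not in c.groups or y_group not in c.groups:
            missing = x_group if (c.groups is None or x_group not in c.groups) else y_group
            raise AnalysisError(
                f"curve {c.run_id!r} lacks per-group series {missing!r}"
            )
        xs.append(c.groups[x_group])
        ys.append(c.groups[y_group])
        ws.append(c.work_kcal(temperature))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    w = np.concatenate(ws)
    beta = beta_kcal(temperature)
    x_edges = np.histogram_bin_edges(x, bins=bins)
    y_edges = np.histogram_bin_edges(y, bins=bins)
    bx = np.clip(np.digitize(x, x_edges) - 1, 0, bins - 1)
    by = np.clip(np.digitize(y, y_edges) - 1, 0, bins - 1)
    w_max = float(w.max())
    if w_max > 0:
        fill = w_max * fill_multiplier
    else:  # keep fill strictly above the maximum even for non-positive work
        fill = w_max + (fill_multiplier - 1.0) * max(abs(w_max), 1.0)
    z = np.full((bins, bins), fill)
    counts = np.zeros((bins, bins), dtype=int)
    frame = pd.DataFrame({"bx": bx, "by": by, "w": w})
    for (i, j), grp in frame.groupby(["bx", "by"], sort=False):
        vals = grp["w"].to_numpy()
        shift = vals.min()
        weights = np.exp(-beta * (vals - shift))
        z[i, j] = float(np.sum(vals * weights) / np.sum(weights))
        counts[i, j] = vals.size
    return Surface2D(
        x_edges=x_edges,
        y_edges=y_edges,
        z=z,
        counts=counts,
        fill=fill,
        temperature=temperature,
    )


def smooth_surface(surface: Surface2D, degree: int = 4) -> np.ndarray:
    """Cosmetic polynomial fit of the occupied bins (least squares).

    Returns a dense z array evaluated on the bin centers; the binned
    surface remains the authoritative construction. Off by default
    everywhere in the pipeline.
    """
    xc = 0.5 * (surface.x_edges[:-1] + surface.x_edges[1:])
    yc = 0.5 * (surface.y_edges[:-1] + surface.y_edges[1:])
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    occ = surface.counts > 0
    if occ.sum() < (degree + 1) * (degree + 2) // 2:
        raise AnalysisError("too few occupied bins for the requested degree")
    powers = [(i, j) for i in range(degree + 1) for j in range(degree + 1 - i)]
    A = np.column_stack([X[occ] ** i * Y[occ] ** j for i, j in powers])
    coef, *_ = np.linalg.lstsq(A, surface.z[occ], rcond=None)
    dense = np.zeros_like(surface.z)
    for c, (i, j) in zip(coef, powers):
        dense += c * X**i * Y**j
    return dense


def classify_pathway(
    curve: WorkCurve,
    q_group: str = "Q112",
    total_threshold: float = 30.0,
    q_threshold: float = 5.0,
    total_groups: Sequence[str] | None = None,
) -> PathClass:
    """Which donor leaves the groove first, read at a total-contact crossing.

    At the FIRST time the total contact count crosses `total_threshold`
    from above, the Q-donor count is read off by linear interpolation
    between the bracketing samples: below `q_threshold` means the
    arginine side dissociates last (R-G-Q route), above means the
    glutamine side does (Q-G-R). An exact tie is labeled R-G-Q and
    flagged.
    """
    if curve.groups is None or q_group not in curve.groups:
        raise AnalysisError(f"curve {curve.run_id!r} lacks group {q_group!r}")
    labels = list(total_groups) if total_groups is not None else list(curve.groups)
    missing = [g for g in labels if g not in curve.groups]
    if missing:
        raise AnalysisError(f"curve {curve.run_id!r} lacks groups {missing}")
    total = np.sum([curve.groups[g] for g in labels], axis=0)
    q = curve.groups[q_group]
    above = total >= total_threshold
    if not above[0]:
        raise AnalysisError(
            f"curve {curve.run_id!r} starts below the total-contact threshold "
            f"{total_threshold}; no crossing from above exists"
        )
    below_idx = np.flatnonzero(total < total_threshold)
    if below_idx.size == 0:
        raise AnalysisError(
            f"curve {curve.run_id!r} never crosses the total-contact "
            f"threshold {total_threshold}"
        )
    k = int(below_idx[0])  # first sample strictly below; k-1 is >= threshold
    t0, t1 = total[k - 1], total[k]
    frac = (t0 - total_threshold) / (t0 - t1)
    c_q = float(q[k - 1] + frac * (q[k] - q[k - 1]))
    if c_q < q_threshold:
        label, tied = PATH_RGQ, False
    elif c_q > q_threshold:
        label, tied = PATH_QGR, False
    else:
        label, tied = PATH_RGQ, True
        logger.warning(
            "run %s: C_Q exactly at the threshold %.3g; labeling %s",
            curve.run_id,
            q_threshold,
            PATH_RGQ,
        )
    return PathClass(run_id=curve.run_id, label=label, c_q=c_q, tied=tied)


def correlate_max_work_rmsd(
    curves: Sequence[WorkCurve], temperature: float = 298.0
) -> tuple[float | None, pd.DataFrame]:
    """Pearson r between per-run maximum work and maximum DNA RMSD.

    High-work runs dragging the DNA out of shape show up as a positive
    correlation. Returns (r, table of per-run maxima); r is None when
    either coordinate has zero variance.
    """
    rows = []
    for c in curves:
        if c.rmsd is None:
            raise AnalysisError(f"curve {c.run_id!r} carries no RMSD series")
        rows.append(
            {
                "run_id": c.run_id,
                "max_work_kcal": float(c.work_kcal(temperature).max()),
                "max_rmsd_nm": float(c.rmsd.max()),
            }
        )
    if len(rows) < 3:
        raise AnalysisError("need at least three runs for a correlation")
    table = pd.DataFrame(rows)
    wv = table["max_work_kcal"].to_numpy()
    rv = table["max_rmsd_nm"].to_numpy()
    if wv.std() == 0 or rv.std() == 0:
        logger.warning("zero variance in maxima; correlation undefined")
        return None, table
    r = float(pearsonr(wv, rv).statistic)
    return r, table
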