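"""Analysis pipeline for single-cell spreading and migration trajectories.

Operates on long-format per-cell time series of volume (µm³) and
substrate-contact area (µm²) sampled about once per minute.  The stages
mirror the measurement protocol: re-zero each record at spreading onset
(first detectable contact below a threshold), fit the contact-area kinetics
with the exponential-saturation ansatz, fit the normalized volume trace with
the mechanosensitive pump-and-leak forward model to estimate (ξ, τ), take
10-min initial slopes of area and volume, split cells into spreading-speed
terciles, and run the summary regressions (volume flux vs spreading speed;
Ponder's relation for shock data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import OsmovolError
from .mechano import MechanoParams, SpreadingAnsatz, simulate_spreading_volume

__all__ = [
    "CellTrajectory",
    "FitResult",
    "FluxEstimate",
    "RegressionResult",
    "SpeedGroups",
    "OnsetNotFoundError",
    "align_spreading_onset",
    "fit_area_ansatz",
    "fit_volume_params",
    "initial_fluxes",
    "classify_by_speed",
    "flux_regression",
    "ponder_regression",
    "windowed_flux_cv",
]


class OnsetNotFoundError(OsmovolError):
    """No sample satisfies the spreading-onset criterion; cell excluded."""


@dataclass
class CellTrajectory:
    """One cell's recording: times in minutes, volume µm³, area µm².

    Missing samples are NaN.  Times must be strictly increasing, every row
    must carry at least one of (volume, area), and values are non-negative.
    """

    cell_id: str
    times: np.ndarray
    volumes: np.ndarray
    areas: np.ndarray
    condition: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if not (len(self.times) == len(self.volumes) == len(self.areas)):
            raise ValueError(f"{self.cell_id}: length mismatch between columns")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.cell_id}: times must be strictly increasing")
        both_missing = np.isnan(self.volumes) & np.isnan(self.areas)
        if np.any(both_missing):
            raise ValueError(f"{self.cell_id}: rows with neither volume nor area")
        for name, arr in (("volumes", self.volumes), ("areas", self.areas)):
            if np.any(arr[~np.isnan(arr)] < 0):
                raise ValueError(f"{self.cell_id}: negative {name}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FitResult:
    """Parameter estimates with convergence bookkeeping."""

    params: dict
    rss: float
    n_points: int
    converged: bool
    bounds_hit: dict = field(default_factory=dict)
    message: str = ""


@dataclass
class FluxEstimate:
    """Initial linear slopes of area and volume (NaN when unavailable)."""

    cell_id: str
    dAdt: float
    dVdt: float
    window: tuple
    n_points: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    stderr_slope: float
    stderr_intercept: float
    extra: dict = field(default_factory=dict)


@dataclass
class SpeedGroups:
    """Tercile split by initial spreading speed."""

    slow: list
    moderate: list
    fast: list
    degenerate: bool = False

    def sizes(self) -> tuple:
        return (len(self.slow), len(self.moderate), len(self.fast))


def align_spreading_onset(traj: CellTrajectory,
                          area_threshold: float = 100.0) -> CellTrajectory:
    """Re-zero a trajectory at spreading onset.

    Onset is the first sample with detectable contact (area > 0); it must
    not exceed ``area_threshold`` (default 100 µm²), otherwise the actual
    onset was missed and the cell is excluded by raising
    :class:`OnsetNotFoundError`.  Samples before onset are dropped.
    """
    detectable = np.nonzero(~np.isnan(traj.areas) & (traj.areas > 0))[0]
    if detectable.size == 0:
        raise OnsetNotFoundError(f"{traj.cell_id}: no detectable contact area")
    i0 = int(detectable[0])
    if traj.areas[i0] > area_threshold:
        raise OnsetNotFoundError(
            f"{traj.cell_id}: first detectable area {traj.areas[i0]:.1f} µm² "
            f"exceeds the onset threshold {area_threshold} µm²"
        )
    return CellTrajectory(
        cell_id=traj.cell_id,
        times=traj.times[i0:] - traj.times[i0],
        volumes=traj.volumes[i0:],
        areas=traj.areas[i0:],
        condition=traj.condition,
    )


def fit_area_ansatz(traj: CellTrajectory,
                    bounds_A0: tuple = (None, 1e4),
                    bounds_tau_a: tuple = (0.5, 500.0)) -> FitResult:
    """Two-parameter fit of the exponential-saturation spreading ansatz.

    ``A_init`` is pinned to the onset-sample area; ``(A0, tau_a)`` are free
    (nonlinear least squares).  The trajectory must be onset-aligned with at
    least 6 area samples.
    """
    mask = ~np.isnan(traj.areas)
    t, A = traj.times[mask], traj.areas[mask]
    if len(A) < 6:
        raise ValueError(f"{traj.cell_id}: need >= 6 area samples, have {len(A)}")
    A_init = float(A[0])
    lo_A0 = bounds_A0[0] if bounds_A0[0] is not None else A_init + 1e-6
    hi_A0 = bounds_A0[1]

    def resid(theta):
        A0, tau_a = theta
        return A_init + (A0 - A_init) * (1.0 - np.exp(-t / tau_a)) - A

    A0_guess = min(max(float(np.max(A)), lo_A0 + 1.0), hi_A0)
    tau_guess = min(max(float(t[-1]) / 4.0, bounds_tau_a[0]), bounds_tau_a[1])
    sol = least_squares(resid, x0=[A0_guess, tau_guess],
                        bounds=([lo_A0, bounds_tau_a[0]], [hi_A0, bounds_tau_a[1]]))
    A0_hat, tau_hat = sol.x
    bounds_hit = {
        "A0": bool(np.isclose(A0_hat, lo_A0, rtol=1e-6)
                   or np.isclose(A0_hat, hi_A0, rtol=1e-6)),
        "tau_a": bool(np.isclose(tau_hat, bounds_tau_a[0], rtol=1e-6)
                      or np.isclose(tau_hat, bounds_tau_a[1], rtol=1e-6)),
    }
    return FitResult(
        params={"A_init": A_init, "A0": float(A0_hat), "tau_a": float(tau_hat)},
        rss=float(np.sum(sol.fun**2)), n_points=int(len(A)),
        converged=bool(sol.success), bounds_hit=bounds_hit, message=sol.message,
    )


#: Multi-start grid for the (xi, tau) volume fit, spanning the weak/strong
#: coupling and fast/slow relaxation corners of the plausible range.
_VOLUME_FIT_STARTS = ((0.3, 5.0), (0.3, 50.0), (2.0, 5.0), (2.0, 50.0))


def fit_volume_params(traj: CellTrajectory, ansatz: SpreadingAnsatz,
                      mech: MechanoParams,
                      bounds_xi: tuple = (0.0, 10.0),
                      bounds_tau: tuple = (0.5, 200.0),
                      sim_dt: float = 0.5) -> FitResult:
    """Estimate (ξ, τ) from a normalized volume trace.

    The forward model is :func:`simulate_spreading_volume` driven by the
    fitted area ansatz, with growth rate and reference volume taken from
    ``mech`` (``V_iso`` is re-pinned to the mean of the first three volume
    samples).  Nonlinear least squares from four starting points guards
    against local minima; a fit pinned at ξ = 0 (flat volume) is a valid
    result, not an error.
    """
    mask = ~np.isnan(traj.volumes)
    t, V = traj.times[mask], traj.volumes[mask]
    if len(V) < 4:
        raise ValueError(f"{traj.cell_id}: need >= 4 volume samples")
    V_iso = float(np.mean(V[:3]))
    v = V / V_iso
    duration = float(t[-1]) + sim_dt

    def forward(xi, tau):
        p = replace(mech, xi=float(xi), tau=float(tau), V_iso=V_iso,
                    alpha=None, k=None, gamma_iso=None)
        sim = simulate_spreading_volume(p, ansatz, duration, dt=sim_dt)
        v_model = np.interp(t, sim.times, sim.V)
        # normalize the model exactly as the data (first-3-sample mean), so
        # the normalization convention cancels instead of biasing xi
        return v_model / np.mean(v_model[:3])

    def resid(theta):
        return forward(*theta) - v

    best = None
    for x0 in _VOLUME_FIT_STARTS:
        x0c = (min(max(x0[0], bounds_xi[0]), bounds_xi[1]),
               min(max(x0[1], bounds_tau[0]), bounds_tau[1]))
        try:
            sol = least_squares(
                resid, x0=x0c,
                bounds=([bounds_xi[0], bounds_tau[0]], [bounds_xi[1], bounds_tau[1]]),
                x_scale=[1.0, 10.0], xtol=1e-10, ftol=1e-10,
            )
        except Exception:  # geometry failure for extreme trial parameters
            continue
        if best is None or np.sum(sol.fun**2) < np.sum(best.fun**2):
            best = sol
    if best is None:
        return FitResult(params={}, rss=math.inf, n_points=int(len(V)),
                         converged=False, message="all starts failed")
    xi_hat, tau_hat = best.x
    bounds_hit = {
        "xi": bool(np.isclose(xi_hat, bounds_xi[0], atol=1e-9)
                   or np.isclose(xi_hat, bounds_xi[1], rtol=1e-6)),
        "tau": bool(np.isclose(tau_hat, bounds_tau[0], rtol=1e-6)
                    or np.isclose(tau_hat, bounds_tau[1], rtol=1e-6)),
    }
    return FitResult(
        params={"xi": float(xi_hat), "tau": float(tau_hat), "V_iso": V_iso},
        rss=float(np.sum(best.fun**2)), n_points=int(len(V)),
        converged=bool(best.success), bounds_hit=bounds_hit, message=best.message,
    )


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def initial_fluxes(traj: CellTrajectory, window_min: float = 10.0) -> FluxEstimate:
    """Initial spreading speed dA/dt and volume flux dV/dt.

    Ordinary least-squares slopes over the first ``window_min`` minutes of
    the onset-aligned record; a series with fewer than 3 samples in the
    window yields NaN for its slope.
    """
    in_win = traj.times <= window_min + 1e-9
    res = {}
    counts = {}
    for name, arr in (("dAdt", traj.areas), ("dVdt", traj.volumes)):
        m = in_win & ~np.isnan(arr)
        counts[name] = int(m.sum())
        res[name] = _ols_slope(traj.times[m], arr[m]) if counts[name] >= 3 else float("nan")
    return FluxEstimate(
        cell_id=traj.cell_id, dAdt=res["dAdt"], dVdt=res["dVdt"],
        window=(0.0, float(window_min)), n_points=min(counts.values()),
    )


def classify_by_speed(cells: list) -> SpeedGroups:
    """Split cells into slow/moderate/fast terciles of dA/dt.

    Rank-based split (stable sort, so tied speeds fall into the lower
    group) with sizes differing by at most one; with remainder 1 the extra
    cell joins the middle group (n = 127 gives 42/43/42), with remainder 2
    the outer groups get the extras.  All-equal speeds are a degenerate
    single-group case, flagged rather than silently split.
    """
    usable = [c for c in cells if not math.isnan(c.dAdt)]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 cells with dA/dt, have {len(usable)}")
    order = sorted(range(len(usable)), key=lambda i: (usable[i].dAdt, str(usable[i].cell_id)))
    speeds = [usable[i].dAdt for i in order]
    if speeds[0] == speeds[-1]:
        return SpeedGroups(slow=[usable[i] for i in order], moderate=[], fast=[],
                           degenerate=True)
    n = len(order)
    q, rem = divmod(n, 3)
    if rem == 0:
        sizes = (q, q, q)
    elif rem == 1:
        sizes = (q, q + 1, q)
    else:
        sizes = (q + 1, q, q + 1)
    i1, i2 = sizes[0], sizes[0] + sizes[1]
    return SpeedGroups(
        slow=[usable[i] for i in order[:i1]],
        moderate=[usable[i] for i in order[i1:i2]],
        fast=[usable[i] for i in order[i2:]],
    )


def _regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if np.ptp(x) == 0:
        raise ValueError("no spread in the regressor")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), n=int(len(x)),
        stderr_slope=float(res.stderr), stderr_intercept=float(res.intercept_stderr),
    )


def flux_regression(cells: list) -> RegressionResult:
    """OLS of volume flux dV/dt on spreading speed dA/dt across cells."""
    pairs = [(c.dAdt, c.dVdt) for c in cells
             if not (math.isnan(c.dAdt) or math.isnan(c.dVdt))]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 cells with both fluxes, have {len(pairs)}")
    arr = np.asarray(pairs)
    return _regress(arr[:, 0], arr[:, 1])


def ponder_regression(points) -> RegressionResult:
    """Ponder regression: passive V/V_iso against P_iso/P.

    The slope estimates the osmotically active fraction R, the intercept
    1 - R.  ``extra['sum_within_ci']`` reports whether slope + intercept is
    compatible with 1 within the joint 95% confidence interval — a check of
    the fixed-content passive model itself.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (ratio, V/V_iso) points")
    if np.unique(pts[:, 0]).size < 2:
        raise ValueError("all osmolarity ratios equal: regression undefined")
    res = _regress(pts[:, 0], pts[:, 1])
    # var(slope + intercept) = var(s) + var(i) + 2 cov(s, i); cov = -xbar var(s)
    xbar = float(np.mean(pts[:, 0]))
    var_sum = res.stderr_slope**2 + res.stderr_intercept**2 \
        - 2.0 * xbar * res.stderr_slope**2
    sd_sum = math.sqrt(max(var_sum, 0.0))
    dev = abs(res.slope + res.intercept - 1.0)
    res.extra["sum_minus_one"] = res.slope + res.intercept - 1.0
    res.extra["sum_within_ci"] = bool(dev <= max(1.96 * sd_sum, 1e-9))
    return res


def windowed_flux_cv(traj: CellTrajectory, window_min: float = 10.0,
                     mode: str = "volume_scale") -> float:
    """Coefficient of variation of the windowed volume flux dV/dt.

    The volume trace is cut into non-overlapping ``window_min`` windows and
    an OLS slope computed per window.  Because the mean flux of a
    fluctuating trace is near zero, the default normalization divides the
    slope standard deviation by the natural flux scale ``mean(V)/window``
    (giving a dimensionless number comparable to a relative volume
    amplitude); ``mode='plain'`` uses std/|mean| of the slopes.
    """
    mask = ~np.isnan(traj.volumes)
    t, V = traj.times[mask], traj.volumes[mask]
    if len(t) == 0:
        raise ValueError(f"{traj.cell_id}: no volume samples")
    t0 = t[0]
    n_win = int(math.floor((t[-1] - t0) / window_min))
    slopes = []
    for i in range(n_win):
        m = (t >= t0 + i * window_min) & (t < t0 + (i + 1) * window_min)
        if m.sum() >= 3:
            slopes.append(_ols_slope(t[m], V[m]))
    if len(slopes) < 3:
        raise ValueError(
            f"{traj.cell_id}: only {len(slopes)} usable windows; >= 3 required"
        )
    slopes = np.asarray(slopes)
    if mode == "plain":
        mean = np.mean(slopes)
        if mean == 0:
            raise ZeroDivisionError("mean windowed flux is zero; use mode='volume_scale'")
        return float(np.std(slopes, ddof=1) / abs(mean))
    if mode != "volume_scale":
        raise ValueError(f"unknown mode {mode!r}")
    scale = float(np.mean(V)) / window_min
    return float(np.std(slopes, ddof=1) / scale)
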