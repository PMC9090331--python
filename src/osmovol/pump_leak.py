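"""Classical pump-and-leak model (PLM) of cell volume regulation.

A cell at osmotic equilibrium balances the osmotic pressure of impermeant
intracellular osmolytes (proteins, metabolites; on average negatively
charged) against permeant ions (Na+, K+, Cl-) whose gradients are maintained
by active pumping.  Passive ion fluxes are Ohmic, ``g_i (Vm - E_i)`` with
Nernst potential ``E_i``; the Na/K pump extrudes 3 Na+ for 2 K+ imported.
The steady state solves, simultaneously,

* zero net flux for each ion species,
* internal electroneutrality (including the charge on trapped osmolytes),
* osmotic balance with the external medium.

Dynamics after an osmotic shock separate into a fast passive phase (water
flux, seconds) at fixed ion content, and a slow regulatory phase (minutes)
in which ion content relaxes toward the value that restores the isosmotic
volume (regulatory volume decrease/increase).  The passive limit is Ponder's
relation: ``V/V_iso = R * (P_iso/P) + (1 - R)``, with ``R`` the osmotically
active volume fraction.

Units: volumes µm³, areas µm², concentrations mM, time minutes internally
(shock protocols and trajectories are stamped in seconds), potentials mV,
pressures Pa.  ``RT = 2577 Pa/mM`` and the Nernst scale ``RT/F = 26.71 mV``
at 310 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import ConvergenceError, StabilityError, VolumeCollapseError
from .geometry import sphere_area_from_volume

__all__ = [
    "RT_PA_PER_MM",
    "NERNST_MV",
    "IonTransportParams",
    "CellOsmoticState",
    "ShockProtocol",
    "OsmoticTrajectory",
    "default_hela_params",
    "flux_residuals",
    "solve_steady_state",
    "ponder_passive_volume",
    "simulate_osmotic_shock",
    "estimate_permeability",
    "adaptation_rate",
    "bulk_modulus",
    "laplace_pressure",
    "trapped_pressure_change",
    "contractility_volume_bound",
]

#: Gas constant times temperature at 310 K, in Pa per mM of osmolarity.
RT_PA_PER_MM = 2577.0
#: Nernst potential scale RT/F at 310 K, in mV.
NERNST_MV = 26.71

_ELECTRONEUTRALITY_TOL = 1e-6  # relative, on the external medium


@dataclass(frozen=True)
class IonTransportParams:
    """Parameters of the three-ion pump-and-leak model.

    Attributes
    ----------
    cNa_ext, cK_ext, cCl_ext : float
        External ion concentrations (mM).  Must be electroneutral within
        tolerance (monovalent approximation).
    gNa, gK, gCl : float
        Passive conductances per unit membrane area
        (amount·min⁻¹·µm⁻²·mV⁻¹ on the package's semantic scale).
    betaNa, betaK, betaCl : float
        Dimensionless mechanosensitivities: each conductance responds to a
        relative tension change x as ``g_i (1 + beta_i x)``.
    pump_rate : float
        Active Na extrusion rate per unit area (amount·min⁻¹·µm⁻²) with
        fixed 3 Na out : 2 K in stoichiometry.
    nX : float
        Amount of charged impermeant osmolyte (mM·µm³), conserved.
    zX : float
        Mean valence of the charged osmolyte; negative.
    nY : float
        Amount of neutral impermeant osmolyte (mM·µm³), conserved.
    Lp_in, Lp_out : float
        Hydraulic permeability for swelling / shrinking (µm·min⁻¹·Pa⁻¹);
        the asymmetry is empirical.
    k_reg : float
        Regulatory ion-content relaxation rate (min⁻¹).
    reg_flux_cap : float or None
        Optional cap on the magnitude of the total regulatory ion flux
        (mM·µm³/min); saturation reproduces partial recovery after large
        hypo-osmotic shocks.
    excluded_fraction : float
        Osmotically inactive volume fraction b/V at the isosmotic steady
        state, in [0, 1).
    RT : float
        Gas constant times temperature (Pa/mM).
    """

    cNa_ext: float = 145.0
    cK_ext: float = 5.0
    cCl_ext: float = 150.0
    gNa: float = 1.0
    gK: float = 1.0
    gCl: float = 1.0
    betaNa: float = 0.0
    betaK: float = 0.0
    betaCl: float = 0.0
    pump_rate: float = 25.0
    nX: float = 134000.0
    zX: float = -0.7
    nY: float = 0.0
    Lp_in: float = 1.5e-5
    Lp_out: float = 7.5e-6
    k_reg: float = 0.1
    reg_flux_cap: float | None = None
    excluded_fraction: float = 0.33
    RT: float = RT_PA_PER_MM

    def __post_init__(self):
        nonneg = {
            "cNa_ext": self.cNa_ext, "cK_ext": self.cK_ext, "cCl_ext": self.cCl_ext,
            "gNa": self.gNa, "gK": self.gK, "gCl": self.gCl,
            "pump_rate": self.pump_rate, "nX": self.nX, "nY": self.nY,
            "Lp_in": self.Lp_in, "Lp_out": self.Lp_out, "k_reg": self.k_reg,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.zX >= 0:
            raise ValueError(f"zX must be < 0 (trapped osmolytes are net negative), got {self.zX}")
        if not (0 <= self.excluded_fraction < 1):
            raise ValueError(f"excluded_fraction must be in [0, 1), got {self.excluded_fraction}")
        net = self.cNa_ext + self.cK_ext - self.cCl_ext
        scale = max(self.cCl_ext, 1.0)
        if abs(net) > _ELECTRONEUTRALITY_TOL * scale:
            raise ValueError(
                f"external medium not electroneutral: cNa+cK-cCl = {net:.3g} mM"
            )

    @property
    def osm_ext(self) -> float:
        """Total external osmolarity (mM)."""
        return self.cNa_ext + self.cK_ext + self.cCl_ext


@dataclass(frozen=True)
class CellOsmoticState:
    """Instantaneous osmotic state of one cell.

    ``V`` is total volume; ``Vw = V - b`` the osmotically active water
    volume; concentrations are per water volume; ``A`` is the membrane area
    used to scale fluxes.
    """

    V: float
    Vw: float
    cNa: float
    cK: float
    cCl: float
    Vm: float
    A: float

    @property
    def b(self) -> float:
        """Osmotically inactive volume (µm³)."""
        return self.V - self.Vw


@dataclass(frozen=True)
class ShockProtocol:
    """Time-stamped external osmolarity steps.

    ``events`` maps times (s, strictly increasing) to the ratio
    ``P_iso / P`` of isosmotic to imposed external osmotic pressure
    (> 1 = hypo-osmotic dilution).  ``dt`` is the output sampling step (s).
    """

    events: tuple[tuple[float, float], ...]
    duration: float
    dt: float

    def __post_init__(self):
        if len(self.events) == 0:
            raise ValueError("protocol needs at least one event")
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(r <= 0 for _, r in self.events):
            raise ValueError("osmolarity ratios must be > 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("duration and dt must be > 0")

    def ratio_at(self, t: float) -> float:
        """Piecewise-constant P_iso/P at time ``t`` (s); 1.0 before the first event."""
        r = 1.0
        for t_ev, r_ev in self.events:
            if t >= t_ev:
                r = r_ev
            else:
                break
        return r


@dataclass
class OsmoticTrajectory:
    """Simulated (or measured) volume response to an osmotic protocol.

    Times in seconds; ``V`` total volume (µm³); ``n_ions`` the per-species
    internal amounts (mM·µm³) stacked as columns (Na, K, Cl); ``osm_ext``
    the external osmolarity (mM).
    """

    times: np.ndarray
    V: np.ndarray
    n_ions: np.ndarray
    osm_ext: np.ndarray
    b: float = 0.0
    V_iso: float = field(default=float("nan"))


def default_hela_params(V_iso: float = 2000.0) -> IonTransportParams:
    """Parameter set reproducing textbook HeLa-scale ion homeostasis.

    Conductance ratios and pump rate are constructed analytically so that
    the steady state sits exactly at the target interior composition
    cNa = 15, cK = 120, cCl = 65 mM with 100 mM of impermeant osmolyte of
    mean valence -0.7 (interior ion sum 200 mM, total 300 mM against a
    300 mM medium), at reference volume ``V_iso``.
    """
    cNa_ext, cK_ext, cCl_ext = 145.0, 5.0, 150.0
    cNa, cK, cCl = 15.0, 120.0, 65.0
    cX, zX = 100.0, -0.7
    phi = 0.33
    Vw = (1.0 - phi) * V_iso
    nX = cX * Vw
    Vm = NERNST_MV * math.log(cCl / cCl_ext)  # Cl at equilibrium sets Vm
    E_Na = NERNST_MV * math.log(cNa_ext / cNa)
    E_K = NERNST_MV * math.log(cK_ext / cK)
    gNa = 1.0
    pump = gNa * (E_Na - Vm) / 3.0
    gK = 2.0 * pump / (Vm - E_K)
    return IonTransportParams(
        cNa_ext=cNa_ext, cK_ext=cK_ext, cCl_ext=cCl_ext,
        gNa=gNa, gK=gK, gCl=1.0, pump_rate=pump,
        nX=nX, zX=zX, nY=0.0, excluded_fraction=phi,
    )


def _nernst(c_ext: float, c_int: float, z: int) -> float:
    return NERNST_MV / z * math.log(c_ext / c_int)


def flux_residuals(params: IonTransportParams, state: CellOsmoticState,
                   tension_rel: float = 0.0) -> tuple[float, float, float]:
    """Net inward molar flux per unit area for (Na, K, Cl).

    ``tension_rel`` is the relative tension change x; conductances scale as
    ``g_i (1 + beta_i x)``.  Zero for all three species defines the steady
    state.
    """
    x = tension_rel
    gNa = params.gNa * (1.0 + params.betaNa * x)
    gK = params.gK * (1.0 + params.betaK * x)
    gCl = params.gCl * (1.0 + params.betaCl * x)
    p = params.pump_rate
    J_Na = -gNa * (state.Vm - _nernst(params.cNa_ext, state.cNa, +1)) - 3.0 * p
    J_K = -gK * (state.Vm - _nernst(params.cK_ext, state.cK, +1)) + 2.0 * p
    J_Cl = gCl * (state.Vm - _nernst(params.cCl_ext, state.cCl, -1))
    return J_Na, J_K, J_Cl


def _interior_at_vm(params: IonTransportParams, Vm: float,
                    tension_rel: float = 0.0) -> tuple[float, float, float]:
    """Interior concentrations implied by zero net flux at potential ``Vm``."""
    x = tension_rel
    gNa = params.gNa * (1.0 + params.betaNa * x)
    gK = params.gK * (1.0 + params.betaK * x)
    gCl = params.gCl * (1.0 + params.betaCl * x)
    p = params.pump_rate
    if gNa <= 0 or gK <= 0 or gCl <= 0:
        raise ConvergenceError(
            "steady state requires strictly positive conductances for all species"
        )
    # zero flux: g(Vm - E) = -3p (Na), = 2p (K), = 0 (Cl)
    cNa = params.cNa_ext * math.exp(-(Vm + 3.0 * p / gNa) / NERNST_MV)
    cK = params.cK_ext * math.exp(-(Vm - 2.0 * p / gK) / NERNST_MV)
    cCl = params.cCl_ext * math.exp(Vm / NERNST_MV)
    return cNa, cK, cCl


def solve_steady_state(params: IonTransportParams, V_init_guess: float = 2000.0,
                       tension_rel: float = 0.0) -> CellOsmoticState:
    """Solve the pump-and-leak steady state.

    At given membrane potential the three zero-flux conditions fix the
    interior concentrations in closed form; electroneutrality then fixes the
    water volume, and the osmotic-balance residual is a function of the
    potential alone, bracketed and solved by Brent's method.

    Raises
    ------
    ConvergenceError
        If no positive-volume solution exists (e.g. the classical
        divergence when the pump is off, or vanishing impermeant content
        which leaves the volume undetermined).
    """
    if V_init_guess <= 0:
        raise ValueError("V_init_guess must be > 0")
    if params.nX <= 0:
        raise ConvergenceError(
            "no impermeant charged osmolyte (nX = 0): steady-state volume is "
            "undetermined in the pump-and-leak model"
        )

    osm_ext = params.osm_ext

    def vw_of(Vm: float) -> float:
        cNa, cK, cCl = _interior_at_vm(params, Vm, tension_rel)
        net_ion_charge = cNa + cK - cCl
        if net_ion_charge <= 0:
            return float("nan")
        return -params.zX * params.nX / net_ion_charge

    def residual(Vm: float) -> float:
        cNa, cK, cCl = _interior_at_vm(params, Vm, tension_rel)
        Vw = vw_of(Vm)
        if not math.isfinite(Vw) or Vw <= 0:
            return float("nan")
        return cNa + cK + cCl + (params.nX + params.nY) / Vw - osm_ext

    # Scan for a sign change on a physiological potential range.
    grid = np.linspace(-250.0, 100.0, 1401)
    vals = np.array([residual(v) for v in grid])
    ok = np.isfinite(vals)
    bracket = None
    for i in range(len(grid) - 1):
        if ok[i] and ok[i + 1] and vals[i] * vals[i + 1] <= 0:
            bracket = (grid[i], grid[i + 1])
            break
    if bracket is None:
        finite = vals[ok]
        raise ConvergenceError(
            "no pump-and-leak steady state found (no sign change of the "
            "osmotic residual over Vm in [-250, 100] mV); minimal |residual| "
            f"= {np.min(np.abs(finite)) if finite.size else float('nan'):.4g} mM. "
            "With the pump off the classical model has no finite-volume solution.",
            residuals=vals,
        )
    Vm = brentq(residual, *bracket, xtol=1e-12, rtol=8.9e-16)
    cNa, cK, cCl = _interior_at_vm(params, Vm, tension_rel)
    Vw = vw_of(Vm)
    V = Vw / (1.0 - params.excluded_fraction)
    state = CellOsmoticState(V=V, Vw=Vw, cNa=cNa, cK=cK, cCl=cCl, Vm=Vm,
                             A=sphere_area_from_volume(V))

    # Post-conditions: fluxes, electroneutrality, osmotic balance.
    J = flux_residuals(params, state, tension_rel)
    flux_scale = max(params.pump_rate, params.gNa * NERNST_MV, 1e-12)
    electro = (cNa + cK - cCl + params.zX * params.nX / Vw) / osm_ext
    osm = residual(Vm) / osm_ext
    norm = math.sqrt(sum((j / flux_scale) ** 2 for j in J) + electro**2 + osm**2)
    if norm > 1e-8:
        raise ConvergenceError(
            f"steady-state residual norm {norm:.3e} exceeds 1e-8",
            residuals={"flux": J, "electroneutrality": electro, "osmotic": osm},
        )
    return state


def ponder_passive_volume(ratio: float, active_fraction: float) -> float:
    """Ponder's relation: passive post-shock volume at fixed solute content.

    ``V/V_iso = R * (P_iso/P) + (1 - R)`` where ``R`` is the osmotically
    active volume fraction and the intercept ``1 - R`` the inactive one.
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    if not (0 < active_fraction <= 1):
        raise ValueError(f"active_fraction must be in (0, 1], got {active_fraction}")
    return active_fraction * ratio + (1.0 - active_fraction)


def simulate_osmotic_shock(params: IonTransportParams, state0: CellOsmoticState,
                           protocol: ShockProtocol,
                           sample_times: np.ndarray | None = None) -> OsmoticTrajectory:
    """Integrate the volume response to a sequence of osmotic steps.

    Water flux: ``dV/dt = Lp A RT (Pi_int - Pi_ext)`` with the swelling
    permeability when the interior is hyper-osmotic relative to the medium
    and the shrinking permeability otherwise.  Ion content relaxes at rate
    ``k_reg`` toward the content that restores the isosmotic water volume
    under the current medium (regulatory volume decrease/increase),
    optionally saturated at ``reg_flux_cap``.  Trapped osmolyte amounts
    ``nX, nY`` are conserved exactly (dry content constant).

    ``state0`` must be a steady state of ``params``.  Integration uses a
    stiff-capable adaptive solver (LSODA) piecewise between protocol events;
    ``protocol.dt`` only sets the output grid but is checked against the
    water-flux timescale so that an aliased passive phase fails loudly
    rather than silently.  ``sample_times`` (s) overrides the uniform grid.
    """
    # pre: state0 consistent with params at rest
    J = flux_residuals(params, state0)
    flux_scale = max(params.pump_rate, params.gNa * NERNST_MV, 1e-12)
    if math.sqrt(sum((j / flux_scale) ** 2 for j in J)) > 1e-6:
        raise ValueError("state0 is not a steady state of params")

    b = state0.b
    A = state0.A
    Vw_iso = state0.Vw
    n_iso = np.array([state0.cNa, state0.cK, state0.cCl]) * Vw_iso
    n_trapped = params.nX + params.nY
    osm_iso = params.osm_ext
    RT = params.RT

    # Water-flux e-folding time (min) at the largest shock, for the dt check.
    Lp_max = max(params.Lp_in, params.Lp_out)
    ratios = [r for _, r in protocol.events]
    osm_max = osm_iso * max(1.0 / min(ratios), 1.0 / max(ratios), 1.0)
    tau_w_min = Vw_iso / (Lp_max * A * RT * osm_max)
    if sample_times is None and protocol.dt / 60.0 > 5.0 * tau_w_min:
        raise StabilityError(
            f"output step {protocol.dt} s cannot resolve the water-flux "
            f"timescale ({tau_w_min * 60:.2f} s); refine protocol.dt or pass "
            "sample_times"
        )

    def rhs(t_min: float, y: np.ndarray, osm_ext: float) -> np.ndarray:
        Vw = y[0]
        n = y[1:]
        pi_int = (n.sum() + n_trapped) / Vw
        Lp = params.Lp_in if pi_int > osm_ext else params.Lp_out
        dVw = Lp * A * RT * (pi_int - osm_ext)
        # regulatory target: content that restores Vw_iso under this medium
        n_target_tot = max(Vw_iso * osm_ext - n_trapped, 0.0)
        n_target = n_iso * (n_target_tot / n_iso.sum())
        dn = -params.k_reg * (n - n_target)
        if params.reg_flux_cap is not None:
            tot = float(np.abs(dn).sum())
            if tot > params.reg_flux_cap:
                dn = dn * (params.reg_flux_cap / tot)
        return np.concatenate([[dVw], dn])

    if sample_times is None:
        ts = np.arange(0.0, protocol.duration + 0.5 * protocol.dt, protocol.dt)
    else:
        ts = np.asarray(sample_times, dtype=float)
    ts_min = ts / 60.0

    # segment boundaries: protocol events clipped to [0, duration]
    ev_times = [max(t, 0.0) / 60.0 for t, _ in protocol.events]
    bounds = sorted({0.0, protocol.duration / 60.0, *ev_times})
    bounds = [t for t in bounds if t <= protocol.duration / 60.0]

    y = np.concatenate([[Vw_iso], n_iso])
    out_t, out_y = [], []
    floor = 1e-6 * Vw_iso

    def collapse(t, y, osm_ext):
        return y[0] - floor
    collapse.terminal = True
    collapse.direction = -1

    for t0, t1 in zip(bounds, bounds[1:]):
        osm_ext = osm_iso / protocol.ratio_at(t0 * 60.0 + 1e-9)
        seg_ts = ts_min[(ts_min >= t0 - 1e-12) & (ts_min <= t1 + 1e-12)]
        t_eval = np.union1d(seg_ts, [t1])
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", args=(osm_ext,),
                        t_eval=t_eval,
                        rtol=1e-9, atol=[1e-8 * Vw_iso] + [1e-8 * n_iso.sum()] * 3,
                        events=collapse, max_step=max((t1 - t0) / 4, 1e-6))
        if sol.t_events[0].size:
            raise VolumeCollapseError(
                f"volume collapsed to the inactive floor at t = {sol.t_events[0][0] * 60:.2f} s",
                t_collapse=sol.t_events[0][0] * 60.0,
            )
        if not sol.success:
            raise ConvergenceError(f"shock integration failed: {sol.message}")
        y = sol.y[:, -1]
        if seg_ts.size:
            n_out = seg_ts.size
            out_t.append(seg_ts)
            out_y.append(sol.y[:, :n_out] if sol.t[-1] > seg_ts[-1] + 1e-15
                         else sol.y[:, -n_out:])

    t_all = np.concatenate(out_t)
    y_all = np.concatenate(out_y, axis=1)
    # deduplicate boundary points sampled by both segments
    t_sec = t_all * 60.0
    keep = np.concatenate([[True], np.diff(t_sec) > 1e-9])
    t_sec, y_all = t_sec[keep], y_all[:, keep]
    osm_trace = np.array([osm_iso / protocol.ratio_at(t) for t in t_sec])
    traj = OsmoticTrajectory(
        times=t_sec, V=y_all[0] + b, n_ions=y_all[1:].T, osm_ext=osm_trace,
        b=b, V_iso=state0.V,
    )
    return traj


def _shock_onset_index(trace: OsmoticTrajectory) -> int:
    d = np.abs(trace.osm_ext - trace.osm_ext[0])
    idx = np.nonzero(d > 1e-9 * trace.osm_ext[0])[0]
    if idx.size == 0:
        return 0
    return int(idx[0])


def estimate_permeability(trace: OsmoticTrajectory, area: float, delta_Pi: float,
                          region: tuple[float, float] | None = None) -> float:
    """Hydraulic permeability from the initial passive slope of V(t).

    ``|dV/dt| / (area |delta_Pi|)`` with the slope (ordinary least squares)
    taken on the designated linear region; by default the first second after
    the shock onset detected from the external-osmolarity trace.
    ``delta_Pi`` is the imposed osmotic pressure step in Pa.
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    if delta_Pi == 0:
        raise ValueError("delta_Pi must be nonzero")
    if region is None:
        t0 = trace.times[_shock_onset_index(trace)]
        region = (t0, t0 + 1.0)
    mask = (trace.times >= region[0]) & (trace.times <= region[1])
    if mask.sum() < 3:
        raise ValueError(
            f"fewer than 3 samples in the designated region {region}"
        )
    slope_per_s = np.polyfit(trace.times[mask], trace.V[mask], 1)[0]
    return abs(slope_per_s) * 60.0 / (area * abs(delta_Pi))


def adaptation_rate(trace: OsmoticTrajectory, window_min: float = 5.0,
                    search_min: float = 3.0) -> float:
    """Regulatory adaptation flux (µm³/min) after an osmotic shock.

    The volume extremum reached during the passive response is located as
    the discrete argmin/argmax (whichever deviates more from the pre-shock
    volume; earliest index on ties) within ``search_min`` minutes of the
    shock onset; the adaptation rate is the least-squares slope of V over
    the following ``window_min`` minutes.
    """
    i0 = _shock_onset_index(trace)
    t, V = trace.times[i0:], trace.V[i0:]
    dV = np.diff(V)
    if np.all(dV > 0) or np.all(dV < 0):
        raise ValueError("monotone trace: no post-shock extremum detectable")
    in_search = t <= t[0] + search_min * 60.0
    Vs = V[in_search]
    v0 = V[0]
    i_max, i_min = int(np.argmax(Vs)), int(np.argmin(Vs))
    i_ext = i_max if abs(Vs[i_max] - v0) >= abs(Vs[i_min] - v0) else i_min
    t_ext = t[i_ext]
    mask = (t >= t_ext) & (t <= t_ext + window_min * 60.0)
    if (t[-1] - t_ext) < window_min * 60.0 - 1e-9:
        raise ValueError(
            f"trace ends {(t[-1] - t_ext) / 60:.2f} min after the extremum; "
            f"{window_min} min required"
        )
    slope_per_s = np.polyfit(t[mask], V[mask], 1)[0]
    return slope_per_s * 60.0


def bulk_modulus(V_iso: float, delta_P: float, delta_V: float) -> float:
    """Osmotic bulk modulus ``B = V_iso * delta_P / delta_V`` (Pa)."""
    if delta_V == 0:
        raise ValueError("delta_V must be nonzero")
    return V_iso * delta_P / delta_V


def laplace_pressure(gamma: float, radius: float) -> float:
    """Laplace pressure ``2 gamma / r`` across a spherical surface.

    ``gamma`` in mN/m, ``radius`` in µm; returns Pa (1 mN/m / 1 µm = 1000 Pa,
    so 1 mN/m at 10 µm gives 200 Pa).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return 2.0 * gamma * 1e-3 / (radius * 1e-6)


def trapped_pressure_change(Pi_trapped: float, volume_decrease_fraction: float,
                            exact: bool = False) -> float:
    """Osmotic pressure rise of trapped osmolytes upon a volume decrease.

    Linearized form ``Pi * f`` by default; the exact concentration-ratio
    form ``Pi * f / (1 - f)`` when ``exact=True``.
    """
    f = volume_decrease_fraction
    if not (0 <= f < 1):
        raise ValueError(f"fraction must be in [0, 1), got {f}")
    if exact:
        return Pi_trapped * f / (1.0 - f)
    return Pi_trapped * f


def contractility_volume_bound(tension_factor: float, P_laplace_base: float,
                               Pi_total: float) -> float:
    """Relative volume change a contractility increase can impose osmotically.

    A ``tension_factor``-fold rise of the baseline cortical Laplace pressure
    must be balanced by concentrating the impermeant osmolytes; the relative
    volume change is ``tension_factor * P_laplace / Pi_total`` — of order 1%
    even for a 10-fold contractility increase, which is why cortical tension
    alone cannot drive the observed volume losses.
    """
    if tension_factor < 0:
        raise ValueError("tension_factor must be >= 0")
    if Pi_total <= 0:
        raise ValueError("Pi_total must be > 0")
    return tension_factor * P_laplace_base / Pi_total
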