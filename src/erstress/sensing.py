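"""Ratiometric ER-stress sensing as a three-way binding competition.

A generic UPR sensor T (standing in for IRE1α/PERK/ATF6α collectively), the
chaperone BiP (B) and an unfolded client (C, the IgM heavy chain µs in the
cell model this emulates) interconvert through three reversible complexes:

    T + B <-> TB   (K_TB)   sensor OFF
    T + C <-> TC   (K_TC)   sensor ON
    B + C <-> BC   (K_BC)   chaperone-client

At equilibrium the fraction of sensor bound to client, TC/T_tot, is the
signaling activity.  Because the sensor is sub-stoichiometric, and BiP and
client concentrations are far above K_BC, the activity depends on B_tot and
C_tot essentially only through their ratio — the ratiometric regime.

A dynamic variant adds UPR-driven BiP upregulation,

    dB_tot/dt = k_syn0 + k_upr * activity(t) - k_deg * B_tot,

with the client following a logistic schedule, reproducing the acute
(client eclipses BiP, activity maximal) to chronic (BiP back in excess,
activity submaximal) transition.

No dissociation constants or sensor copy numbers are published for this
system; the defaults here are invented model parameters chosen so the
ratiometric regime holds at the mM-scale BiP concentrations the pipeline
estimates, and are meant to be overridden via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .quantitation import AbundanceTimeCourse

__all__ = [
    "EquilibriumError",
    "SensorSystem",
    "EquilibriumState",
    "FeedbackParams",
    "Trajectory",
    "solve_equilibrium",
    "activity_vs_ratio",
    "predict_amplitude_timecourse",
    "logistic_schedule",
    "default_feedback_params",
    "simulate_feedback",
]


class EquilibriumError(RuntimeError):
    """The fixed-point iteration failed to reach the residual tolerance."""


@dataclass(frozen=True)
class SensorSystem:
    """Totals and dissociation constants, all in the same units (mM).

    ``free_sensor_active`` controls whether unbound sensor counts toward
    activity; by default only client-bound sensor is ON.
    """

    T_tot: float = 1e-3
    B_tot: float = 0.5
    C_tot: float = 0.0
    K_TB: float = 1e-3
    K_TC: float = 1e-3
    K_BC: float = 1e-2
    free_sensor_active: bool = False

    def __post_init__(self) -> None:
        if min(self.T_tot, self.B_tot, self.C_tot) < 0:
            raise ValueError("totals must be non-negative")
        if min(self.K_TB, self.K_TC, self.K_BC) <= 0:
            raise ValueError("dissociation constants must be positive")


@dataclass(frozen=True)
class EquilibriumState:
    """Free species, complexes and derived sensor activity at equilibrium."""

    T: float
    B: float
    C: float
    TB: float
    TC: float
    BC: float
    activity: float
    off_fraction: float


@dataclass(frozen=True)
class FeedbackParams:
    """Rates for the BiP-upregulation feedback loop (mM and hours)."""

    k_syn0: float            # basal BiP synthesis, mM/hr
    k_upr: float             # UPR-driven synthesis gain, mM/hr per unit activity
    k_deg: float             # first-order BiP turnover, 1/hr
    client_schedule: Callable[[float], float]  # C_tot(t), mM
    sensors: SensorSystem = field(default_factory=SensorSystem)

    def __post_init__(self) -> None:
        if min(self.k_syn0, self.k_upr, self.k_deg) < 0:
            raise ValueError("rates must be non-negative")
        if self.k_deg == 0:
            raise ValueError("k_deg must be positive for a bounded steady state")


@dataclass(frozen=True)
class Trajectory:
    """Time series of totals and sensor activity."""

    times_hr: tuple[float, ...]
    B_tot: tuple[float, ...]
    C_tot: tuple[float, ...]
    activity: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.times_hr)
        if not (len(self.B_tot) == len(self.C_tot) == len(self.activity) == n):
            raise ValueError("trajectory series must have equal length")

    @property
    def ratio(self) -> np.ndarray:
        """Client-to-BiP total ratio C_tot/B_tot (inf where B_tot is 0)."""
        b = np.asarray(self.B_tot)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.asarray(self.C_tot) / b

    @property
    def argmax_activity(self) -> int:
        return int(np.argmax(self.activity))

    @property
    def argmax_ratio(self) -> int:
        return int(np.argmax(self.ratio))

    @property
    def argmax_client(self) -> int:
        return int(np.argmax(self.C_tot))


# ---------------------------------------------------------------------------
# equilibrium solver
# ---------------------------------------------------------------------------

def _state_from_free(sys: SensorSystem, B: float, C: float) -> EquilibriumState:
    T = sys.T_tot / (1.0 + B / sys.K_TB + C / sys.K_TC)
    TB = T * B / sys.K_TB
    TC = T * C / sys.K_TC
    BC = B * C / sys.K_BC
    if sys.T_tot > 0:
        on = (TC + T) / sys.T_tot if sys.free_sensor_active else TC / sys.T_tot
        off = TB / sys.T_tot
    else:
        on = off = 0.0
    return EquilibriumState(T, B, C, TB, TC, BC, on, off)


def _residuals(sys: SensorSystem, B: float, C: float) -> tuple[float, float]:
    st = _state_from_free(sys, B, C)
    scale_b = max(sys.B_tot, sys.K_TB, sys.K_BC)
    scale_c = max(sys.C_tot, sys.K_TC, sys.K_BC)
    rb = (st.B + st.TB + st.BC - sys.B_tot) / scale_b
    rc = (st.C + st.TC + st.BC - sys.C_tot) / scale_c
    return rb, rc


def solve_equilibrium(
    sys: SensorSystem,
    *,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> EquilibriumState:
    """Solve the three conservation/mass-action equations for free T, B, C.

    Uses a damped fixed-point iteration on the free chaperone and client
    concentrations, with the damping factor halved whenever the residual
    fails to shrink.  The unique non-negative solution is returned; failure
    to converge raises :class:`EquilibriumError` with diagnostics.
    """
    B, C = sys.B_tot, sys.C_tot
    alpha = 1.0
    err_prev = np.inf
    best = (np.inf, B, C)
    for iteration in range(max_iter):
        T = sys.T_tot / (1.0 + B / sys.K_TB + C / sys.K_TC)
        B_new = sys.B_tot / (1.0 + T / sys.K_TB + C / sys.K_BC)
        C_new = sys.C_tot / (1.0 + T / sys.K_TC + B / sys.K_BC)
        err = max(abs(B_new - B), abs(C_new - C))
        if err > err_prev:
            alpha = max(alpha / 2.0, 1e-3)
        err_prev = err
        B += alpha * (B_new - B)
        C += alpha * (C_new - C)
        rb, rc = _residuals(sys, B, C)
        res = max(abs(rb), abs(rc))
        if res < best[0]:
            best = (res, B, C)
        if res < max(tol, 1e-8):  # close enough for the Newton polish
            break
    else:
        _, B, C = best
    B, C, res = _newton_polish(sys, B, C)
    if res < max(tol, 1e-9):
        return _state_from_free(sys, B, C)
    raise EquilibriumError(
        f"no convergence after {max_iter} iterations "
        f"(residual {res:.2e}, damping {alpha})"
    )


def _newton_polish(sys: SensorSystem, B: float, C: float,
                   max_steps: int = 60) -> tuple[float, float, float]:
    """Damped Newton on the two conservation residuals; quadratic near the
    solution, driving residuals to machine precision."""
    def res_vec(B, C):
        rb, rc = _residuals(sys, B, C)
        return np.array([rb, rc])

    r = res_vec(B, C)
    for _ in range(max_steps):
        norm = np.abs(r).max()
        if norm < 1e-15:
            break
        T = sys.T_tot / (1.0 + B / sys.K_TB + C / sys.K_TC)
        if sys.T_tot > 0:
            dT_dB = -(T**2) / (sys.T_tot * sys.K_TB)
            dT_dC = -(T**2) / (sys.T_tot * sys.K_TC)
        else:
            dT_dB = dT_dC = 0.0
        scale_b = max(sys.B_tot, sys.K_TB, sys.K_BC)
        scale_c = max(sys.C_tot, sys.K_TC, sys.K_BC)
        j = np.array([
            [(1 + T / sys.K_TB + B / sys.K_TB * dT_dB + C / sys.K_BC) / scale_b,
             (B / sys.K_TB * dT_dC + B / sys.K_BC) / scale_b],
            [(C / sys.K_TC * dT_dB + C / sys.K_BC) / scale_c,
             (1 + T / sys.K_TC + C / sys.K_TC * dT_dC + B / sys.K_BC) / scale_c],
        ])
        try:
            step = np.linalg.solve(j, r)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        for _ in range(40):  # backtrack, keeping concentrations non-negative
            B_try = max(B - lam * step[0], 0.0)
            C_try = max(C - lam * step[1], 0.0)
            r_try = res_vec(B_try, C_try)
            if np.abs(r_try).max() < norm:
                B, C, r = B_try, C_try, r_try
                break
            lam /= 2.0
        else:
            break
    return B, C, float(np.abs(r).max())


def activity_vs_ratio(
    sys: SensorSystem,
    ratios: Sequence[float],
    *,
    mode: str = "fixed_B",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sensor activity across a sweep of the C_tot/B_tot ratio.

    ``mode='fixed_B'`` holds B_tot at the template value and varies C_tot;
    ``mode='fixed_sum'`` holds B_tot + C_tot constant.  Returns (ratios,
    activities, argmax index).
    """
    ratios = np.asarray(ratios, float)
    if ratios.size == 0:
        raise ValueError("ratio sweep is empty")
    if np.any(ratios < 0):
        raise ValueError("ratios must be non-negative")
    activities = np.empty(ratios.size)
    for i, rho in enumerate(ratios):
        if mode == "fixed_B":
            trial = replace(sys, C_tot=rho * sys.B_tot)
        elif mode == "fixed_sum":
            total = sys.B_tot + sys.C_tot
            b = total / (1.0 + rho)
            trial = replace(sys, B_tot=b, C_tot=total - b)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        activities[i] = solve_equilibrium(trial).activity
    return ratios, activities, int(np.argmax(activities))


def predict_amplitude_timecourse(
    bip_tc: AbundanceTimeCourse,
    client_tc: AbundanceTimeCourse,
    volumes_fl: Sequence[float],
    sys: SensorSystem = SensorSystem(),
) -> Trajectory:
    """Equilibrium UPR activity along measured copies-per-cell courses.

    ``volumes_fl`` supplies the ER volume at each shared time point to
    convert copies into lumenal concentrations.  The returned trajectory
    exposes argmax of activity, of the client/BiP ratio, and of the client
    itself, for checking which one signaling follows.
    """
    from .morphometry import molar_concentration

    t_b = np.asarray(bip_tc.times_hr)
    t_c = np.asarray(client_tc.times_hr)
    if t_b.shape != t_c.shape or not np.allclose(t_b, t_c):
        raise ValueError("time courses must share a time grid "
                         "(interpolate via fit_sigmoid first)")
    volumes = np.asarray(volumes_fl, float)
    if volumes.shape != t_b.shape:
        raise ValueError("need one ER volume per time point")
    if np.any(volumes <= 0):
        raise ValueError("ER volume must be positive at every time")
    B = [molar_concentration(c, v) for c, v in zip(bip_tc.copies, volumes)]
    C = [molar_concentration(c, v) for c, v in zip(client_tc.copies, volumes)]
    act = [
        solve_equilibrium(replace(sys, B_tot=b, C_tot=c)).activity
        for b, c in zip(B, C)
    ]
    return Trajectory(tuple(t_b), tuple(B), tuple(C), tuple(act))


# ---------------------------------------------------------------------------
# feedback dynamics
# ---------------------------------------------------------------------------

def logistic_schedule(
    plateau_mm: float = 1.4,
    half_time_hr: float = 12.0,
    hill: float = 2.5,
) -> Callable[[float], float]:
    """Logistic client onset C_tot(t), the shape the kinetic fits supply."""
    def schedule(t: float) -> float:
        if t <= 0:
            return 0.0
        th = t**hill
        return plateau_mm * th / (th + half_time_hr**hill)
    return schedule


def default_feedback_params(**overrides) -> FeedbackParams:
    """Feedback rates sized so basal BiP sits at 0.5 mM and the chronic
    steady state ends with BiP back in excess of the client plateau."""
    defaults = dict(
        k_syn0=0.025,     # 0.5 mM basal level at k_deg = 0.05/hr
        k_upr=0.2,
        k_deg=0.05,
        client_schedule=logistic_schedule(),
        sensors=SensorSystem(),
    )
    defaults.update(overrides)
    return FeedbackParams(**defaults)


def simulate_feedback(
    params: FeedbackParams,
    horizon_hr: float = 168.0,
    *,
    n_eval: int = 337,
    rtol: float = 1e-6,
    B0_mm: float | None = None,
) -> Trajectory:
    """Integrate the BiP-upregulation ODE against the client schedule.

    Starts from the basal steady state k_syn0/k_deg unless ``B0_mm`` is
    given.  Activity along the trajectory is recomputed from the
    equilibrium solver on the evaluation grid.
    """
    if horizon_hr <= 0:
        raise ValueError("horizon must be positive")
    b0 = params.k_syn0 / params.k_deg if B0_mm is None else float(B0_mm)

    def activity_at(t: float, b: float) -> float:
        sys = replace(params.sensors, B_tot=max(b, 0.0),
                      C_tot=params.client_schedule(t))
        return solve_equilibrium(sys).activity

    def rhs(t, y):
        a = activity_at(t, y[0])
        return [params.k_syn0 + params.k_upr * a - params.k_deg * y[0]]

    t_eval = np.linspace(0.0, horizon_hr, n_eval)
    sol = solve_ivp(rhs, (0.0, horizon_hr), [b0], t_eval=t_eval,
                    rtol=rtol, atol=1e-9, method="RK45")
    if not sol.success:
        raise EquilibriumError(f"ODE integration failed: {sol.message}")
    b = sol.y[0]
    c = np.array([params.client_schedule(t) for t in t_eval])
    act = np.array([activity_at(t, bi) for t, bi in zip(t_eval, b)])
    return Trajectory(tuple(t_eval), tuple(b), tuple(c), tuple(act))
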