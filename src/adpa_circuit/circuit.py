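"""Delayed negative-feedback circuit of AdpA autoregulation under sulfane sulfur.

The model tracks four species: apo-AdpA (``A``), persulfidated AdpA
(``As``), the intracellular sulfane-sulfur pool (``S``) and a downstream
target protein (``G``, an ActII-4/EGFP proxy).  AdpA represses its own
promoter and activates the target promoter; persulfidation of Cys62 lowers
the DNA affinity of AdpA by a factor ``alpha_K``, so the effective repressor
concentration is ``R_eff = A + As / alpha_K``.  Transcription plus
translation of *adpA* takes a discrete delay ``tau``; above a critical delay
the self-repression loop undergoes a Hopf bifurcation and AdpA expression
becomes wave-like.  A pulse of sulfane sulfur converts A into the weakly
binding As form, transiently breaking the loop.

Units are nM and minutes throughout.

dA/dt  = beta_A * p_adpA(R_eff(t - tau)) - d_A*A - k_mod*A*S + k_red*As
dAs/dt = k_mod*A*S - k_red*As - d_A*As
dS/dt  = input(t) - k_mod*A*S - d_S*S
dG/dt  = beta_G * p_target(R_eff(t)) - d_G*G

Integration is fixed-step classical Runge-Kutta with the method of steps
for the delayed term (history before t = 0 held constant at the initial
state).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CircuitParams",
    "SulfurSchedule",
    "CircuitState",
    "Trajectory",
    "OscillationSummary",
    "PulseComparison",
    "promoter_activities",
    "steady_state",
    "linear_stability",
    "simulate",
    "detect_oscillation",
    "pulse_response",
]

_NEG_TOL = 1e-9  # integrator guard: state may not dip below -1e-9 nM


@dataclass(frozen=True)
class CircuitParams:
    """Kinetic constants of the circuit (nM, min).

    Defaults give a loop whose critical delay is ~58 min, so the default
    ``tau`` = 80 min places the system past the Hopf point and AdpA
    expression oscillates in the absence of sulfane sulfur.
    """

    beta_A: float = 20.0     # max AdpA synthesis rate, nM/min
    K_rep: float = 100.0     # self-repression half-max, nM
    n_rep: float = 2.0       # repression Hill coefficient
    tau: float = 80.0        # transcription+translation delay, min
    d_A: float = 0.05        # degradation/dilution of both AdpA forms, 1/min
    k_mod: float = 1e-3      # persulfidation rate constant, 1/(nM*min)
    k_red: float = 0.01      # back-reduction of AdpA-S, 1/min
    d_S: float = 0.02        # sulfane-sulfur loss to other sinks, 1/min
    beta_G: float = 10.0     # max target synthesis rate, nM/min
    K_act: float = 200.0     # activation half-max, nM
    n_act: float = 2.0       # activation Hill coefficient
    d_G: float = 0.05        # target degradation, 1/min
    alpha_K: float = 20.0    # K_D fold-increase of persulfidated AdpA

    def __post_init__(self) -> None:
        for name in ("beta_A", "K_rep", "tau", "d_A", "k_mod", "k_red",
                     "d_S", "beta_G", "K_act", "d_G"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.n_rep < 1 or self.n_act < 1:
            raise ValueError("Hill coefficients must be >= 1")
        if self.alpha_K < 1:
            raise ValueError("alpha_K must be >= 1")
        if self.K_rep <= 0 or self.K_act <= 0:
            raise ValueError("K_rep and K_act must be > 0")

    def replace(self, **changes) -> "CircuitParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SulfurSchedule:
    """Exogenous sulfane-sulfur input: impulse events plus a constant feed.

    ``events`` are (time, amount) pairs in min and nM sulfane-sulfur
    equivalents; an event adds its amount to S at the nearest grid point.
    ``baseline_input`` (nM/min) models endogenous accumulation.
    """

    events: tuple = ()
    baseline_input: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events",
                           tuple((float(t), float(a)) for t, a in self.events))
        for t, a in self.events:
            if t < 0 or a < 0:
                raise ValueError("event times and amounts must be >= 0")
        if self.baseline_input < 0:
            raise ValueError("baseline_input must be >= 0")


@dataclass(frozen=True)
class CircuitState:
    """Concentrations (nM) of apo-AdpA, AdpA-S, sulfane sulfur and target."""

    A: float = 0.0
    As: float = 0.0
    S: float = 0.0
    G: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A", "As", "S", "G"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.As, self.S, self.G], dtype=float)


@dataclass
class Trajectory:
    """Simulated time course on a uniform grid."""

    times: np.ndarray
    A: np.ndarray
    As: np.ndarray
    S: np.ndarray
    G: np.ndarray
    params_used: CircuitParams
    schedule_used: SulfurSchedule

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def state_at(self, i: int) -> CircuitState:
        return CircuitState(A=float(self.A[i]), As=float(self.As[i]),
                            S=float(self.S[i]), G=float(self.G[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "A": self.A, "As": self.As,
                             "S": self.S, "G": self.G})


@dataclass(frozen=True)
class OscillationSummary:
    n_peaks: int
    period_mean: float  # min; NaN with < 2 peaks
    amplitude_mean: float  # nM
    sustained: bool


@dataclass(frozen=True)
class PulseComparison:
    """Pulse run vs baseline run, compared from the first pulse onward."""

    peak_A_ratio: float        # pulsed/baseline max of A
    dominance_interval: float  # total min with As > A in the pulsed run
    G_delay: float             # lag (min) between A and G first exceeding baseline maxima
    G_gain: float              # pulsed/baseline integral of G


def _effective_repressor(A, As, params: CircuitParams):
    return A + As / params.alpha_K


def _activities(A, As, params: CircuitParams):
    """Promoter activities from concentrations; vectorized over A/As."""
    R = _effective_repressor(A, As, params)
    u = (R / params.K_rep) ** params.n_rep
    p_adpA = 1.0 / (1.0 + u)
    v = (R / params.K_act) ** params.n_act
    p_target = v / (1.0 + v)
    return p_adpA, p_target


def promoter_activities(state: CircuitState, params: CircuitParams):
    """Fractional activity of P_adpA (repressed) and P_target (activated).

    The effective repressor is ``A + As/alpha_K``: the persulfidated form
    still binds, alpha_K-fold more weakly.
    """
    for v in (state.A, state.As):
        if not math.isfinite(v):
            raise ValueError("non-finite state")
    p_a, p_t = _activities(state.A, state.As, params)
    return float(p_a), float(p_t)


def steady_state(params: CircuitParams) -> float:
    """Fixed point of the S = 0 loop: beta_A/(1+(A/K_rep)^n_rep) = d_A*A."""
    if params.d_A <= 0:
        raise ValueError("d_A must be > 0 for a steady state")
    if params.beta_A == 0:
        return 0.0

    def g(a: float) -> float:
        return params.beta_A / (1.0 + (a / params.K_rep) ** params.n_rep) \
            - params.d_A * a

    hi = params.beta_A / params.d_A
    # g(0) = beta_A > 0, g(hi) <= 0: bracketing is guaranteed
    root = brentq(g, 0.0, hi, xtol=1e-14, rtol=1e-12, maxiter=200)
    return float(root)


def linear_stability(params: CircuitParams):
    """Steady state, delayed loop gain b, and critical delay tau_c.

    Linearizing dA/dt = beta_A f(A(t-tau)) - d_A A about A* gives
    b = beta_A f'(A*).  A delay-induced Hopf bifurcation exists only when
    |b| > d_A, at tau_c = arccos(-d_A/|b|) / sqrt(b^2 - d_A^2); otherwise
    tau_c is infinite and the fixed point is stable for every delay.
    """
    a_star = steady_state(params)
    n, K = params.n_rep, params.K_rep
    if a_star > 0:
        u = (a_star / K) ** n
        fprime = -(n / a_star) * u / (1.0 + u) ** 2
    else:
        fprime = -1.0 / K if n == 1 else 0.0
    b = params.beta_A * fprime
    if abs(b) <= params.d_A:
        tau_c = math.inf
    else:
        tau_c = math.acos(-params.d_A / abs(b)) / math.sqrt(b * b - params.d_A ** 2)
    return a_star, float(b), float(tau_c)


def simulate(params: CircuitParams, init: CircuitState,
             schedule: SulfurSchedule, horizon: float, dt: float) -> Trajectory:
    """Integrate the circuit with RK4 and the method of steps.

    History before t = 0 is held constant at ``init``.  Impulse events add
    their amount to S at the nearest grid point.  Requires dt <= tau/10
    when tau > 0 so the delayed term is resolved.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if params.tau > 0 and dt > params.tau / 10.0 + 1e-12:
        raise ValueError(f"dt={dt} too large: need dt <= tau/10 = {params.tau / 10.0}")

    n_steps = int(round(horizon / dt))
    times = np.arange(n_steps + 1) * dt

    A = np.empty(n_steps + 1)
    As = np.empty(n_steps + 1)
    S = np.empty(n_steps + 1)
    G = np.empty(n_steps + 1)

    event_add = np.zeros(n_steps + 1)
    for t_ev, amount in schedule.events:
        idx = int(round(t_ev / dt))
        if idx > n_steps:
            raise ValueError(f"event at t={t_ev} beyond horizon {horizon}")
        event_add[idx] += amount

    p = params
    tau, feed = p.tau, schedule.baseline_input
    beta_A, K_rep, n_rep, d_A = p.beta_A, p.K_rep, p.n_rep, p.d_A
    k_mod, k_red, d_S = p.k_mod, p.k_red, p.d_S
    beta_G, K_act, n_act, d_G = p.beta_G, p.K_act, p.n_act, p.d_G
    alpha_K = p.alpha_K
    init_p_adpA = 1.0 / (1.0 + ((init.A + init.As / alpha_K) / K_rep) ** n_rep)
    # Stored time derivatives of A and As enable cubic Hermite history
    # interpolation, keeping the method-of-steps integration 4th order.
    # Impulse events kink the derivative, so left/right limits are kept
    # separately: interval [j, j+1] interpolates with the right-limit at j
    # and the left-limit at j+1.
    dA_r = np.empty(n_steps + 1)
    dAs_r = np.empty(n_steps + 1)
    dA_l = np.empty(n_steps + 1)
    dAs_l = np.empty(n_steps + 1)

    def delayed_p_adpA(tq: float) -> float:
        """P_adpA activity at time tq <= current t from stored history."""
        if tq <= 0.0:
            return init_p_adpA
        j = tq / dt
        j0 = int(j)
        w = j - j0
        if w == 0.0:
            a, s = A[j0], As[j0]
        else:
            w2 = w * w
            w3 = w2 * w
            h00 = 2 * w3 - 3 * w2 + 1
            h10 = w3 - 2 * w2 + w
            h01 = -2 * w3 + 3 * w2
            h11 = w3 - w2
            a = (h00 * A[j0] + h10 * dt * dA_r[j0]
                 + h01 * A[j0 + 1] + h11 * dt * dA_l[j0 + 1])
            s = (h00 * As[j0] + h10 * dt * dAs_r[j0]
                 + h01 * As[j0 + 1] + h11 * dt * dAs_l[j0 + 1])
            a = max(a, 0.0)
            s = max(s, 0.0)
        return 1.0 / (1.0 + ((a + s / alpha_K) / K_rep) ** n_rep)

    def deriv(a, as_, s, g, p_rep):
        r = a + as_ / alpha_K
        v = (r / K_act) ** n_act
        flux = k_mod * a * s
        return (beta_A * p_rep - d_A * a - flux + k_red * as_,
                flux - (k_red + d_A) * as_,
                feed - flux - d_S * s,
                beta_G * v / (1.0 + v) - d_G * g)

    y0, y1, y2, y3 = init.A, init.As, init.S, init.G
    for i in range(n_steps + 1):
        t = times[i]
        if tau > 0.0 and event_add[i] != 0.0:
            dl = deriv(y0, y1, y2, y3, delayed_p_adpA(t - tau))
            dA_l[i], dAs_l[i] = dl[0], dl[1]
        y2 += event_add[i]
        A[i], As[i], S[i], G[i] = y0, y1, y2, y3
        if tau > 0.0:
            d0 = deriv(y0, y1, y2, y3, delayed_p_adpA(t - tau))
            dA_r[i], dAs_r[i] = d0[0], d0[1]
            if event_add[i] == 0.0:
                dA_l[i], dAs_l[i] = d0[0], d0[1]
        if i == n_steps:
            break
        # substep when the modification flux stiffens the system (big S pulse)
        lam = d_A + d_S + k_red + k_mod * (y0 + y2)
        m = max(1, min(1000, int(dt * lam / 0.5) + 1))
        h = dt / m
        for k in range(m):
            ts = t + k * h
            if tau == 0.0:
                def p_rep_at(a, as_):
                    return 1.0 / (1.0 + ((a + as_ / alpha_K) / K_rep) ** n_rep)
                k1 = deriv(y0, y1, y2, y3, p_rep_at(y0, y1))
                a_, b_, c_, d_ = (y0 + 0.5 * h * k1[0], y1 + 0.5 * h * k1[1],
                                  y2 + 0.5 * h * k1[2], y3 + 0.5 * h * k1[3])
                k2 = deriv(a_, b_, c_, d_, p_rep_at(a_, b_))
                a_, b_, c_, d_ = (y0 + 0.5 * h * k2[0], y1 + 0.5 * h * k2[1],
                                  y2 + 0.5 * h * k2[2], y3 + 0.5 * h * k2[3])
                k3 = deriv(a_, b_, c_, d_, p_rep_at(a_, b_))
                a_, b_, c_, d_ = (y0 + h * k3[0], y1 + h * k3[1],
                                  y2 + h * k3[2], y3 + h * k3[3])
                k4 = deriv(a_, b_, c_, d_, p_rep_at(a_, b_))
            else:
                r0 = delayed_p_adpA(ts - tau)
                rh = delayed_p_adpA(ts + 0.5 * h - tau)
                r1 = delayed_p_adpA(ts + h - tau)
                k1 = deriv(y0, y1, y2, y3, r0)
                k2 = deriv(y0 + 0.5 * h * k1[0], y1 + 0.5 * h * k1[1],
                           y2 + 0.5 * h * k1[2], y3 + 0.5 * h * k1[3], rh)
                k3 = deriv(y0 + 0.5 * h * k2[0], y1 + 0.5 * h * k2[1],
                           y2 + 0.5 * h * k2[2], y3 + 0.5 * h * k2[3], rh)
                k4 = deriv(y0 + h * k3[0], y1 + h * k3[1],
                           y2 + h * k3[2], y3 + h * k3[3], r1)
            y0 += (h / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            y1 += (h / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            y2 += (h / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            y3 += (h / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            if min(y0, y1, y2, y3) < -_NEG_TOL:
                raise RuntimeError(
                    "state went negative beyond tolerance at "
                    f"t={ts + h:.3f}: {(y0, y1, y2, y3)}")
            y0, y1, y2, y3 = (max(y0, 0.0), max(y1, 0.0),
                              max(y2, 0.0), max(y3, 0.0))

    return Trajectory(times=times, A=A, As=As, S=S, G=G,
                      params_used=params, schedule_used=schedule)


def detect_oscillation(traj: Trajectory,
                       discard_fraction: float = 0.3) -> OscillationSummary:
    """Peak statistics of A after discarding the initial transient.

    Peaks are strict local maxima of A above the midrange of the retained
    window; the oscillation counts as sustained when the last two peak
    amplitudes agree within 20%.
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    if len(traj.times) < 3:
        raise ValueError("trajectory too short (< 3 points)")
    t_end = traj.times[-1]
    mask = traj.times >= discard_fraction * t_end
    a = traj.A[mask]
    t = traj.times[mask]
    if len(a) < 3:
        raise ValueError("retained window too short (< 3 points)")
    lo, hi = float(a.min()), float(a.max())
    thr = 0.5 * (lo + hi)
    interior = np.arange(1, len(a) - 1)
    is_peak = (a[interior] > a[interior - 1]) & (a[interior] > a[interior + 1]) \
        & (a[interior] > thr)
    peaks = interior[is_peak]
    n_peaks = int(len(peaks))
    amplitudes = a[peaks] - lo
    period = float(np.mean(np.diff(t[peaks]))) if n_peaks >= 2 else math.nan
    amp_mean = float(np.mean(amplitudes)) if n_peaks else 0.0
    sustained = False
    if n_peaks >= 2:
        a1, a2 = amplitudes[-2], amplitudes[-1]
        sustained = bool(abs(a2 - a1) <= 0.2 * max(a1, a2))
    return OscillationSummary(n_peaks=n_peaks, period_mean=period,
                              amplitude_mean=amp_mean, sustained=sustained)


def default_init(params: CircuitParams) -> CircuitState:
    """Sulfur-free fixed point: A at steady state, G at its matched level."""
    a_star = steady_state(params)
    _, p_tgt = _activities(a_star, 0.0, params)
    g = params.beta_G * p_tgt / params.d_G if params.d_G > 0 else 0.0
    return CircuitState(A=a_star, As=0.0, S=0.0, G=g)


def pulse_response(params: CircuitParams, pulse: SulfurSchedule,
                   horizon: float, dt: float,
                   init: CircuitState | None = None) -> PulseComparison:
    """Compare a pulsed simulation against the pulse-free baseline.

    Both runs share params, init, horizon and dt; metrics are computed on
    the window from the first pulse event onward.  ``G_delay`` is the lag
    between A first exceeding the baseline's maximum and G doing the same
    (0 when neither run ever exceeds baseline, as with an empty schedule).
    """
    for t_ev, _ in pulse.events:
        if t_ev > horizon:
            raise ValueError(f"pulse at t={t_ev} beyond horizon {horizon}")
    if init is None:
        init = default_init(params)
    baseline_sched = SulfurSchedule(events=(), baseline_input=pulse.baseline_input)
    base = simulate(params, init, baseline_sched, horizon, dt)
    puls = simulate(params, init, pulse, horizon, dt)

    t0 = min((t for t, _ in pulse.events), default=0.0)
    w = base.times >= t0
    max_A_base = float(base.A[w].max())
    max_G_base = float(base.G[w].max())
    peak_A_ratio = float(puls.A[w].max()) / max_A_base
    dominance = float(dt * np.count_nonzero(puls.As[w] > puls.A[w]))

    tw = puls.times[w]
    exceed_A = tw[puls.A[w] > max_A_base * (1 + 1e-12)]
    exceed_G = tw[puls.G[w] > max_G_base * (1 + 1e-12)]
    if len(exceed_A) and len(exceed_G):
        g_delay = float(exceed_G[0] - exceed_A[0])
    else:
        g_delay = 0.0

    gain = float(np.trapezoid(puls.G[w], tw) / np.trapezoid(base.G[w], tw))
    return PulseComparison(peak_A_ratio=peak_A_ratio,
                           dominance_interval=dominance,
                           G_delay=g_delay, G_gain=gain)
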