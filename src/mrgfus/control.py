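"""Ramp-and-hold hyperthermia protocol on a lumped bioheat surrogate.

The treatment logic being modeled: sonicate at maximum power for 2 minutes to
raise the target from 37 to 45 °C, then reduce the power to a small fraction
(10-15% of maximum) and hold 45 °C for 30 minutes.

The tissue is a single thermal compartment obeying

    dT/dt = a * P - (T - T_base) / tau_cool

with ``P`` the commanded power fraction in [0, 1], ``a`` the heating gain
(°C/s at full power) and ``tau_cool`` the perfusion/conduction cooling time
constant.  This is a lumped Pennes-type surrogate: the protocol logic (ramp,
hold band, feedback cadence) is the content, not spatial heat transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BioheatParams",
    "ProtocolState",
    "bioheat_step",
    "calibrate",
    "run_protocol",
    "DEFAULT_TAU_COOL_S",
]

#: Default cooling time constant (s).  Chosen so that the steady-state power
#: fraction needed to hold 45 °C with the 2-min-ramp-calibrated gain falls at
#: the middle of the protocol's 10-15% hold band (exactly 12.5% at 898.6 s;
#: 900 s keeps it at 12.49%).  See docs/methods.md.
DEFAULT_TAU_COOL_S = 900.0


@dataclass
class BioheatParams:
    """Lumped bioheat parameters.

    Attributes
    ----------
    a : float
        Heating gain at full power, °C/s.
    tau_cool_s : float
        Exponential cooling time constant, s.
    T_base : float
        Baseline (body) temperature, °C.
    """

    a: float
    tau_cool_s: float
    T_base: float = 37.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.tau_cool_s <= 0:
            raise ValueError("gain and time constant must be positive")

    def steady_state(self, P: float) -> float:
        """Equilibrium temperature under constant power fraction P."""
        return self.T_base + self.a * self.tau_cool_s * P


def bioheat_step(T: float, P: float, params: BioheatParams, dt: float) -> float:
    """Advance the compartment temperature by one explicit Euler step.

    Requires ``dt <= tau_cool/10`` for stability/accuracy of the explicit
    scheme.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > params.tau_cool_s / 10:
        raise ValueError(f"dt={dt} too large for tau_cool={params.tau_cool_s}")
    return T + dt * (params.a * P - (T - params.T_base) / params.tau_cool_s)


def calibrate(tau_cool_s: float = DEFAULT_TAU_COOL_S,
              delta_T: float = 8.0,
              ramp_s: float = 120.0,
              T_base: float = 37.0) -> BioheatParams:
    """Solve for the gain that reaches ``T_base + delta_T`` in ``ramp_s`` at P=1.

    From the linear ODE, full power from baseline gives
    ``T(t) = T_base + a*tau*(1 - exp(-t/tau))``; inverting at ``t = ramp_s``:

        a = delta_T / (tau * (1 - exp(-ramp_s / tau)))
    """
    if tau_cool_s <= 0 or ramp_s <= 0 or delta_T <= 0:
        raise ValueError("infeasible ramp specification")
    a = delta_T / (tau_cool_s * (1.0 - np.exp(-ramp_s / tau_cool_s)))
    return BioheatParams(a=a, tau_cool_s=tau_cool_s, T_base=T_base)


@dataclass
class ProtocolState:
    """Logged protocol trajectory at integration resolution."""

    time_s: np.ndarray
    temp_C: np.ndarray
    power_fraction: np.ndarray
    phase: np.ndarray  # str array: ramp | hold | cooldown

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.temp_C) == len(self.power_fraction) == len(self.phase) == n):
            raise ValueError("trace arrays must share length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s,
            "temp_C": self.temp_C,
            "power_fraction": self.power_fraction,
            "phase": self.phase,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def hold_trace(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["phase"] == "hold"]

    def crossing_time(self, target: float) -> float:
        """First time the true temperature reaches ``target`` (linear interp)."""
        above = np.nonzero(self.temp_C >= target)[0]
        if len(above) == 0:
            raise ValueError(f"temperature never reaches {target}")
        i = above[0]
        if i == 0:
            return float(self.time_s[0])
        t0, t1 = self.time_s[i - 1], self.time_s[i]
        y0, y1 = self.temp_C[i - 1], self.temp_C[i]
        return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))


def run_protocol(params: BioheatParams,
                 target_C: float = 45.0,
                 hold_s: float = 1800.0,
                 cooldown_s: float = 0.0,
                 control_interval_s: float = 55.0,
                 dt: float = 1.0,
                 power_band: tuple[float, float] = (0.10, 0.15),
                 controller: str = "hysteresis",
                 feedback_noise_sd_C: float = 0.0,
                 rng: np.random.Generator | int | None = None) -> ProtocolState:
    """Simulate the ramp-and-hold protocol.

    Ramp: full power (P=1) until the temperature reaches ``target_C`` (with
    calibrated parameters this takes the protocol's 2 minutes).  Hold: a
    controller updates P at the imaging cadence ``control_interval_s`` —
    matching the sonicate-then-image loop — using the measured temperature
    (true temperature plus optional Gaussian probe noise).  The hysteresis
    controller commands the low band edge when the measurement is at/above
    target and the high edge otherwise; the proportional alternative clips
    ``P = P_mid + 0.05*(target - measured)`` into the band.  An optional
    cooldown phase at P=0 follows.

    Raises a diagnostic error if the hold target is unreachable inside the
    power band (target outside the band's steady-state range).
    """
    lo, hi = power_band
    if not (0 <= lo < hi <= 1):
        raise ValueError("power band must satisfy 0 <= lo < hi <= 1")
    if params.steady_state(1.0) < target_C:
        raise ValueError("target unreachable even at full power")
    if not (params.steady_state(lo) <= target_C <= params.steady_state(hi)):
        raise ValueError(
            f"hold at {target_C} °C infeasible with P in [{lo}, {hi}]: "
            f"steady-state range is [{params.steady_state(lo):.2f}, "
            f"{params.steady_state(hi):.2f}] °C; adjust tau_cool or the band")
    if controller not in ("hysteresis", "proportional"):
        raise ValueError(f"unknown controller {controller!r}")
    rng = np.random.default_rng(rng)

    times, temps, powers, phases = [0.0], [params.T_base], [1.0], ["ramp"]
    T, t = params.T_base, 0.0

    # Open-loop ramp at maximum power until the target is first reached.
    max_ramp_s = 20 * params.tau_cool_s
    while T < target_C:
        T = bioheat_step(T, 1.0, params, dt)
        t += dt
        times.append(t)
        temps.append(T)
        powers.append(1.0)
        phases.append("ramp")
        if t > max_ramp_s:
            raise RuntimeError("ramp failed to reach target")

    def _command(measured: float, current: float) -> float:
        if controller == "hysteresis":
            return lo if measured >= target_C else hi
        mid = 0.5 * (lo + hi)
        return float(np.clip(mid + 0.05 * (target_C - measured), lo, hi))

    t_hold_end = t + hold_s
    next_decision = t
    P = lo  # arriving at target from a full-power ramp: back off first
    while t < t_hold_end - 1e-9:
        if t >= next_decision - 1e-9:
            measured = T + (feedback_noise_sd_C * rng.standard_normal()
                            if feedback_noise_sd_C > 0 else 0.0)
            P = _command(measured, P)
            next_decision += control_interval_s
        T = bioheat_step(T, P, params, dt)
        t += dt
        times.append(t)
        temps.append(T)
        powers.append(P)
        phases.append("hold")

    t_cool_end = t + cooldown_s
    while t < t_cool_end - 1e-9:
        T = bioheat_step(T, 0.0, params, dt)
        t += dt
        times.append(t)
        temps.append(T)
        powers.append(0.0)
        phases.append("cooldown")

    return ProtocolState(np.asarray(times), np.asarray(temps),
                         np.asarray(powers), np.asarray(phases, dtype=object))
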