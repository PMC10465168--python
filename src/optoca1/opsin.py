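"""ChR2(H134R) photocurrent kinetics: the double two-state ("RSRS") model.

The opsin is described by two independent first-order gates: ``O``, the
open fraction of the channel population, and ``R``, a slow dark-light
adaptation factor.  Both relax toward irradiance-dependent steady states
with time constants that combine an irradiance- and a voltage-dependent
component harmonically.  The transmembrane current density is

    i_ChR2 = g_ChR2 * D(V) * O * R      (mA/cm^2)

where ``D(V) = 1 - 1.25*exp(-(V - E_ChR2)/44.52)`` is the inward-rectifying
driving term and ``G(V) = D(V)/(V - E_ChR2)`` the rectification function.
``G`` has a removable singularity at ``V = E_ChR2``; the current always
uses ``D`` directly.

Units: irradiance in mW/mm^2, time in ms, voltage in mV, current density
in mA/cm^2, specific conductance in S/cm^2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpsinParams",
    "OpsinState",
    "chr2_h134r_rsrs_final",
    "rectified_driving",
    "steady_states",
    "time_constants",
    "step_state",
    "photocurrent_density",
    "voltage_clamp_protocol",
]

# Time constants are floored at this value (ms) so the harmonic combination
# and the exponential-Euler update stay finite when a component tau
# approaches zero at saturating irradiance.
_TAU_FLOOR = 1e-9


@dataclass(frozen=True)
class OpsinParams:
    """All numeric constants of the RSRS ChR2(H134R) model.

    Every coefficient of the steady-state and time-constant expressions is a
    field, so a revised parameterization is a configuration change rather
    than a code change.  The irradiance-dependent expressions follow the
    pattern ``a / (1 + exp(b) * Irr**c)``.
    """

    g_chr2: float = 1.0  # specific conductance, S/cm^2
    e_chr2: float = 0.0  # reversal parameter, mV

    # D(V) = 1 - rect_amp * exp(-(V - e_chr2)/rect_vscale)
    rect_amp: float = 1.25
    rect_vscale: float = 44.52  # mV

    # O_inf(Irr) = 1 / (1 + exp(o_inf_b) * Irr**o_inf_c)
    o_inf_b: float = 5.45
    o_inf_c: float = -0.70

    # R_inf(Irr) = 1 - r_inf_a / (1 + exp(r_inf_b) * Irr**r_inf_c)
    r_inf_a: float = 0.77
    r_inf_b: float = 16.33
    r_inf_c: float = -3.62

    # tau_O(Irr) = tau_o_amp / (1 + exp(tau_o_b) * Irr**tau_o_c)   [ms]
    tau_o_amp: float = 0.021
    tau_o_b: float = 1.55
    tau_o_c: float = 0.37

    # tau_O(V) = tau_ov_amp / (1 + exp(-(V - tau_ov_vhalf)/tau_ov_k))   [ms]
    tau_ov_amp: float = 23.14
    tau_ov_vhalf: float = -0.39
    tau_ov_k: float = 13.19

    # tau_R(Irr) = tau_r_amp * (1 - a1/(1+exp(b1)*Irr**c1)
    #                             - a2/(1+exp(b2)*Irr**c2))   [ms]
    tau_r_amp: float = 10.0
    tau_r_a1: float = 0.56
    tau_r_b1: float = -1.82
    tau_r_c1: float = -0.50
    tau_r_a2: float = 0.44
    tau_r_b2: float = 17.82
    tau_r_c2: float = -3.95

    # tau_R(V) = tau_rv_amp / (1 + exp(-(V - tau_rv_vhalf)/tau_rv_k))   [ms]
    tau_rv_amp: float = 99.74
    tau_rv_vhalf: float = -38.69
    tau_rv_k: float = 12.02

    def __post_init__(self) -> None:
        if self.g_chr2 < 0:
            raise ValueError("g_chr2 must be >= 0")
        for name in ("tau_o_amp", "tau_ov_amp", "tau_r_amp", "tau_rv_amp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {"chr2_h134r_rsrs_final": dataclasses.asdict(self)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "OpsinParams":
        if "chr2_h134r_rsrs_final" in d:
            d = d["chr2_h134r_rsrs_final"]
        return cls(**d)


def chr2_h134r_rsrs_final(**overrides) -> OpsinParams:
    """The default ChR2(H134R) parameter set, optionally with overrides."""
    return OpsinParams(**overrides)


@dataclass
class OpsinState:
    """Gating state of the opsin population: open fraction and adaptation."""

    O: np.ndarray | float = 0.0
    R: np.ndarray | float = 1.0

    def validate(self) -> None:
        O = np.asarray(self.O, dtype=float)
        R = np.asarray(self.R, dtype=float)
        if np.any(O < -1e-12) or np.any(O > 1 + 1e-12):
            raise ValueError("open fraction O outside [0, 1]")
        if np.any(R < -1e-12) or np.any(R > 1 + 1e-12):
            raise ValueError("adaptation factor R outside [0, 1]")

    @classmethod
    def dark_adapted(cls, n: int | None = None) -> "OpsinState":
        """Resting state in darkness: all channels closed, fully recovered."""
        if n is None:
            return cls(0.0, 1.0)
        return cls(np.zeros(n), np.ones(n))


def rectified_driving(V, params: OpsinParams | None = None):
    """Driving term D(V) and rectification function G(V) = D(V)/(V - E).

    ``D`` is finite everywhere; ``G`` has a removable singularity at
    ``V = E_ChR2`` and is returned as NaN there (the photocurrent uses ``D``
    directly, so the singularity never enters the current).
    """
    p = params or _DEFAULT
    V = np.asarray(V, dtype=float)
    dv = V - p.e_chr2
    D = 1.0 - p.rect_amp * np.exp(-dv / p.rect_vscale)
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(dv != 0.0, D / np.where(dv != 0.0, dv, 1.0), np.nan)
    if V.ndim == 0:
        return float(D), float(G)
    return D, G


def _sigmoid_fraction(irr, b, c):
    """a=1 fraction 1/(1 + exp(b)*Irr**c), with the Irr->0 limit handled."""
    irr = np.asarray(irr, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        powered = np.where(irr > 0, irr, 1.0) ** c
        # Irr -> 0+ limit: Irr**c diverges for c < 0 (fraction -> 0) and
        # vanishes for c > 0 (fraction -> 1)
        powered = np.where(irr > 0, powered, np.inf if c < 0 else 0.0)
        term = np.exp(b) * powered
    return np.asarray(1.0 / (1.0 + term))


def steady_states(irr, params: OpsinParams | None = None):
    """Steady-state gate values (O_inf, R_inf) at irradiance ``irr``.

    O_inf rises from 0 (dark) to 1; R_inf falls from 1 toward
    ``1 - r_inf_a`` at saturating light.
    """
    p = params or _DEFAULT
    irr = np.asarray(irr, dtype=float)
    if np.any(irr < 0):
        raise ValueError("irradiance must be >= 0")
    o_inf = _sigmoid_fraction(irr, p.o_inf_b, p.o_inf_c)
    r_inf = 1.0 - p.r_inf_a * _sigmoid_fraction(irr, p.r_inf_b, p.r_inf_c)
    if irr.ndim == 0:
        return float(o_inf), float(r_inf)
    return o_inf, r_inf


def time_constants(irr, V, params: OpsinParams | None = None):
    """Harmonically combined (tau_O, tau_R) in ms at (irr, V)."""
    p = params or _DEFAULT
    irr = np.asarray(irr, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(irr < 0):
        raise ValueError("irradiance must be >= 0")

    tau_o_irr = p.tau_o_amp * _sigmoid_fraction(irr, p.tau_o_b, p.tau_o_c)
    tau_o_v = p.tau_ov_amp / (1.0 + np.exp(-(V - p.tau_ov_vhalf) / p.tau_ov_k))

    tau_r_irr = p.tau_r_amp * (
        1.0
        - p.tau_r_a1 * _sigmoid_fraction(irr, p.tau_r_b1, p.tau_r_c1)
        - p.tau_r_a2 * _sigmoid_fraction(irr, p.tau_r_b2, p.tau_r_c2)
    )
    tau_r_v = p.tau_rv_amp / (1.0 + np.exp(-(V - p.tau_rv_vhalf) / p.tau_rv_k))

    tau_o = _harmonic(tau_o_irr, tau_o_v)
    tau_r = _harmonic(tau_r_irr, tau_r_v)
    if irr.ndim == 0 and V.ndim == 0:
        return float(tau_o), float(tau_r)
    return tau_o, tau_r


def _harmonic(tau_a, tau_b):
    tau_a = np.maximum(tau_a, _TAU_FLOOR)
    tau_b = np.maximum(tau_b, _TAU_FLOOR)
    return 1.0 / (1.0 / tau_a + 1.0 / tau_b)


def step_state(state: OpsinState, irr, V, dt: float,
               params: OpsinParams | None = None) -> OpsinState:
    """Advance both gates by one exponential-Euler step of length ``dt`` ms.

    X <- X_inf + (X - X_inf) * exp(-dt/tau_X).  Exact for piecewise-constant
    (irr, V), unconditionally stable, and keeps X inside [min(X, X_inf),
    max(X, X_inf)] so the state stays boxed in [0, 1]^2.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params or _DEFAULT
    o_inf, r_inf = steady_states(irr, p)
    tau_o, tau_r = time_constants(irr, V, p)
    fo = np.exp(-dt / np.asarray(tau_o))
    fr = np.exp(-dt / np.asarray(tau_r))
    O = o_inf + (state.O - o_inf) * fo
    R = r_inf + (state.R - r_inf) * fr
    new = OpsinState(O, R)
    new.validate()
    return new


def photocurrent_density(state: OpsinState, V, params: OpsinParams | None = None):
    """Transmembrane photocurrent density i_ChR2 (mA/cm^2).

    i = g_ChR2 * D(V) * O * R; negative (inward, depolarizing) below the
    zero of D at V* = E_ChR2 + 44.52*ln(1.25) ~ 9.93 mV.
    """
    p = params or _DEFAULT
    D, _ = rectified_driving(V, p)
    return p.g_chr2 * D * np.asarray(state.O) * np.asarray(state.R)


def voltage_clamp_protocol(v_clamp: float, irr: float, pd: float,
                           t0: float = 10.0, t_end: float | None = None,
                           dt: float = 0.025,
                           params: OpsinParams | None = None):
    """Simulate a voltage-clamp light-pulse protocol from dark adaptation.

    A single rectangular light pulse of duration ``pd`` ms and irradiance
    ``irr`` starts at ``t0``; the membrane is clamped at ``v_clamp`` mV
    throughout.  Returns ``(t, O, R, i)`` arrays plus the peak and
    steady-state current magnitudes during the pulse (steady state taken at
    pulse end).
    """
    if pd <= 0:
        raise ValueError("pd must be > 0")
    p = params or _DEFAULT
    if t_end is None:
        t_end = t0 + pd + 100.0
    n = int(round(t_end / dt)) + 1
    t = np.arange(n) * dt
    O = np.empty(n)
    R = np.empty(n)
    state = OpsinState.dark_adapted()
    O[0], R[0] = state.O, state.R
    for k in range(1, n):
        irr_k = irr if (t[k - 1] >= t0 and t[k - 1] < t0 + pd) else 0.0
        state = step_state(state, irr_k, v_clamp, dt, p)
        O[k], R[k] = state.O, state.R
    D, _ = rectified_driving(v_clamp, p)
    i = p.g_chr2 * D * O * R
    in_pulse = (t >= t0) & (t <= t0 + pd)
    if np.any(in_pulse):
        peak = float(np.max(np.abs(i[in_pulse])))
        steady = float(np.abs(i[in_pulse][-1]))
    else:  # pragma: no cover - contract requires pd > 0
        peak = steady = 0.0
    return t, O, R, i, peak, steady


def export_trace_csv(path, t, O, R, i) -> None:
    """Write a (t, O, R, i) clamp trace as CSV."""
    arr = np.column_stack([t, O, R, i])
    np.savetxt(path, arr, delimiter=",", header="t_ms,O,R,i_mA_per_cm2",
               comments="")


_DEFAULT = OpsinParams()
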