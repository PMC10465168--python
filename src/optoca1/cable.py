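"""Multicompartment membrane solver with opsin photocurrent coupling.

Each morphology segment is a compartment with membrane capacitance, leak,
and Hodgkin-Huxley-style spiking conductances (transient Na and delayed
rectifier K, densities scaled per region with axon > soma > dendrites).
The ChR2 photocurrent of :mod:`optoca1.opsin` enters each compartment
scaled by the local irradiance (fiber-field gain x fiber intensity, or a
uniform irradiance).

Numerics: backward Euler on the branched-tree linear system (Hines
elimination, exact O(n) per step), with gating variables advanced by
exponential Euler one half-step behind the voltage.  The photocurrent's
voltage dependence is linearized around the previous voltage each step;
its slope is nonnegative, which preserves diagonal dominance.

Units: mV, ms, nA, uS, nF internally; membrane densities are specified in
S/cm^2 and uF/cm^2 and converted at assembly time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .morphology import Morphology
from .opsin import OpsinParams

__all__ = [
    "MembraneModel",
    "StimulusProtocol",
    "SimResult",
    "simulate",
    "detect_spike",
    "input_impedance",
]

SPIKE_THRESHOLD_MV = -10.0  # somatic crossing level defining an action potential


@dataclass(frozen=True)
class MembraneModel:
    """Passive properties plus simplified per-region spiking conductances."""

    cm: float = 1.0          # uF/cm^2
    ra: float = 150.0        # axial resistivity, Ohm*cm
    g_leak: float = 0.0003   # S/cm^2
    e_leak: float = -70.0    # mV
    e_na: float = 50.0
    e_k: float = -77.0
    gna: dict = field(default_factory=lambda: {
        "axon": 0.30, "soma": 0.12, "basal": 0.03, "apic": 0.03, "dend": 0.03})
    gk: dict = field(default_factory=lambda: {
        "axon": 0.06, "soma": 0.036, "basal": 0.01, "apic": 0.01, "dend": 0.01})

    def __post_init__(self) -> None:
        if self.cm <= 0 or self.ra <= 0 or self.g_leak < 0:
            raise ValueError("cm, ra must be > 0 and g_leak >= 0")
        if any(v < 0 for v in self.gna.values()) or \
           any(v < 0 for v in self.gk.values()):
            raise ValueError("channel densities must be >= 0")

    def passive(self) -> "MembraneModel":
        return MembraneModel(cm=self.cm, ra=self.ra, g_leak=self.g_leak,
                             e_leak=self.e_leak,
                             gna={k: 0.0 for k in self.gna},
                             gk={k: 0.0 for k in self.gk})


@dataclass(frozen=True)
class StimulusProtocol:
    """Single rectangular light pulse."""

    pd: float = 10.0         # pulse duration, ms
    t0: float = 100.0        # onset (after a settling period), ms
    i_fiber: float = 1.0     # fiber-face irradiance, mW/mm^2

    def __post_init__(self) -> None:
        if self.pd <= 0:
            raise ValueError("pd must be > 0")
        if self.i_fiber < 0:
            raise ValueError("I_fiber must be >= 0")

    @property
    def t_end(self) -> float:
        """max(500 ms, t0 + pd + 100 ms): long enough for channel closure."""
        return max(500.0, self.t0 + self.pd + 100.0)


@dataclass
class SimResult:
    t: np.ndarray                 # ms
    v_soma: np.ndarray            # mV
    chr2_time_integral: np.ndarray  # per segment, mA/cm^2 * ms over [t0, end]
    v_all: np.ndarray | None = None      # (nseg, nt) if recorded
    i_chr2: np.ndarray | None = None     # (nseg, nt) mA/cm^2 if recorded
    protocol: StimulusProtocol | None = None


def _opsin_const_vector(p: OpsinParams) -> np.ndarray:
    return np.array([
        p.e_chr2, p.rect_amp, p.rect_vscale,
        p.o_inf_b, p.o_inf_c, p.r_inf_a, p.r_inf_b, p.r_inf_c,
        p.tau_o_amp, p.tau_o_b, p.tau_o_c,
        p.tau_ov_amp, p.tau_ov_vhalf, p.tau_ov_k,
        p.tau_r_amp, p.tau_r_a1, p.tau_r_b1, p.tau_r_c1,
        p.tau_r_a2, p.tau_r_b2, p.tau_r_c2,
        p.tau_rv_amp, p.tau_rv_vhalf, p.tau_rv_k,
    ])


@njit(cache=True, fastmath=True, inline="always")
def _frac(irr, b, c):
    if irr <= 0.0:
        return 0.0 if c < 0 else 1.0
    return 1.0 / (1.0 + np.exp(b) * irr ** c)


@njit(cache=True, fastmath=True)
def _opsin_rates(irr, v, oc):
    """(o_inf, r_inf, tau_o, tau_r) at one (irradiance, voltage) point."""
    o_inf = _frac(irr, oc[3], oc[4])
    r_inf = 1.0 - oc[5] * _frac(irr, oc[6], oc[7])
    tau_o_irr = oc[8] * _frac(irr, oc[9], oc[10])
    tau_o_v = oc[11] / (1.0 + np.exp(-(v - oc[12]) / oc[13]))
    tau_r_irr = oc[14] * (1.0 - oc[15] * _frac(irr, oc[16], oc[17])
                          - oc[18] * _frac(irr, oc[19], oc[20]))
    tau_r_v = oc[21] / (1.0 + np.exp(-(v - oc[22]) / oc[23]))
    floor = 1e-9
    if tau_o_irr < floor:
        tau_o_irr = floor
    if tau_o_v < floor:
        tau_o_v = floor
    if tau_r_irr < floor:
        tau_r_irr = floor
    if tau_r_v < floor:
        tau_r_v = floor
    tau_o = 1.0 / (1.0 / tau_o_irr + 1.0 / tau_o_v)
    tau_r = 1.0 / (1.0 / tau_r_irr + 1.0 / tau_r_v)
    return o_inf, r_inf, tau_o, tau_r


@njit(cache=True, fastmath=True, inline="always")
def _vtrap(x, y):
    # x/(1-exp(-x/y)) with the removable singularity handled
    if np.abs(x / y) < 1e-6:
        return y
    return x / (1.0 - np.exp(-x / y))


@njit(cache=True, fastmath=True)
def _hh_rates(v):
    """Classic HH rate constants (1/ms) shifted to a ~-65 mV resting frame."""
    a_m = 0.1 * _vtrap(v + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    a_n = 0.01 * _vtrap(v + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


@njit(cache=True, fastmath=True)
def _step_gates(v, m, h, n, O, R, irr, dt, oc, has_chr2):
    nseg = v.shape[0]
    for i in range(nseg):
        a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v[i])
        tm = 1.0 / (a_m + b_m)
        th = 1.0 / (a_h + b_h)
        tn = 1.0 / (a_n + b_n)
        m[i] = a_m * tm + (m[i] - a_m * tm) * np.exp(-dt / tm)
        h[i] = a_h * th + (h[i] - a_h * th) * np.exp(-dt / th)
        n[i] = a_n * tn + (n[i] - a_n * tn) * np.exp(-dt / tn)
        if has_chr2[i]:
            o_inf, r_inf, tau_o, tau_r = _opsin_rates(irr[i], v[i], oc)
            O[i] = o_inf + (O[i] - o_inf) * np.exp(-dt / tau_o)
            R[i] = r_inf + (R[i] - r_inf) * np.exp(-dt / tau_r)


@njit(cache=True, fastmath=True)
def _cable_kernel(parent, g_ax, cap, gl, el, gna, gk, ena, ek,
                  gchr2_us, gains, oc, i_fiber, t0, pd, t_end, dt,
                  v_init, inj_seg, inj_na, inj_t0, inj_t1,
                  record_all, record_i):
    """Backward-Euler/Hines time stepper.

    Conductances in uS, capacitance in nF, currents in nA, times in ms.
    ``gchr2_us`` is the per-segment ChR2 conductance scale (uS) such that
    the photocurrent in nA is gchr2_us * D(V) * O * R.
    Returns (t, v_soma, chr2_integral_us_scaled, v_all, i_chr2_us, books)
    where chr2 integrals/traces are in nA (current) terms.
    """
    nseg = parent.shape[0]
    nt = int(np.round(t_end / dt)) + 1
    t = np.arange(nt) * dt

    v = np.full(nseg, v_init)
    m = np.empty(nseg)
    h = np.empty(nseg)
    n = np.empty(nseg)
    for i in range(nseg):
        a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v_init)
        m[i] = a_m / (a_m + b_m)
        h[i] = a_h / (a_h + b_h)
        n[i] = a_n / (a_n + b_n)
    O = np.zeros(nseg)
    R = np.ones(nseg)
    irr = np.zeros(nseg)
    has_chr2 = gchr2_us > 0.0

    v_soma = np.empty(nt)
    v_soma[0] = v_init
    v_all = np.empty((nseg if record_all else 1, nt))
    i_rec = np.empty((nseg if record_i else 1, nt))
    if record_all:
        v_all[:, 0] = v
    if record_i:
        i_rec[:, 0] = 0.0
    chr2_int = np.zeros(nseg)   # trapezoid of photocurrent (nA*ms)
    i_prev = np.zeros(nseg)

    d = np.empty(nseg)
    rhs = np.empty(nseg)
    e_c = oc[0]
    amp = oc[1]
    vs = oc[2]
    max_res = 0.0

    for k in range(1, nt):
        tk = t[k - 1]
        light_on = (tk >= t0) and (tk < t0 + pd)
        for i in range(nseg):
            irr[i] = i_fiber * gains[i] if light_on else 0.0
        _step_gates(v, m, h, n, O, R, irr, dt, oc, has_chr2)

        # assemble
        for i in range(nseg):
            g_na_i = gna[i] * m[i] * m[i] * m[i] * h[i]
            g_k_i = gk[i] * n[i] ** 4
            g_sum = gl[i] + g_na_i + g_k_i
            b = (cap[i] / dt) * v[i] + gl[i] * el + g_na_i * ena + g_k_i * ek
            if has_chr2[i]:
                ex = np.exp(-(v[i] - e_c) / vs)
                i0 = gchr2_us[i] * O[i] * R[i] * (1.0 - amp * ex)
                slope = gchr2_us[i] * O[i] * R[i] * (amp / vs) * ex
                g_sum += slope
                b += -i0 + slope * v[i]
            if i == inj_seg and (tk >= inj_t0) and (tk < inj_t1):
                b += inj_na
            d[i] = cap[i] / dt + g_sum
            rhs[i] = b

        for i in range(nseg):
            if parent[i] >= 0:
                d[i] += g_ax[i]
                d[parent[i]] += g_ax[i]

        # Hines elimination (children ordered after parents)
        for i in range(nseg - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / d[i]
            d[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        v_new = np.empty(nseg)
        v_new[0] = rhs[0] / d[0]
        for i in range(1, nseg):
            v_new[i] = (rhs[i] + g_ax[i] * v_new[parent[i]]) / d[i]

        for i in range(nseg):
            if not np.isfinite(v_new[i]):
                return (t, v_soma, chr2_int, v_all, i_rec, -1.0)
            v[i] = v_new[i]

        v_soma[k] = v[0]
        if record_all:
            v_all[:, k] = v
        # photocurrent at the new state (nA per segment)
        for i in range(nseg):
            if has_chr2[i]:
                cur = gchr2_us[i] * O[i] * R[i] * \
                    (1.0 - amp * np.exp(-(v[i] - e_c) / vs))
            else:
                cur = 0.0
            if record_i:
                i_rec[i, k] = cur
            if t[k] > t0:
                chr2_int[i] += 0.5 * (cur + i_prev[i]) * dt
            i_prev[i] = cur

    return (t, v_soma, chr2_int, v_all, i_rec, max_res)


def _assemble(morph: Morphology, membrane: MembraneModel):
    seg = morph.segments()
    nseg = len(seg.area)
    area_cm2 = seg.area * 1e-8
    cap = membrane.cm * area_cm2 * 1e3            # nF
    gl = membrane.g_leak * area_cm2 * 1e6         # uS
    gna = np.array([membrane.gna.get(r, 0.0) for r in seg.region]) * area_cm2 * 1e6
    gk = np.array([membrane.gk.get(r, 0.0) for r in seg.region]) * area_cm2 * 1e6
    # axial conductance to parent (uS): series of two half-segments
    L_cm = seg.length * 1e-4
    d_cm = seg.diam * 1e-4
    half_res = membrane.ra * (L_cm / 2.0) / (np.pi * d_cm ** 2 / 4.0)  # Ohm
    g_ax = np.zeros(nseg)
    for i in range(1, nseg):
        p = seg.parent[i]
        if p >= 0:
            g_ax[i] = 1e6 / (half_res[i] + half_res[p])
    return seg, cap, gl, gna, gk, g_ax


def simulate(morph: Morphology, membrane: MembraneModel,
             opsin_distribution: np.ndarray | None,
             stimulus: StimulusProtocol,
             field=None, fiber=None, roll: float = 0.0,
             uniform: bool = False,
             dt: float = 0.025, v_init: float = -70.0,
             opsin_params: OpsinParams | None = None,
             record_all: bool = False, record_i: bool = False,
             inj_seg: int = -1, inj_na: float = 0.0,
             inj_t0: float = 0.0, inj_t1: float = 0.0) -> SimResult:
    """Simulate the morphology under a single light pulse.

    ``opsin_distribution`` is the per-segment g_ChR2 (S/cm^2), typically
    from :func:`optoca1.morphology.distribute_opsin`.  In uniform mode all
    segments receive ``stimulus.i_fiber``; otherwise each segment receives
    ``i_fiber`` times the fluence-field gain at its centroid for the given
    fiber placement.
    """
    from . import light as _light

    seg, cap, gl, gna, gk, g_ax = _assemble(morph, membrane)
    nseg = len(cap)
    if opsin_distribution is None:
        gchr2 = np.zeros(nseg)
    else:
        gchr2 = np.asarray(opsin_distribution, dtype=float)
        if gchr2.shape != (nseg,):
            raise ValueError("opsin distribution does not match segment count")
    gchr2_us = gchr2 * seg.area * 1e-8 * 1e6   # S -> uS

    if uniform or field is None:
        gains = np.ones(nseg)
    else:
        if fiber is None:
            raise ValueError("fiber placement required for field mode")
        gains = _light.segment_gains(field, seg.centroid, fiber, roll)

    oc = _opsin_const_vector(opsin_params or OpsinParams())
    out = _cable_kernel(seg.parent, g_ax, cap, gl, membrane.e_leak,
                        gna, gk, membrane.e_na, membrane.e_k,
                        gchr2_us, gains, oc,
                        stimulus.i_fiber, stimulus.t0, stimulus.pd,
                        stimulus.t_end, dt, v_init,
                        inj_seg, inj_na, inj_t0, inj_t1,
                        record_all, record_i)
    t, v_soma, chr2_int_na, v_all, i_rec, flag = out
    if flag < 0:
        raise FloatingPointError(
            "numerical divergence in cable solve "
            f"(nseg={nseg}, dt={dt}, I_fiber={stimulus.i_fiber})")
    area_cm2 = seg.area * 1e-8
    # convert integrated current (nA*ms) back to density integral (mA/cm2*ms)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens_int = np.where(area_cm2 > 0, chr2_int_na * 1e-6 / area_cm2, 0.0)
    res = SimResult(
        t=t, v_soma=v_soma, chr2_time_integral=dens_int,
        v_all=v_all if record_all else None,
        i_chr2=(i_rec * 1e-6 / area_cm2[:, None]) if record_i else None,
        protocol=stimulus)
    return res


def detect_spike(soma_trace: np.ndarray, t: np.ndarray | None = None,
                 t0: float | None = None, t_end: float | None = None) -> bool:
    """True iff the somatic voltage strictly exceeds -10 mV in the window."""
    trace = np.asarray(soma_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if t is not None and t0 is not None:
        hi = t_end if t_end is not None else np.inf
        trace = trace[(t >= t0) & (t <= hi)]
        if trace.size == 0:
            raise ValueError("window [t0, t_end] not covered by trace")
    return bool(np.max(trace) > SPIKE_THRESHOLD_MV)


def input_impedance(morph: Morphology, membrane: MembraneModel,
                    seg_index: int = 0, amp_na: float = -0.01,
                    settle_ms: float = 100.0, step_ms: float = 300.0,
                    dt: float = 0.025, v_init: float = -70.0) -> float:
    """Input impedance at 0 Hz (MOhm) at one segment.

    A small hyperpolarizing current step is applied after a settling
    period initialized at -70 mV; the impedance is delta-V / delta-I at the
    injected segment.  Raises if the measurement provokes a spike.
    """
    if amp_na == 0:
        raise ValueError("step amplitude must be nonzero")
    stim = StimulusProtocol(pd=1.0, t0=settle_ms + step_ms + 50.0, i_fiber=0.0)
    res = simulate(morph, membrane, None, stim, uniform=True, dt=dt,
                   v_init=v_init, record_all=True,
                   inj_seg=seg_index, inj_na=amp_na,
                   inj_t0=settle_ms, inj_t1=settle_ms + step_ms)
    v = res.v_all[seg_index]
    t = res.t
    if detect_spike(res.v_soma, t, 0.0, settle_ms + step_ms):
        raise RuntimeError("impedance step caused spiking; reduce amplitude")
    v_before = v[np.searchsorted(t, settle_ms) - 1]
    v_after = v[np.searchsorted(t, settle_ms + step_ms) - 1]
    return float((v_after - v_before) / amp_na)  # mV/nA = MOhm
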