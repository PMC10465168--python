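"""Threshold titration, TAC, position sweeps, SoFPAN and fiber placement.

The central metric is the surface of fiber positions for the activation of
neurons (SoFPAN): in a 2D plane of fiber placements around the cell, the
area of positions from which a single light pulse elicits a somatic action
potential.  It is the cell-centered counterpart of the volume of tissue
activated.  Thresholds are found by bisection titration; SoFPAN carries a
lower bound (grid cells fully enclosed by supra-threshold nodes) and an
upper bound (same count after 3x3 binary dilation of the node field).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ThresholdMap",
    "SofpanResult",
    "titrate_threshold",
    "compute_TAC",
    "position_grid",
    "sweep_positions",
    "sofpan",
    "sofpan_uniform_map",
    "relative_error",
    "optimal_worst_positions",
    "I_FIBER_GRID",
]

NO_THRESHOLD = np.nan  # sentinel: not excitable within the intensity bracket

# nine log-spaced fiber intensities, mW/mm^2
I_FIBER_GRID = np.logspace(np.log10(0.1), np.log10(1000.0), 9)

_TITRATION_FLOOR = 1e-6   # mW/mm^2; lowest bracket endpoint scanned
_TITRATION_CAP = 1e3      # mW/mm^2; "no threshold" above this


def titrate_threshold(spike_at, a0: float = 1e-3, cap: float = _TITRATION_CAP,
                      n_bisect: int = 7, check_monotone: bool = False):
    """Bisection titration of the spiking threshold intensity.

    ``spike_at(I) -> bool`` must be monotone in I.  A bracket [a, b] with
    b = 10 a, no spike at a and a spike at b, is located by scanning
    decade-spaced intensities upward from ``a0`` (and below it if the
    response is already suprathreshold); seven bisection iterations then
    narrow it and the midpoint of the final bracket is returned.  Returns
    NaN (sentinel) if no spike occurs up to ``cap``.
    """
    # decade scan for the (no-spike, spike) bracket
    decades = []
    lo = a0
    while lo <= cap * 1.0000001:
        decades.append(lo)
        lo *= 10.0
    responses = {}

    def probe(x):
        if x not in responses:
            responses[x] = bool(spike_at(x))
        return responses[x]

    def scan(ladder):
        for lo, hi in itertools.pairwise(ladder):
            if not probe(lo) and probe(hi):
                return (lo, hi)
        return None

    if probe(decades[0]):
        # suprathreshold already at the lowest planned intensity: shift the
        # bracket down geometrically
        down = decades[0]
        while down > _TITRATION_FLOOR:
            down /= 10.0
            if not probe(down):
                break
        else:
            # spikes at arbitrarily low intensity: report the floor
            return _TITRATION_FLOOR
        bracket = (down, down * 10.0)
    else:
        bracket = scan(decades)
        if bracket is None:
            # the photocurrent saturates and adapts, so narrow spiking
            # windows can exist; refine once with half-decade midpoints
            half = sorted(set(decades)
                          | {np.sqrt(a * b)
                             for a, b in itertools.pairwise(decades)})
            bracket = scan(half)
        if bracket is None:
            return NO_THRESHOLD

    a, b = bracket
    for _ in range(n_bisect):
        c = 0.5 * (a + b)
        if probe(c):
            b = c
        else:
            a = c
    if check_monotone:
        xs = sorted(responses)
        seen_spike = False
        for x in xs:
            if responses[x]:
                seen_spike = True
            elif seen_spike:
                raise RuntimeError("non-monotone spiking response detected")
    return 0.5 * (a + b)


def compute_TAC(i_traces: np.ndarray, t: np.ndarray, areas_um2: np.ndarray,
                pd: float, t0: float, t_end: float | None = None) -> float:
    """Total temporal averaged current (uA) at the stimulus.

    TAC = (1/pd) * sum_j A_j * int_{t0}^{T_end} i_j dt with i_j the
    photocurrent density (mA/cm^2) of segment j and A_j its area.
    Trapezoidal integration; T_end defaults to max(500, t0+pd+100) ms.
    """
    i_traces = np.atleast_2d(np.asarray(i_traces, dtype=float))
    areas_um2 = np.atleast_1d(np.asarray(areas_um2, dtype=float))
    if i_traces.shape[0] != areas_um2.shape[0]:
        raise ValueError("trace/area mismatch")
    if t_end is None:
        t_end = max(500.0, t0 + pd + 100.0)
    if t[0] > t0 or t[-1] < t_end - 1e-9:
        raise ValueError("traces do not cover [t0, T_end]")
    sel = (t >= t0) & (t <= t_end)
    integ = np.trapezoid(i_traces[:, sel], t[sel], axis=1)  # mA/cm^2 * ms
    area_cm2 = areas_um2 * 1e-8
    return float(np.sum(integ * area_cm2) / pd * 1e3)  # mA -> uA


def tac_from_integrals(chr2_time_integral: np.ndarray, areas_um2: np.ndarray,
                       pd: float) -> float:
    """TAC (uA) from per-segment time integrals of photocurrent density."""
    area_cm2 = np.asarray(areas_um2, dtype=float) * 1e-8
    return float(np.sum(chr2_time_integral * area_cm2) / pd * 1e3)


@dataclass
class ThresholdMap:
    """I_th and TAC over a (x, z) grid of fiber positions."""

    x: np.ndarray            # um, fiber grid coordinate
    z: np.ndarray            # um
    i_th: np.ndarray         # (nx, nz) mW/mm^2, NaN sentinel where not excitable
    tac: np.ndarray          # (nx, nz) uA at threshold (NaN where sentinel)
    pitch: float = np.pi / 2
    pd: float = 10.0
    g_max: float = 1.0
    region: str = "allsec"
    cell_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.i_th = np.asarray(self.i_th, dtype=float)
        if self.i_th.shape != (len(self.x), len(self.z)):
            raise ValueError("i_th grid shape mismatch")
        if np.any(self.i_th[np.isfinite(self.i_th)] <= 0):
            raise ValueError("defined thresholds must be > 0")

    @property
    def cell_area_mm2(self) -> float:
        """Discretization surface per grid cell (mm^2)."""
        dx = abs(self.x[1] - self.x[0]) if len(self.x) > 1 else 0.0
        dz = abs(self.z[1] - self.z[0]) if len(self.z) > 1 else 0.0
        return dx * dz * 1e-6

    def to_dataframe(self):
        import pandas as pd

        xx, zz = np.meshgrid(self.x, self.z, indexing="ij")
        return pd.DataFrame({
            "x_um": xx.ravel(), "z_um": zz.ravel(),
            "i_th": self.i_th.ravel(), "tac_uA": self.tac.ravel()})

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for name in ("x", "z", "i_th", "tac"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.attrs.update({"pitch": self.pitch, "pd": self.pd,
                             "g_max": self.g_max, "region": self.region,
                             "cell_id": self.cell_id})

    @classmethod
    def load(cls, path) -> "ThresholdMap":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(x=fh["x"][:], z=fh["z"][:], i_th=fh["i_th"][:],
                       tac=fh["tac"][:], pitch=float(fh.attrs["pitch"]),
                       pd=float(fh.attrs["pd"]),
                       g_max=float(fh.attrs["g_max"]),
                       region=str(fh.attrs["region"]),
                       cell_id=str(fh.attrs["cell_id"]))


@dataclass
class SofpanResult:
    """SoFPAN point estimate with discretization bounds, mm^2."""

    i_fiber: float
    lower: float
    estimate: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.estimate + 1e-12
                and self.estimate <= self.upper + 1e-12):
            raise ValueError("SoFPAN bounds out of order")


def position_grid(pitch: float, nx: int | None = None, nz: int | None = None):
    """Fiber-position grid per pitch.

    Full layout: 11 z values in [-400, 700] um; x in [-1000, 4000] um
    (step 500) for pitch pi/2 and [0, 2500] um (step 250) for pitches 0
    and pi — 121 positions.  ``nx``/``nz`` override the point counts for
    scaled-down sweeps (same extents).
    """
    z = np.linspace(-400.0, 700.0, nz or 11)
    if np.isclose(pitch, np.pi / 2):
        x = np.linspace(-1000.0, 4000.0, nx or 11)
    elif np.isclose(pitch, 0.0) or np.isclose(pitch, np.pi):
        x = np.linspace(0.0, 2500.0, nx or 11)
    else:
        raise ValueError("pitch must be one of {0, pi/2, pi}")
    return x, z


def sweep_positions(threshold_fn, pitch: float, nx: int | None = None,
                    nz: int | None = None, pd: float = 10.0,
                    g_max: float = 1.0, region: str = "allsec",
                    cell_id: str = "") -> ThresholdMap:
    """Evaluate ``threshold_fn(x, z) -> (I_th, TAC)`` over the position grid.

    Positions are independent; failures at single positions propagate as
    sentinels rather than aborting the sweep.
    """
    x, z = position_grid(pitch, nx, nz)
    i_th = np.full((len(x), len(z)), np.nan)
    tac = np.full((len(x), len(z)), np.nan)
    for i, xi in enumerate(x):
        for j, zj in enumerate(z):
            try:
                i_th[i, j], tac[i, j] = threshold_fn(xi, zj)
            except Exception:  # noqa: BLE001 - per-position isolation
                i_th[i, j] = np.nan
    return ThresholdMap(x=x, z=z, i_th=i_th, tac=tac, pitch=pitch, pd=pd,
                        g_max=g_max, region=region, cell_id=cell_id)


def _enclosed_cells(true_nodes: np.ndarray) -> int:
    """Count grid cells whose four corner nodes are all true."""
    a = true_nodes
    return int(np.sum(a[:-1, :-1] & a[1:, :-1] & a[:-1, 1:] & a[1:, 1:]))


def sofpan(tmap: ThresholdMap, i_fiber: float) -> SofpanResult:
    """SoFPAN at one fiber intensity, with discretization bounds.

    A node is activating if its titrated threshold lies below ``i_fiber``.
    The point estimate weights boundary nodes by the fraction of their
    discretization cell inside the explored domain (1/2 on edges, 1/4 at
    corners), so a fully activating map equals the domain area.  The lower
    bound counts cells enclosed by four activating nodes; the upper bound
    does the same after dilating the node field with a 3x3 mask.  For the
    axial pitches (0 and pi) the surfaces are doubled, exploiting the
    mirror symmetry of the half-plane grid.
    """
    with np.errstate(invalid="ignore"):
        true = np.where(np.isfinite(tmap.i_th), tmap.i_th < i_fiber, False)
    cell = tmap.cell_area_mm2
    w = np.ones(true.shape)
    w[0, :] *= 0.5
    w[-1, :] *= 0.5
    w[:, 0] *= 0.5
    w[:, -1] *= 0.5
    estimate = float(np.sum(w[true]) * cell)
    lower = _enclosed_cells(true) * cell
    dilated = ndimage.binary_dilation(true, structure=np.ones((3, 3), bool))
    upper = _enclosed_cells(dilated) * cell
    mult = 2.0 if (np.isclose(tmap.pitch, 0.0) or np.isclose(tmap.pitch, np.pi)) \
        else 1.0
    return SofpanResult(i_fiber=float(i_fiber), lower=mult * lower,
                        estimate=mult * estimate, upper=mult * upper)


def sofpan_uniform_map(i_th_uniform: float, field_, fiber_factory,
                       soma_xyz, pitch: float, nx: int | None = None,
                       nz: int | None = None, pd: float = 10.0,
                       g_max: float = 1.0, region: str = "allsec",
                       roll: float = 0.0) -> ThresholdMap:
    """Threshold map under the uniform-field (point-cell) approximation.

    The cell is collapsed onto its soma: a fiber position excites it iff
    the local gain g satisfies g * I_fiber >= I_th_uniform, i.e. the
    position's threshold is I_th_uniform / g.
    """
    from . import light as _light

    x, z = position_grid(pitch, nx, nz)
    i_th = np.full((len(x), len(z)), np.nan)
    for i, xi in enumerate(x):
        for j, zj in enumerate(z):
            fiber = fiber_factory(xi, zj)
            gain = _light.segment_gains(field_, np.asarray(soma_xyz)[None, :],
                                        fiber, roll)[0]
            if gain > 0 and np.isfinite(i_th_uniform):
                val = i_th_uniform / gain
                i_th[i, j] = val if val <= _TITRATION_CAP else np.nan
    return ThresholdMap(x=x, z=z, i_th=i_th, tac=np.full_like(i_th, np.nan),
                        pitch=pitch, pd=pd, g_max=g_max, region=region)


def relative_error(sofpan_uniform_val: float, sofpan_mc_val: float) -> float:
    """(SoFPAN_uniform - SoFPAN_MC) / SoFPAN_MC with degenerate sentinels.

    MC = 0 with a nonzero uniform estimate yields +inf; a zero uniform
    estimate against nonzero MC yields -1 (a -100% error).
    """
    if sofpan_mc_val == 0:
        return 0.0 if sofpan_uniform_val == 0 else float("inf")
    return (sofpan_uniform_val - sofpan_mc_val) / sofpan_mc_val


def optimal_worst_positions(tmap: ThresholdMap, i_fiber: float):
    """(z_opt, z_worst): grid rows maximizing/minimizing depth of activation.

    Depth of activation of a z row is the number of x positions with
    I_th < I_fiber.  Ties are broken by the mean TAC along x: lowest mean
    wins the optimal slot, highest wins the worst slot; remaining ties fall
    to the first grid z (deterministic).  An all-sentinel map is undefined.
    """
    finite = np.isfinite(tmap.i_th)
    if not finite.any():
        raise ValueError("all positions are sentinels; positions undefined")
    with np.errstate(invalid="ignore"):
        true = np.where(finite, tmap.i_th < i_fiber, False)
    depth = true.sum(axis=0)  # per z row
    mean_tac = np.where(np.isfinite(tmap.tac), tmap.tac, np.nan)
    n_def = np.isfinite(mean_tac).sum(axis=0)
    row_sum = np.nansum(mean_tac, axis=0)
    row_tac = np.where(n_def > 0, row_sum / np.maximum(n_def, 1), np.inf)

    def _select(maximize_depth: bool):
        d = depth if maximize_depth else -depth
        best = d.max()
        cand = np.flatnonzero(d == best)
        if len(cand) == 1:
            return cand[0]
        tacs = row_tac[cand]
        if maximize_depth:   # optimal: lowest mean TAC
            pick = np.argmin(tacs)
        else:                # worst: highest mean TAC (inf rows excluded)
            finite_t = np.where(np.isinf(tacs), -np.inf, tacs)
            pick = np.argmax(finite_t)
        return cand[pick]

    z_opt = float(tmap.z[_select(True)])
    z_worst = float(tmap.z[_select(False)])
    return z_opt, z_worst
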