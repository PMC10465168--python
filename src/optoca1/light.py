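"""Monte Carlo photon transport from a flat-tip optical fiber.

Photons are launched uniformly over the fiber face with directions uniform
in the numerical-aperture cone (half-angle ``asin(NA/n)``), propagated
through a homogeneous turbid medium (Henyey-Greenstein scattering, implicit
absorption weighting, Russian roulette), and tallied on a cylindrical
(r, z) grid.  The tally is the absorbed weight per voxel; dividing by
``mu_a * voxel volume`` gives the fluence rate, which normalized by the
fiber-face irradiance yields a unitless irradiance gain field.

Geometry helpers map neuron (cell-frame) coordinates into the fiber frame
for the three fiber pitches used throughout: pi/2 (fiber axis along +x,
light travelling toward -x), 0 (axis along +z) and pi (axis along -z).
All lengths inside the transport kernel are mm; the cell frame uses um.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

__all__ = [
    "OpticalProperties",
    "FiberSpec",
    "FluenceField",
    "GRAY_MATTER",
    "sample_scatter_cos",
    "run_monte_carlo",
    "irradiance_at",
    "to_fiber_frame",
]

_W_ROULETTE = 1e-4  # weight threshold for Russian roulette
_P_SURVIVE = 0.1    # roulette survival probability


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the (homogeneous) tissue at 470 nm."""

    mu_a: float = 0.42    # absorption coefficient, mm^-1
    mu_s: float = 11.33   # scattering coefficient, mm^-1
    g: float = 0.88       # scattering anisotropy
    n: float = 1.36       # refractive index

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be >= 0")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.mu_a == 0 and self.mu_s == 0:
            raise ValueError("medium must interact with light")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s*(1-g), mm^-1."""
        return self.mu_s * (1.0 - self.g)

    @classmethod
    def from_reduced(cls, mu_a: float, mu_s_prime: float, g: float = 0.88,
                     n: float = 1.36) -> "OpticalProperties":
        return cls(mu_a=mu_a, mu_s=mu_s_prime / (1.0 - g), g=g, n=n)


GRAY_MATTER = OpticalProperties()


@dataclass(frozen=True)
class FiberSpec:
    """Flat-tip optical fiber and its placement in the cell frame."""

    radius_um: float = 100.0
    na: float = 0.39
    pitch: float = np.pi / 2          # one of {0, pi/2, pi} radians
    position: tuple = (0.0, 0.0)      # (x, z) um in the cell frame

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("fiber radius must be > 0")
        if not 0 < self.na:
            raise ValueError("numerical aperture must be > 0")

    def validate_against(self, optics: OpticalProperties) -> None:
        if self.na >= optics.n:
            raise ValueError("NA must be smaller than the medium index")


@dataclass
class FluenceField:
    """Normalized irradiance gain on a cylindrical (r, z) grid.

    ``values[i, j]`` is the local irradiance per unit fiber-face irradiance
    at the voxel center ``(r[i], z[j])``.  ``r`` spans [0, r_max], ``z``
    spans [z_min, z_max]; the fiber face sits at z = 0 emitting toward +z.
    """

    r: np.ndarray           # voxel-center radii, mm
    z: np.ndarray           # voxel-center axial positions, mm
    values: np.ndarray      # (nr, nz) gain
    optics: OpticalProperties = field(default_factory=OpticalProperties)
    fiber_radius_mm: float = 0.1
    na: float = 0.39
    n_photons: int = 0
    seed: int = 0

    def cache_key(self) -> str:
        meta = dict(mu_a=self.optics.mu_a, mu_s=self.optics.mu_s,
                    g=self.optics.g, n=self.optics.n,
                    fiber_radius_mm=self.fiber_radius_mm, na=self.na,
                    n_photons=self.n_photons, seed=self.seed,
                    nr=len(self.r), nz=len(self.z),
                    r0=float(self.r[0]), z0=float(self.z[0]))
        return hashlib.sha1(json.dumps(meta, sort_keys=True).encode()).hexdigest()

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("r", data=self.r)
            fh.create_dataset("z", data=self.z)
            fh.create_dataset("values", data=self.values)
            for k, v in (("mu_a", self.optics.mu_a), ("mu_s", self.optics.mu_s),
                         ("g", self.optics.g), ("n", self.optics.n),
                         ("fiber_radius_mm", self.fiber_radius_mm),
                         ("na", self.na), ("n_photons", self.n_photons),
                         ("seed", self.seed)):
                fh.attrs[k] = v
            fh.attrs["cache_key"] = self.cache_key()

    @classmethod
    def load(cls, path) -> "FluenceField":
        with h5py.File(path, "r") as fh:
            optics = OpticalProperties(
                mu_a=float(fh.attrs["mu_a"]), mu_s=float(fh.attrs["mu_s"]),
                g=float(fh.attrs["g"]), n=float(fh.attrs["n"]))
            return cls(r=fh["r"][:], z=fh["z"][:], values=fh["values"][:],
                       optics=optics,
                       fiber_radius_mm=float(fh.attrs["fiber_radius_mm"]),
                       na=float(fh.attrs["na"]),
                       n_photons=int(fh.attrs["n_photons"]),
                       seed=int(fh.attrs["seed"]))


def sample_scatter_cos(g: float, u) -> np.ndarray | float:
    """Inverse-transform sample of the Henyey-Greenstein scattering cosine.

    For ``g == 0`` the phase function is isotropic and ``cos = 2u - 1``.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - frac * frac) / (2.0 * g)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _hg_cos(g, u):
    if g == 0.0:
        c = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        c = (1.0 + g * g - frac * frac) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def _mc_kernel(n_photons, seed, mu_a, mu_s, g, fiber_r, cos_max,
               r_max, z_min, z_max, dr, dz, nr, nz):
    """Propagate photons; return (tally, absorbed, escaped, roulette_net).

    ``tally[i, j]`` accumulates weight absorbed in voxel (i, j): at every
    interaction site the fraction ``mu_a/mu_t`` of the photon weight is
    deposited (implicit capture) and the remainder is scattered.
    ``roulette_net`` is killed-weight minus boost-weight so the energy
    bookkeeping identity closes exactly per run.
    """
    np.random.seed(seed)
    tally = np.zeros((nr, nz))
    absorbed = 0.0
    escaped = 0.0
    roulette_net = 0.0
    mu_t = mu_a + mu_s
    frac_abs = mu_a / mu_t

    for _ in range(n_photons):
        # launch: uniform over the fiber disk, uniform solid angle in cone
        rr = fiber_r * np.sqrt(np.random.random())
        phi = 2.0 * np.pi * np.random.random()
        x = rr * np.cos(phi)
        y = rr * np.sin(phi)
        z = 0.0
        cth = cos_max + (1.0 - cos_max) * np.random.random()
        sth = np.sqrt(1.0 - cth * cth)
        psi = 2.0 * np.pi * np.random.random()
        ux = sth * np.cos(psi)
        uy = sth * np.sin(psi)
        uz = cth
        w = 1.0

        while True:
            s = -np.log(np.random.random() + 1e-300) / mu_t
            x += ux * s
            y += uy * s
            z += uz * s
            rad = np.sqrt(x * x + y * y)
            if rad >= r_max or z <= z_min or z >= z_max:
                # absorbing boundary: record the escape and terminate
                escaped += w
                break
            dw = w * frac_abs
            ir = int(rad / dr)
            iz = int((z - z_min) / dz)
            if ir < nr and 0 <= iz < nz:
                tally[ir, iz] += dw
            absorbed += dw
            w -= dw
            if w <= 1e-300:  # pure absorber deposits everything at once
                break
            # scatter into a new direction (Henyey-Greenstein)
            cth_s = _hg_cos(g, np.random.random())
            sth_s = np.sqrt(1.0 - cth_s * cth_s)
            psi = 2.0 * np.pi * np.random.random()
            cpsi = np.cos(psi)
            spsi = np.sin(psi)
            if np.abs(uz) > 0.99999:
                ux_n = sth_s * cpsi
                uy_n = sth_s * spsi
                uz_n = cth_s * (1.0 if uz > 0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                ux_n = sth_s * (ux * uz * cpsi - uy * spsi) / den + ux * cth_s
                uy_n = sth_s * (uy * uz * cpsi + ux * spsi) / den + uy * cth_s
                uz_n = -sth_s * cpsi * den + uz * cth_s
            norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
            ux, uy, uz = ux_n / norm, uy_n / norm, uz_n / norm
            # Russian roulette below the weight threshold
            if w < _W_ROULETTE:
                if np.random.random() < _P_SURVIVE:
                    roulette_net -= w * (1.0 / _P_SURVIVE - 1.0)
                    w = w / _P_SURVIVE
                else:
                    roulette_net += w
                    break

    return tally, absorbed, escaped, roulette_net


def run_monte_carlo(optics: OpticalProperties | None = None,
                    fiber: FiberSpec | None = None,
                    r_max: float = 5.0, z_min: float = -4.0, z_max: float = 6.0,
                    dr: float = 0.005, dz: float = 0.005,
                    n_photons: int = 1_000_000, seed: int = 0,
                    return_books: bool = False):
    """Run the photon-transport simulation and return a :class:`FluenceField`.

    Grid extents and spacings are in mm (defaults match the full-resolution
    production grid: r in [0, 5] mm, z in [-4, 6] mm).  ``return_books``
    additionally returns the energy bookkeeping tuple
    ``(launched, absorbed, escaped, roulette_net)``.
    """
    optics = optics or GRAY_MATTER
    fiber = fiber or FiberSpec()
    fiber.validate_against(optics)
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    nr = int(round(r_max / dr))
    nz = int(round((z_max - z_min) / dz))
    cos_max = np.cos(np.arcsin(fiber.na / optics.n))
    fiber_r_mm = fiber.radius_um * 1e-3

    tally, absorbed, escaped, roulette_net = _mc_kernel(
        int(n_photons), int(seed), optics.mu_a, optics.mu_s, optics.g,
        fiber_r_mm, cos_max, r_max, z_min, z_max, dr, dz, nr, nz)

    # fluence rate per photon: absorbed/(mu_a * V); gain = fluence / E_face
    # with E_face = 1 photon-unit / fiber area
    r_centers = (np.arange(nr) + 0.5) * dr
    z_centers = z_min + (np.arange(nz) + 0.5) * dz
    r_edges = np.arange(nr + 1) * dr
    vol = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2) * dz  # mm^3
    fiber_area = np.pi * fiber_r_mm ** 2
    if optics.mu_a > 0:
        gain = tally / (optics.mu_a * vol[:, None]) / n_photons * fiber_area
    else:  # pragma: no cover - mu_a == 0 means no deposition
        gain = np.zeros_like(tally)

    field_ = FluenceField(r=r_centers, z=z_centers, values=gain,
                          optics=optics, fiber_radius_mm=fiber_r_mm,
                          na=fiber.na, n_photons=int(n_photons),
                          seed=int(seed))
    if return_books:
        return field_, (float(n_photons), absorbed, escaped, roulette_net)
    return field_


def irradiance_at(field_: FluenceField, r, z):
    """Bilinear interpolation of the gain field; 0 outside the grid.

    Queries exactly at voxel centers return the stored value.
    """
    scalar = np.isscalar(r) and np.isscalar(z)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    r, z = np.broadcast_arrays(r, z)
    rg, zg, vals = field_.r, field_.z, field_.values

    rq = np.abs(r)  # radii are nonnegative by definition
    inside = (rq <= rg[-1]) & (z >= zg[0]) & (z <= zg[-1])
    # queries inside the innermost voxel center clamp to the axis value
    rc = np.clip(rq, rg[0], rg[-1])
    i = np.clip(np.searchsorted(rg, rc) - 1, 0, len(rg) - 2)
    j = np.clip(np.searchsorted(zg, z) - 1, 0, len(zg) - 2)
    tr = np.clip((rc - rg[i]) / (rg[i + 1] - rg[i]), 0.0, 1.0)
    tz = np.clip((z - zg[j]) / (zg[j + 1] - zg[j]), 0.0, 1.0)
    interp = (vals[i, j] * (1 - tr) * (1 - tz) + vals[i + 1, j] * tr * (1 - tz)
              + vals[i, j + 1] * (1 - tr) * tz + vals[i + 1, j + 1] * tr * tz)
    out = np.where(inside, np.maximum(interp, 0.0), 0.0)
    return float(out[0]) if scalar else out


_SUPPORTED_PITCHES = (0.0, np.pi / 2, np.pi)


def to_fiber_frame(point_xyz, fiber: FiberSpec, roll: float = 0.0):
    """Map cell-frame point(s) (um) into fiber coordinates (r, z_fiber) um.

    ``roll`` first rotates the morphology about the somato-dendritic (z)
    axis.  The fiber face sits at ``fiber.position`` and emits:

    * pitch pi/2 : along -x (axis along +x; cell illuminated from x = fiber.x)
    * pitch 0    : along +z (fiber below the cell, axis along +z)
    * pitch pi   : along -z (fiber above the cell, axis along -z)
    """
    p = np.atleast_2d(np.asarray(point_xyz, dtype=float))
    if not any(np.isclose(fiber.pitch, q) for q in _SUPPORTED_PITCHES):
        raise ValueError("pitch must be one of {0, pi/2, pi}")
    if roll != 0.0:
        c, s = np.cos(roll), np.sin(roll)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        p = p @ rot.T
    fx, fz = fiber.position
    if np.isclose(fiber.pitch, np.pi / 2):
        z_f = fx - p[:, 0]
        r_f = np.hypot(p[:, 1], p[:, 2] - fz)
    elif np.isclose(fiber.pitch, 0.0):
        z_f = p[:, 2] - fz
        r_f = np.hypot(p[:, 0] - fx, p[:, 1])
    else:  # pitch pi
        z_f = fz - p[:, 2]
        r_f = np.hypot(p[:, 0] - fx, p[:, 1])
    if np.asarray(point_xyz).ndim == 1:
        return float(r_f[0]), float(z_f[0])
    return r_f, z_f


def segment_gains(field_: FluenceField, centroids_um, fiber: FiberSpec,
                  roll: float = 0.0) -> np.ndarray:
    """Irradiance gain at each segment centroid for a given fiber placement."""
    r_um, z_um = to_fiber_frame(centroids_um, fiber, roll)
    return np.asarray(irradiance_at(field_, np.asarray(r_um) * 1e-3,
                                    np.asarray(z_um) * 1e-3))
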