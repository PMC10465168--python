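"""Synthetic CA1-like morphologies and membrane-area bookkeeping.

The generators emulate the gross architecture of CA1 cells: pyramidal
cells have a soma at the origin, a thin descending axon, a basal dendritic
tree pointing into -z (stratum oriens) and an apical trunk plus tuft
aligned with +z; interneurons (basket / bistratified presets) have an
undifferentiated dendritic arbor and a large, highly branched axonal
arbor.  Default parameters are calibrated so region membrane areas fall in
the ranges observed for reconstructed CA1 cells (soma ~400-1,400 um^2,
dendrites ~2e4 um^2, interneuron axons 2.5e4-1.1e5 um^2).

A morphology is a tree of sections (polyline + per-point diameters +
region label); for simulation each section is subdivided into segments of
bounded length, each carrying a centroid, a frustum lateral area and tree
connectivity.  SWC import/export uses the standard 7-column format with
type codes {1: soma, 2: axon, 3: basal, 4: apic}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "generate_pyramidal",
    "generate_interneuron",
    "region_area",
    "align_somatodendritic_axis",
    "distribute_opsin",
    "read_swc",
    "write_swc",
]

BASE_REGIONS = ("soma", "axon", "basal", "apic", "dend")
_SWC_TYPE = {"soma": 1, "axon": 2, "basal": 3, "apic": 4, "dend": 3}
_SWC_REGION = {1: "soma", 2: "axon", 3: "basal", 4: "apic"}


@dataclass
class Section:
    """A single unbranched neurite stretch."""

    region: str
    points: np.ndarray      # (n, 3) um
    diams: np.ndarray       # (n,) um
    parent: int = -1        # index of parent section, -1 for root

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.diams = np.asarray(self.diams, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if len(self.diams) != len(self.points):
            raise ValueError("diams must match points")
        if np.any(self.diams <= 0):
            raise ValueError("diameters must be > 0")
        if self.region not in BASE_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class Segments:
    """Flat segment arrays derived from a morphology (simulation view)."""

    region: np.ndarray      # (nseg,) str
    centroid: np.ndarray    # (nseg, 3) um
    area: np.ndarray        # (nseg,) um^2 lateral frustum area
    length: np.ndarray      # (nseg,) um
    diam: np.ndarray        # (nseg,) um  (mean)
    parent: np.ndarray      # (nseg,) int, -1 for root; parent[i] < i


@dataclass
class Morphology:
    """Connected tree of labeled sections rooted at the soma."""

    sections: list = field(default_factory=list)
    max_seg_len: float = 20.0  # um; fixed-length discretization rule

    def __post_init__(self) -> None:
        self._segments = None
        self.validate()

    def validate(self) -> None:
        if not self.sections:
            raise ValueError("morphology has no sections")
        if self.sections[0].region != "soma" or self.sections[0].parent != -1:
            raise ValueError("first section must be the soma root")
        for i, sec in enumerate(self.sections):
            if i > 0 and not 0 <= sec.parent < i:
                raise ValueError("sections must be topologically ordered "
                                 "(parent before child)")

    @property
    def regions(self) -> set:
        return {s.region for s in self.sections}

    def segments(self) -> Segments:
        """Subdivide sections into segments no longer than ``max_seg_len``."""
        if self._segments is not None:
            return self._segments
        regions, cents, areas, lens, diams, parents = [], [], [], [], [], []
        sec_last_seg = {}
        for si, sec in enumerate(self.sections):
            pts, dms = _resample(sec.points, sec.diams, self.max_seg_len)
            prev = -1 if sec.parent < 0 else sec_last_seg[sec.parent]
            for k in range(len(pts) - 1):
                p0, p1 = pts[k], pts[k + 1]
                r0, r1 = dms[k] / 2.0, dms[k + 1] / 2.0
                L = float(np.linalg.norm(p1 - p0))
                slant = np.hypot(L, r1 - r0)
                regions.append(sec.region)
                cents.append((p0 + p1) / 2.0)
                areas.append(np.pi * (r0 + r1) * slant)
                lens.append(L)
                diams.append(r0 + r1)
                parents.append(prev)
                prev = len(regions) - 1
            sec_last_seg[si] = prev
        self._segments = Segments(
            region=np.array(regions), centroid=np.array(cents),
            area=np.array(areas), length=np.array(lens),
            diam=np.array(diams), parent=np.array(parents, dtype=np.int64))
        return self._segments

    def invalidate(self) -> None:
        self._segments = None

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean per-segment mask; understands composite region names."""
        seg = self.segments()
        region = "dend" if region == "alldend" else region
        if region in ("all", "allsec"):
            return np.ones(len(seg.region), dtype=bool)
        if region == "dend":
            return np.isin(seg.region, ("basal", "apic", "dend"))
        if region not in BASE_REGIONS:
            raise KeyError(f"unknown region {region!r}")
        return seg.region == region

    def summary(self):
        """Per-region (area, n_segments) table as a pandas DataFrame."""
        import pandas as pd

        seg = self.segments()
        rows = []
        for region in sorted(set(seg.region)) + ["dend", "allsec"]:
            m = self.region_mask(region)
            if m.any():
                rows.append({"region": region, "area_um2": float(seg.area[m].sum()),
                             "n_segments": int(m.sum())})
        return pd.DataFrame(rows).drop_duplicates(subset="region")


def _resample(points: np.ndarray, diams: np.ndarray, max_len: float):
    """Resample a polyline so no inter-point distance exceeds ``max_len``."""
    seglens = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = float(seglens.sum())
    if total == 0:
        raise ValueError("zero-length section")
    arc = np.concatenate([[0.0], np.cumsum(seglens)])
    n = max(int(np.ceil(total / max_len)), 1)
    s_new = np.linspace(0.0, total, n + 1)
    pts = np.empty((n + 1, 3))
    for d in range(3):
        pts[:, d] = np.interp(s_new, arc, points[:, d])
    dms = np.interp(s_new, arc, diams)
    return pts, dms


def region_area(morph: Morphology, region: str) -> float:
    """Total membrane surface area of a (possibly composite) region, um^2."""
    mask = morph.region_mask(region)
    if not mask.any():
        raise KeyError(f"region {region!r} has no segments in this morphology")
    return float(morph.segments().area[mask].sum())


# ---------------------------------------------------------------------------
# synthetic generators

def _grow_tree(rng, direction, n_stems, stem_len, diam0, taper,
               depth, branch_angle=0.5, spread=0.9, jitter=0.25):
    """Grow ``n_stems`` stochastic binary subtrees; returns section specs.

    Each stem leaves the root in a cone around ``direction``; at every
    branch point the child directions fan out by ``branch_angle`` radians
    and lengths shrink geometrically.  Returns a list of
    (points, diams, parent_slot) where parent_slot is an index into the
    returned list or -1 (attach to root).
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    out = []

    def _unit(vec):
        return vec / np.linalg.norm(vec)

    def _perturb(vec, angle):
        # random direction at ~angle from vec
        a = rng.normal(size=3)
        a -= a.dot(vec) * vec
        a = _unit(a) if np.linalg.norm(a) > 1e-12 else np.array([1.0, 0, 0])
        th = angle * (1.0 + jitter * rng.standard_normal())
        return _unit(np.cos(th) * vec + np.sin(th) * a)

    def _grow(start, vec, length, diam, level, parent_slot):
        length = max(length * (1.0 + jitter * rng.standard_normal()), 5.0)
        end = start + vec * length
        pts = np.vstack([start, end])
        dms = np.array([diam, max(diam * taper, 0.2)])
        out.append((pts, dms, parent_slot))
        slot = len(out) - 1
        if level < depth:
            for _ in range(2):
                _grow(end, _perturb(vec, branch_angle), length * 0.7,
                      dms[1], level + 1, slot)
        return slot

    for _ in range(n_stems):
        vec = _perturb(direction, spread * rng.random())
        _grow(np.zeros(3), vec, stem_len, diam0, 1, -1)
    return out


def _attach(sections, specs, region, root_idx, origin):
    slot_to_sec = {}
    for slot, (pts, dms, parent_slot) in enumerate(specs):
        parent = root_idx if parent_slot == -1 else slot_to_sec[parent_slot]
        sections.append(Section(region, pts + origin, dms, parent))
        slot_to_sec[slot] = len(sections) - 1


@dataclass(frozen=True)
class PyramidalParams:
    """Generator knobs for a synthetic CA1 pyramidal cell."""

    soma_len: float = 15.0
    soma_diam: float = 15.0
    axon_len: float = 500.0
    axon_diam: float = 1.0
    n_basal: int = 5
    basal_len: float = 125.0
    basal_diam: float = 1.3
    basal_depth: int = 3
    trunk_len: float = 350.0
    trunk_diam: float = 2.6
    n_tuft: int = 5
    tuft_len: float = 165.0
    tuft_diam: float = 1.3
    tuft_depth: int = 3
    taper: float = 0.75

    def __post_init__(self) -> None:
        for name in ("soma_len", "soma_diam", "axon_len", "axon_diam",
                     "basal_len", "trunk_len", "tuft_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def generate_pyramidal(params: PyramidalParams | None = None,
                       seed: int = 1, max_seg_len: float = 20.0) -> Morphology:
    """Synthetic CA1 pyramidal cell: apical tree toward +z, basal toward -z."""
    p = params or PyramidalParams()
    rng = np.random.default_rng(seed)
    sections = []

    half = p.soma_len / 2.0
    soma = Section("soma",
                   np.array([[0.0, 0.0, -half], [0.0, 0.0, half]]),
                   np.array([p.soma_diam, p.soma_diam]), -1)
    sections.append(soma)

    # axon: thin process descending from the soma
    ax_dir = np.array([0.25, 0.0, -1.0])
    ax_dir /= np.linalg.norm(ax_dir)
    ax_pts = np.vstack([[0.0, 0.0, -half],
                        [0.0, 0.0, -half] + ax_dir * p.axon_len])
    sections.append(Section("axon", ax_pts,
                            np.array([p.axon_diam, p.axon_diam * 0.8]), 0))

    if p.n_basal > 0:
        specs = _grow_tree(rng, np.array([0.0, 0.0, -1.0]), p.n_basal,
                           p.basal_len, p.basal_diam, p.taper, p.basal_depth,
                           spread=1.0)
        _attach(sections, specs, "basal", 0, np.array([0.0, 0.0, -half]))

    # apical trunk straight up, tuft branching from its end
    trunk_pts = np.array([[0.0, 0.0, half], [0.0, 0.0, half + p.trunk_len]])
    sections.append(Section("apic", trunk_pts,
                            np.array([p.trunk_diam, p.trunk_diam * 0.7]), 0))
    trunk_idx = len(sections) - 1
    specs = _grow_tree(rng, np.array([0.0, 0.0, 1.0]), p.n_tuft,
                       p.tuft_len, p.tuft_diam, p.taper, p.tuft_depth,
                       spread=0.8)
    _attach(sections, specs, "apic", trunk_idx,
            np.array([0.0, 0.0, half + p.trunk_len]))

    return Morphology(sections, max_seg_len=max_seg_len)


@dataclass(frozen=True)
class InterneuronParams:
    """Generator knobs for a synthetic CA1 interneuron."""

    soma_len: float = 18.0
    soma_diam: float = 18.0
    n_dend: int = 8
    dend_len: float = 150.0
    dend_diam: float = 1.6
    dend_depth: int = 3
    n_axon: int = 8
    axon_len: float = 185.0
    axon_diam: float = 1.1
    axon_depth: int = 4
    taper: float = 0.85


BISTRATIFIED = InterneuronParams(n_axon=14, axon_len=300.0, axon_depth=4,
                                 axon_diam=1.2)
BASKET = InterneuronParams()


def generate_interneuron(params: InterneuronParams | str = "basket",
                         seed: int = 1, max_seg_len: float = 20.0) -> Morphology:
    """Synthetic interneuron; presets ``"basket"`` and ``"bistratified"``.

    The bistratified preset carries a much larger axonal arbor than its
    dendrites; the basket preset's axon is comparable to (slightly above)
    its dendritic area, mirroring reconstructed CA1 interneurons.
    Dendrites are undifferentiated (region label ``dend``).
    """
    if isinstance(params, str):
        try:
            params = {"basket": BASKET, "bistratified": BISTRATIFIED}[params]
        except KeyError:
            raise ValueError(f"unknown interneuron preset {params!r}") from None
    p = params
    rng = np.random.default_rng(seed)
    sections = []
    half = p.soma_len / 2.0
    sections.append(Section("soma",
                            np.array([[0.0, 0.0, -half], [0.0, 0.0, half]]),
                            np.array([p.soma_diam, p.soma_diam]), -1))
    # undifferentiated dendrites radiate in all directions
    specs = _grow_tree(rng, np.array([0.0, 0.0, 1.0]), p.n_dend // 2,
                       p.dend_len, p.dend_diam, p.taper, p.dend_depth,
                       spread=1.4)
    _attach(sections, specs, "dend", 0, np.array([0.0, 0.0, half]))
    specs = _grow_tree(rng, np.array([0.0, 0.0, -1.0]),
                       p.n_dend - p.n_dend // 2, p.dend_len, p.dend_diam,
                       p.taper, p.dend_depth, spread=1.4)
    _attach(sections, specs, "dend", 0, np.array([0.0, 0.0, -half]))
    # large axonal arbor spreading laterally
    specs = _grow_tree(rng, np.array([1.0, 0.0, -0.3]), p.n_axon,
                       p.axon_len, p.axon_diam, p.taper, p.axon_depth,
                       spread=2.0)
    _attach(sections, specs, "axon", 0, np.array([0.0, 0.0, -half]))
    return Morphology(sections, max_seg_len=max_seg_len)


# ---------------------------------------------------------------------------
# alignment and opsin distribution

def align_somatodendritic_axis(morph: Morphology) -> Morphology:
    """Rotate so the somato-dendritic axis (PCA of non-axon compartments)
    lies on z, apical side toward +z, soma centroid at the origin."""
    seg = morph.segments()
    non_axon = seg.region != "axon"
    pts = seg.centroid[non_axon]
    if len(pts) < 3:
        raise ValueError("need at least 3 non-axon segments for alignment")
    soma_c = seg.centroid[seg.region == "soma"].mean(axis=0)
    centered = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] < 1e-9 or np.isclose(svals[0], svals[-1]):
        raise ValueError("degenerate geometry: no principal axis")
    axis = vt[0]
    # choose the sign so the apical (or dominant dendritic) mass points +z
    ref = seg.centroid[seg.region == "apic"] if (seg.region == "apic").any() \
        else pts
    if np.dot(ref.mean(axis=0) - soma_c, axis) < 0:
        axis = -axis
    rot = _rotation_onto_z(axis)
    new_sections = []
    for sec in morph.sections:
        new_sections.append(Section(sec.region, (sec.points - soma_c) @ rot.T,
                                    sec.diams.copy(), sec.parent))
    return Morphology(new_sections, max_seg_len=morph.max_seg_len)


def _rotation_onto_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending ``axis`` onto +z (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, z))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def distribute_opsin(morph: Morphology, region: str, g_max_us: float) -> np.ndarray:
    """Uniform opsin distribution over a region at fixed total conductance.

    Returns the per-segment specific conductance g_ChR2 in S/cm^2 such that
    sum(g * area) over the region equals ``g_max_us`` (uS) exactly; zero
    outside the region.
    """
    if g_max_us <= 0:
        raise ValueError("G_max must be > 0")
    mask = morph.region_mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} has zero area")
    area_um2 = float(morph.segments().area[mask].sum())
    # uS / um^2 -> S/cm^2: 1e-6 S / 1e-8 cm^2 = 100 S/cm^2
    g = 100.0 * g_max_us / area_um2
    out = np.zeros(mask.shape)
    out[mask] = g
    return out


# ---------------------------------------------------------------------------
# SWC input/output

def read_swc(path, interneuron: bool = False,
             max_seg_len: float = 20.0) -> Morphology:
    """Read a standard 7-column SWC file.

    Consecutive same-type runs of points become sections.  With
    ``interneuron=True`` the basal/apic type codes collapse onto the
    undifferentiated ``dend`` label.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            ids.append(int(f[0]))
            types.append(int(f[1]))
            xyz.append([float(f[2]), float(f[3]), float(f[4])])
            radii.append(float(f[5]))
            parents.append(int(f[6]))
    id_map = {pid: k for k, pid in enumerate(ids)}
    xyz = np.asarray(xyz)
    radii = np.asarray(radii)

    children: dict[int, list[int]] = {}
    for k, pid in enumerate(parents):
        if pid != -1:
            children.setdefault(id_map[pid], []).append(k)

    roots = [k for k, pid in enumerate(parents) if pid == -1]
    if len(roots) != 1:
        raise ValueError("SWC must have exactly one root")

    sections: list[Section] = []
    point_sec: dict[int, int] = {}

    def region_of(t: int) -> str:
        reg = _SWC_REGION.get(t, "dend")
        if interneuron and reg in ("basal", "apic"):
            reg = "dend"
        return reg

    # soma: all contiguous type-1 points from the root
    soma_pts = [roots[0]]
    stack = [roots[0]]
    while stack:
        k = stack.pop()
        for ch in children.get(k, []):
            if types[ch] == 1:
                soma_pts.append(ch)
                stack.append(ch)
    soma_xyz = xyz[soma_pts]
    if len(soma_pts) == 1:
        r = radii[soma_pts[0]]
        # single-point soma: equivalent cylinder length = diameter
        soma_xyz = np.vstack([soma_xyz[0] - [0, 0, r], soma_xyz[0] + [0, 0, r]])
        soma_d = np.array([2 * r, 2 * r])
    else:
        soma_d = 2 * radii[soma_pts]
    sections.append(Section("soma", soma_xyz, soma_d, -1))
    for k in soma_pts:
        point_sec[k] = 0

    # walk non-soma trees: a section is a run until branch point / type change
    def walk(start, parent_sec):
        run = [start]
        cur = start
        while True:
            ch = [c for c in children.get(cur, []) if types[c] != 1]
            if len(ch) == 1 and types[ch[0]] == types[cur]:
                cur = ch[0]
                run.append(cur)
            else:
                break
        # prepend the attachment point (child diameter) only when needed to
        # make the polyline well-formed; skip soma parents so the soma
        # extent does not leak into neurite length
        pk = id_map[parents[start]]
        if types[pk] == 1 and len(run) >= 2:
            pts = xyz[run]
            dms = 2 * radii[run]
        else:
            pts = np.vstack([xyz[pk], xyz[run]])
            dms = np.concatenate([[2 * radii[start]], 2 * radii[run]])
        sections.append(Section(region_of(types[start]), pts, dms, parent_sec))
        sec_idx = len(sections) - 1
        for k in run:
            point_sec.setdefault(k, sec_idx)
        for c in children.get(cur, []):
            if types[c] != 1:
                walk(c, sec_idx)

    for k in soma_pts:
        for ch in children.get(k, []):
            if types[ch] != 1:
                walk(ch, 0)

    return Morphology(sections, max_seg_len=max_seg_len)


def write_swc(morph: Morphology, path) -> None:
    """Write the morphology as a standard 7-column SWC file (1-based ids)."""
    lines = []
    next_id = 1
    sec_last_id = {}
    for si, sec in enumerate(morph.sections):
        t = _SWC_TYPE[sec.region]
        parent_id = -1 if sec.parent < 0 else sec_last_id[sec.parent]
        start = 0
        if sec.parent >= 0:
            start = 0  # repeat the first point as the section's own sample
        for k in range(start, len(sec.points)):
            x, y, z = sec.points[k]
            lines.append(f"{next_id} {t} {x:.3f} {y:.3f} {z:.3f} "
                         f"{sec.diams[k] / 2:.3f} {parent_id}")
            parent_id = next_id
            next_id += 1
        sec_last_id[si] = parent_id
    with open(path, "w") as fh:
        fh.write("# generated by optoca1\n")
        fh.write("\n".join(lines) + "\n")
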