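"""End-to-end experiment recipes on synthetic CA1 cells.

Three studies mirror the analysis stages of the pipeline: thresholds and
strength-duration regression under a uniform light field, position sweeps
and SoFPAN in the Monte Carlo fiber field, and an elementary-effects
sensitivity screen over the uncertain inputs (optical coefficients,
expression level, cell, opsin location, roll).  Each study is a plain
function of an :class:`ExperimentConfig`; outputs are pandas tables plus
metadata carrying the config hash and seeds for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cable, excitability as ex, light, morphology as morph, stats
from .opsin import OpsinParams

__all__ = [
    "ExperimentConfig",
    "build_cell",
    "build_field",
    "uniform_threshold",
    "mc_threshold_fn",
    "run_uniform_field_study",
    "run_mc_field_study",
    "run_sensitivity_study",
]

# production grids: G_max 8 log points in [1e-1, 10^1.5] uS; pd 5 log points
# in [1, 100] ms (9 in [1e-1, 1e3] for uniform-field runs)
GMAX_GRID = np.logspace(-1.0, 1.5, 8)
PD_GRID = np.logspace(0.0, 2.0, 5)
PD_GRID_UNIFORM = np.logspace(-1.0, 3.0, 9)


@dataclass
class ExperimentConfig:
    """Inputs, grids and seeds of one experiment."""

    cells: tuple = (("pyramidal", 1), ("basket", 1))
    regions: tuple = ("allsec", "soma")
    g_max_grid: tuple = (0.5, 1.0, 3.16)
    pd_grid: tuple = (3.16, 10.0, 100.0)
    pitches: tuple = (np.pi / 2,)
    i_fiber_grid: tuple = tuple(ex.I_FIBER_GRID)
    optics: dict = dc_field(default_factory=dict)
    n_photons: int = 100_000
    mc_dr: float = 0.01
    mc_dz: float = 0.01
    mc_seed: int = 0
    nx: int | None = None            # position-grid override (None = 11)
    nz: int | None = None
    max_seg_len: float = 20.0
    cell_scale: str = "full"         # "full" or "small" synthetic presets
    dt: float = 0.025
    out_dir: str | None = None

    def optical_properties(self) -> light.OpticalProperties:
        return light.OpticalProperties(**self.optics) if self.optics \
            else light.GRAY_MATTER

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha1(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(plain(dataclasses.asdict(self)), fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("cells", "regions", "g_max_grid", "pd_grid", "pitches",
                    "i_fiber_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(tuple(v) if isinstance(v, list) else v
                               for v in d[key])
        return cls(**d)


_SMALL_PYR = morph.PyramidalParams(n_basal=3, basal_depth=2, n_tuft=3,
                                   tuft_depth=2)
_SMALL_BASKET = morph.InterneuronParams(n_dend=4, dend_depth=2, n_axon=4,
                                        axon_depth=3)
_SMALL_BISTRAT = morph.InterneuronParams(n_dend=4, dend_depth=2, n_axon=7,
                                         axon_len=260.0, axon_diam=1.2,
                                         axon_depth=3)


def build_cell(kind: str, seed: int = 1, max_seg_len: float = 20.0,
               scale: str = "full") -> morph.Morphology:
    """Synthetic cell factory (``pyramidal``, ``basket``, ``bistratified``
    or an SWC path)."""
    small = scale == "small"
    if kind == "pyramidal":
        return morph.generate_pyramidal(_SMALL_PYR if small else None,
                                        seed=seed, max_seg_len=max_seg_len)
    if kind == "basket":
        return morph.generate_interneuron(
            _SMALL_BASKET if small else "basket", seed=seed,
            max_seg_len=max_seg_len)
    if kind == "bistratified":
        return morph.generate_interneuron(
            _SMALL_BISTRAT if small else "bistratified", seed=seed,
            max_seg_len=max_seg_len)
    path = Path(kind)
    if path.suffix.lower() == ".swc" and path.exists():
        return morph.read_swc(path, max_seg_len=max_seg_len)
    raise ValueError(f"unknown cell kind {kind!r}")


def build_field(config: ExperimentConfig, cache_dir=None) -> light.FluenceField:
    """Build (or load from cache) the fiber fluence field."""
    optics = config.optical_properties()
    fiber = light.FiberSpec()
    key_src = json.dumps([dataclasses.asdict(optics), config.n_photons,
                          config.mc_dr, config.mc_dz, config.mc_seed],
                         sort_keys=True)
    key = hashlib.sha1(key_src.encode()).hexdigest()[:16]
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        path = cache_dir / f"field_{key}.h5"
        if path.exists():
            return light.FluenceField.load(path)
    fld = light.run_monte_carlo(optics, fiber, dr=config.mc_dr,
                                dz=config.mc_dz, n_photons=config.n_photons,
                                seed=config.mc_seed)
    if cache_dir is not None:
        fld.save(path)
    return fld


def uniform_threshold(cell: morph.Morphology, membrane: cable.MembraneModel,
                      region: str, g_max: float, pd: float,
                      dt: float = 0.025,
                      opsin_params: OpsinParams | None = None):
    """(I_th, TAC at threshold) under spatially uniform irradiance."""
    gdist = morph.distribute_opsin(cell, region, g_max)
    areas = cell.segments().area
    tac_holder = {}

    def spike_at(i_fiber):
        stim = cable.StimulusProtocol(pd=pd, i_fiber=i_fiber)
        res = cable.simulate(cell, membrane, gdist, stim, uniform=True,
                             dt=dt, opsin_params=opsin_params)
        spk = cable.detect_spike(res.v_soma, res.t, stim.t0, stim.t_end)
        tac_holder[i_fiber] = ex.tac_from_integrals(res.chr2_time_integral,
                                                    areas, pd)
        return spk

    i_th = ex.titrate_threshold(spike_at)
    if np.isnan(i_th):
        return np.nan, np.nan
    stim = cable.StimulusProtocol(pd=pd, i_fiber=i_th)
    res = cable.simulate(cell, membrane, gdist, stim, uniform=True, dt=dt,
                         opsin_params=opsin_params)
    tac = ex.tac_from_integrals(res.chr2_time_integral, areas, pd)
    # report the magnitude of the (inward, hence negative) photocurrent
    return float(i_th), float(abs(tac))


def mc_threshold_fn(cell: morph.Morphology, membrane: cable.MembraneModel,
                    region: str, g_max: float, pd: float,
                    fld: light.FluenceField, pitch: float,
                    roll: float = 0.0, dt: float = 0.025,
                    opsin_params: OpsinParams | None = None):
    """Closure (x, z) -> (I_th, TAC) for a position sweep in the MC field."""
    gdist = morph.distribute_opsin(cell, region, g_max)
    areas = cell.segments().area

    def threshold_at(x_um, z_um):
        fiber = light.FiberSpec(pitch=pitch, position=(x_um, z_um))

        def spike_at(i_fiber):
            stim = cable.StimulusProtocol(pd=pd, i_fiber=i_fiber)
            res = cable.simulate(cell, membrane, gdist, stim, field=fld,
                                 fiber=fiber, roll=roll, dt=dt,
                                 opsin_params=opsin_params)
            return cable.detect_spike(res.v_soma, res.t, stim.t0, stim.t_end)

        i_th = ex.titrate_threshold(spike_at)
        if np.isnan(i_th):
            return np.nan, np.nan
        stim = cable.StimulusProtocol(pd=pd, i_fiber=i_th)
        res = cable.simulate(cell, membrane, gdist, stim, field=fld,
                             fiber=fiber, roll=roll, dt=dt,
                             opsin_params=opsin_params)
        return float(i_th), abs(ex.tac_from_integrals(res.chr2_time_integral,
                                                      areas, pd))

    return threshold_at


def _regions_for(cell_kind: str, regions) -> list:
    """Drop the basal/apic split for interneurons."""
    interneuron = cell_kind in ("basket", "bistratified")
    out = []
    for r in regions:
        if interneuron and r in ("basal", "apic"):
            continue
        out.append(r)
    return out


def run_uniform_field_study(config: ExperimentConfig,
                            membrane: cable.MembraneModel | None = None):
    """Uniform-irradiance thresholds, regression fits and Wilcoxon scores."""
    membrane = membrane or cable.MembraneModel()
    rows = []
    for kind, seed in config.cells:
        cell = build_cell(kind, seed, config.max_seg_len, config.cell_scale)
        for region in _regions_for(kind, config.regions):
            for pd_ms in config.pd_grid:
                for g_max in config.g_max_grid:
                    try:
                        i_th, tac = uniform_threshold(cell, membrane, region,
                                                      g_max, pd_ms, config.dt)
                    except Exception as exc:  # noqa: BLE001 - isolate stages
                        i_th, tac = np.nan, np.nan
                        rows.append(dict(cell=kind, region=region, pd=pd_ms,
                                         g_max=g_max, i_th=i_th, tac=tac,
                                         error=str(exc)))
                        continue
                    rows.append(dict(cell=kind, region=region, pd=pd_ms,
                                     g_max=g_max, i_th=i_th, tac=tac,
                                     error=""))
    table = pd.DataFrame(rows)

    fits = []
    for (kind, region), grp in table.groupby(["cell", "region"]):
        ok = grp.dropna(subset=["i_th", "tac"])
        ok = ok[(ok.i_th > 0) & (ok.tac > 0)]
        if len(ok) < 4 or ok.g_max.nunique() < 2 or ok.pd.nunique() < 3:
            continue
        try:
            fit = stats.fit_two_step(ok.pd.values, ok.g_max.values,
                                     ok.tac.values, ok.i_th.values)
        except (ValueError, RuntimeError):
            continue
        fits.append(dict(cell=kind, region=region, tac0=fit.tac0,
                         tau_tac=fit.tau_tac, r2_tac=fit.r2_tac,
                         a_g=fit.a_g, a_pd=fit.a_pd, c=fit.c,
                         r2_tot=fit.r2_tot))
    fits = pd.DataFrame(fits)

    # class scores on I_th (lower is better), paired over (pd, G_max)
    vectors = {}
    for (kind, region), grp in table.groupby(["cell", "region"]):
        v = grp.sort_values(["pd", "g_max"]).i_th.values
        if np.all(np.isfinite(v)):
            vectors[f"{region}-{kind}"] = v
    scores = {}
    if len(vectors) >= 2:
        scores, _ = stats.wilcoxon_excitability_scores(vectors,
                                                       larger_is_better=False)

    meta = dict(config_hash=config.config_hash(), stage="uniform")
    out = dict(thresholds=table, fits=fits, scores=scores, meta=meta)
    _maybe_save(config, out, "uniform")
    return out


def run_mc_field_study(config: ExperimentConfig,
                       membrane: cable.MembraneModel | None = None,
                       fld: light.FluenceField | None = None,
                       pd_ms: float = 10.0, g_max: float = 1.0,
                       uniform_table: pd.DataFrame | None = None):
    """Position sweeps, SoFPAN curves with bounds, optimal/worst z, and the
    uniform-approximation error, per pitch and (cell, region)."""
    membrane = membrane or cable.MembraneModel()
    if fld is None:
        fld = build_field(config, cache_dir=config.out_dir)
    maps = {}
    sofpan_rows = []
    pos_rows = []
    err_rows = []
    for kind, seed in config.cells:
        cell = build_cell(kind, seed, config.max_seg_len, config.cell_scale)
        soma_xyz = cell.segments().centroid[
            cell.segments().region == "soma"].mean(axis=0)
        for region in _regions_for(kind, config.regions):
            try:
                i_th_u, _ = uniform_threshold(cell, membrane, region, g_max,
                                              pd_ms, config.dt)
            except Exception:  # noqa: BLE001
                i_th_u = np.nan
            for pitch in config.pitches:
                tfn = mc_threshold_fn(cell, membrane, region, g_max, pd_ms,
                                      fld, pitch, dt=config.dt)
                tmap = ex.sweep_positions(tfn, pitch, config.nx, config.nz,
                                          pd=pd_ms, g_max=g_max,
                                          region=region, cell_id=kind)
                maps[(kind, region, pitch)] = tmap
                umap = ex.sofpan_uniform_map(
                    i_th_u, fld,
                    lambda x, z, p=pitch: light.FiberSpec(pitch=p,
                                                          position=(x, z)),
                    soma_xyz, pitch, config.nx, config.nz,
                    pd=pd_ms, g_max=g_max, region=region)
                for i_f in config.i_fiber_grid:
                    sp = ex.sofpan(tmap, i_f)
                    sofpan_rows.append(dict(
                        cell=kind, region=region, pitch=pitch, i_fiber=i_f,
                        lower=sp.lower, estimate=sp.estimate, upper=sp.upper))
                    sp_u = ex.sofpan(umap, i_f)
                    err_rows.append(dict(
                        cell=kind, region=region, pitch=pitch, i_fiber=i_f,
                        sofpan_mc=sp.estimate, sofpan_uniform=sp_u.estimate,
                        rel_error=ex.relative_error(sp_u.estimate,
                                                    sp.estimate)))
                    try:
                        z_opt, z_worst = ex.optimal_worst_positions(tmap, i_f)
                    except ValueError:
                        z_opt = z_worst = np.nan
                    pos_rows.append(dict(cell=kind, region=region,
                                         pitch=pitch, i_fiber=i_f,
                                         z_opt=z_opt, z_worst=z_worst))
    meta = dict(config_hash=config.config_hash(), stage="mc",
                field_seed=config.mc_seed, pd=pd_ms, g_max=g_max)
    out = dict(maps=maps, sofpan=pd.DataFrame(sofpan_rows),
               positions=pd.DataFrame(pos_rows),
               uniform_error=pd.DataFrame(err_rows), meta=meta)
    _maybe_save(config, {k: v for k, v in out.items() if k != "maps"}, "mc")
    return out


def default_ee_factors(pyramidal: bool = True) -> list:
    """The six uncertain factors of the sensitivity screen."""
    locations = ("allsec", "axon", "soma", "basal") if pyramidal \
        else ("allsec", "axon", "soma")
    cells = ("pyr_a", "pyr_b") if pyramidal else ("int_a", "int_b")
    return [
        stats.EEFactorSpec("mu_a", "normal", (0.42, 0.15)),
        stats.EEFactorSpec("mu_s_prime", "normal", (11.33 * (1 - 0.88), 0.15)),
        stats.EEFactorSpec("g_max", "normal", (1.0, 0.15)),
        stats.EEFactorSpec("cell", "discrete", cells),
        stats.EEFactorSpec("location", "discrete", locations),
        stats.EEFactorSpec("roll", "uniform", (-np.pi, np.pi)),
    ]


def run_sensitivity_study(config: ExperimentConfig, r: int = 4,
                          seed: int = 0, pd_ms: float = 10.0,
                          i_fiber: float = 10.0, pitch: float = np.pi / 2,
                          pyramidal: bool = True,
                          membrane: cable.MembraneModel | None = None):
    """Elementary-effects screen of SoFPAN over the six uncertain factors.

    The wrapped model builds a fluence field for the sampled optics
    (cached per optics pair), sweeps a reduced position grid and returns
    the SoFPAN estimate at ``i_fiber``.
    """
    membrane = membrane or cable.MembraneModel()
    factors = default_ee_factors(pyramidal)
    cell_seeds = {"pyr_a": 1, "pyr_b": 2, "int_a": 1, "int_b": 2}
    cell_kind = {"pyr_a": "pyramidal", "pyr_b": "pyramidal",
                 "int_a": "basket", "int_b": "bistratified"}
    field_cache = {}
    cells_cache = {}

    def model(x):
        mu_a, mu_sp, g_max, cell_label, location, roll = x
        okey = (round(float(mu_a), 9), round(float(mu_sp), 9))
        if okey not in field_cache:
            optics = light.OpticalProperties.from_reduced(
                max(float(mu_a), 1e-4), max(float(mu_sp), 1e-4))
            field_cache[okey] = light.run_monte_carlo(
                optics, light.FiberSpec(), dr=config.mc_dr, dz=config.mc_dz,
                n_photons=config.n_photons, seed=config.mc_seed)
        fld = field_cache[okey]
        if cell_label not in cells_cache:
            cells_cache[cell_label] = build_cell(
                cell_kind[cell_label], cell_seeds[cell_label],
                config.max_seg_len, config.cell_scale)
        cell = cells_cache[cell_label]
        tfn = mc_threshold_fn(cell, membrane, location, max(float(g_max), 1e-3),
                              pd_ms, fld, pitch, roll=float(roll),
                              dt=config.dt)
        tmap = ex.sweep_positions(tfn, pitch, config.nx, config.nz, pd=pd_ms,
                                  g_max=g_max, region=location)
        return ex.sofpan(tmap, i_fiber).estimate

    result = stats.elementary_effects(model, factors, r=r, seed=seed)
    meta = dict(config_hash=config.config_hash(), stage="ee", seed=seed,
                r=r, pd=pd_ms, i_fiber=i_fiber, pitch=pitch)
    out = dict(ee=result, table=result.to_dataframe(), meta=meta)
    _maybe_save(config, {"table": out["table"], "meta": meta}, "ee")
    return out


def _maybe_save(config: ExperimentConfig, out: dict, stage: str) -> None:
    if config.out_dir is None:
        return
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in out.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{stage}_{name}.csv", index=False)
    meta = dict(out.get("meta", {}))
    meta["config_hash"] = config.config_hash()
    with open(out_dir / f"{stage}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
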