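"""End-to-end orchestration: synthgen -> climatology -> train -> flux ->
ebullition -> attribute -> report.

Each stage reads its inputs from the run directory and writes its outputs
there, so stages can be re-run individually; a missing upstream artifact
raises a :class:`StageError` naming the stage.  A run manifest records the
config snapshot, per-stage derived seeds, timings, row/cell counts and
output-file digests; identical config + seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import attribution as attr
from . import ebullition as eb
from . import flux as fx
from . import mapping as mp
from .disequilibrium import (AtmosphericField, bin_climatology, delta_ch4,
                             mixed_layer_filter, perturb_measurements)
from .synthetic import (SyntheticWorldConfig, hypsometry_table, make_world,
                        mld_climatology, stage_seed)

STAGES = ("synthgen", "climatology", "train", "flux", "ebullition",
          "attribute", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    world: SyntheticWorldConfig = field(default_factory=SyntheticWorldConfig)
    n_members: int = 100              # per model family
    families: tuple = ("ann", "rrf")
    n_draws: int = 1000
    measurement_relative_error: float = 0.0
    seafloor_flux_best: float = 35.0          # Tg yr^-1
    seafloor_flux_range: tuple = (18.0, 48.0)
    seep_depth_scenarios: tuple = ((0.0, 200.0), (0.0, 100.0))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        world = SyntheticWorldConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("world", {}) or {}).items()
        })
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        cfg = cls(world=world, **raw)
        if "seed" in raw:
            cfg.world.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_nc(ds: xr.Dataset, path: Path) -> None:
    ds.to_netcdf(path, engine="scipy")


def _require(path: Path, stage: str) -> Path:
    if not Path(path).exists():
        raise StageError(stage, f"missing upstream artifact {path}")
    return Path(path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_synthgen(config: PipelineConfig, outdir: Path) -> dict:
    world = make_world(config.world)
    world.observations.to_csv(outdir / "observations.csv", index=False)
    world.stations.to_csv(outdir / "stations.csv", index=False)
    _write_nc(world.fields, outdir / "fields.nc")
    _write_nc(world.winds.to_dataset(name="u10"), outdir / "winds.nc")
    _write_nc(world.ices.to_dataset(name="f_ice"), outdir / "ices.nc")
    world.bubble_spectrum.to_csv(outdir / "bubble_spectrum.csv", index=False)
    hyps = hypsometry_table(world.fields)
    hyps.to_csv(outdir / "hypsometry.csv", index=False)
    return {"n_observations": len(world.observations),
            "n_grid_cells": int(world.fields["depth_m"].size)}


def stage_climatology(config: PipelineConfig, outdir: Path) -> dict:
    obs = pd.read_csv(_require(outdir / "observations.csv", "climatology"))
    stations = pd.read_csv(_require(outdir / "stations.csv", "climatology"))
    fields = xr.open_dataset(_require(outdir / "fields.nc", "climatology"),
                             engine="scipy").load()
    if config.measurement_relative_error > 0:
        obs = perturb_measurements(obs, config.measurement_relative_error,
                                   stage_seed(config.seed, "perturb"))
    kept = mixed_layer_filter(obs, mld_climatology)
    atm = AtmosphericField(stations)
    records = delta_ch4(kept, atm)
    w = config.world
    clim = bin_climatology(records, w.resolution, w.lat_extent, w.lon_extent,
                           depth_field=fields["depth_m"])
    _write_nc(clim, outdir / "climatology.nc")
    records.drop(columns=["date"]).assign(date=records["date"].astype(str)) \
        .to_csv(outdir / "records_dch4.csv", index=False)
    return {"n_records_in": len(obs), "n_records_kept": len(kept),
            "n_cell_months": int((clim["count"].values > 0).sum())}


def stage_train(config: PipelineConfig, outdir: Path) -> dict:
    clim = xr.open_dataset(_require(outdir / "climatology.nc", "train"),
                           engine="scipy").load()
    fields = xr.open_dataset(_require(outdir / "fields.nc", "train"),
                             engine="scipy").load()
    table = mp.build_training_table(clim, fields)
    ens = mp.generate_ensemble(table, fields, n_members=config.n_members,
                               families=config.families,
                               seed=stage_seed(config.seed, "train"))
    maps = xr.Dataset(
        {"dch4_nM": (("member", "month", "lat", "lon"), ens.maps)},
        coords={"member": np.arange(ens.maps.shape[0]),
                "month": np.arange(1, 13),
                "lat": ens.lat, "lon": ens.lon},
    )
    maps["family"] = ("member", ens.families.astype("U8"))
    _write_nc(maps, outdir / "maps.nc")
    ens.skills.to_csv(outdir / "member_skills.csv", index=False)
    baselines = mp.baseline_models(table, seed=stage_seed(config.seed, "baseline"))
    (outdir / "baselines.json").write_text(json.dumps(baselines, indent=2))
    return {"n_training_rows": len(table), "n_members": len(ens.members),
            "min_val_R": float(ens.skills["R"].min())}


def _load_ensemble(outdir: Path, stage: str) -> mp.MapEnsemble:
    maps = xr.open_dataset(_require(outdir / "maps.nc", stage),
                           engine="scipy").load()
    return mp.MapEnsemble(
        members=[], maps=maps["dch4_nM"].values,
        families=maps["family"].values.astype(str),
        lat=maps["lat"].values, lon=maps["lon"].values,
    )


def stage_flux(config: PipelineConfig, outdir: Path) -> dict:
    ens = _load_ensemble(outdir, "flux")
    fields = xr.open_dataset(_require(outdir / "fields.nc", "flux"),
                             engine="scipy").load()
    winds = xr.open_dataset(_require(outdir / "winds.nc", "flux"),
                            engine="scipy").load()["u10"]
    ices = xr.open_dataset(_require(outdir / "ices.nc", "flux"),
                           engine="scipy").load()["f_ice"]
    result = fx.monte_carlo(
        ens, winds, ices, fields["sst_C"].values,
        fields["cell_area"].values, fields["region"].values,
        n_draws=config.n_draws, seed=stage_seed(config.seed, "flux"),
    )
    result.table.to_csv(outdir / "flux_members.csv", index=False)
    result.summary().to_csv(outdir / "flux_summary.csv", index=False)
    vp = fx.variance_partition(ens, winds, ices, fields["sst_C"].values,
                               fields["cell_area"].values,
                               fields["region"].values)
    (outdir / "variance_partition.json").write_text(json.dumps(
        {k: v for k, v in vp.items() if np.ndim(v) == 0}, indent=2))
    return {"n_draws": config.n_draws,
            "global_mean_Tg": float(result.table["global"].mean())}


def stage_ebullition(config: PipelineConfig, outdir: Path) -> dict:
    spectrum = pd.read_csv(_require(outdir / "bubble_spectrum.csv", "ebullition"))
    hyps = pd.read_csv(_require(outdir / "hypsometry.csv", "ebullition"))
    members = pd.read_csv(_require(outdir / "flux_members.csv", "ebullition"))
    depths = np.concatenate([np.arange(1.0, 30.0, 2.0),
                             np.arange(30.0, 101.0, 5.0),
                             np.arange(110.0, 201.0, 10.0)])
    curve = eb.efficiency_curve(spectrum, depths)
    curve.to_csv(outdir / "transfer_efficiency.csv", index=False)
    eps = {f"{int(lo)}-{int(hi)}m": eb.depth_averaged_efficiency(curve, hyps, (lo, hi))
           for lo, hi in config.seep_depth_scenarios}
    eps_range = (min(eps.values()), max(eps.values()))
    best = eb.ebullitive_emissions(eps_range, config.seafloor_flux_best)
    full = eb.ebullitive_emissions(eps_range, config.seafloor_flux_range)
    diffusive = members["global"].to_numpy()
    seed = stage_seed(config.seed, "ebullition")
    totals = {
        "best": {k: float(v) for k, v in
                 eb.total_emissions(diffusive, best, seed=seed).items()
                 if np.ndim(v) == 0},
        "full": {k: float(v) for k, v in
                 eb.total_emissions(diffusive, full, seed=seed + 1).items()
                 if np.ndim(v) == 0},
    }
    summary = {"depth_averaged_efficiency": eps,
               "ebullitive_interval_best_Tg": list(best),
               "ebullitive_interval_full_Tg": list(full),
               "total_emissions_Tg": totals}
    (outdir / "ebullition_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def stage_attribute(config: PipelineConfig, outdir: Path) -> dict:
    ens = _load_ensemble(outdir, "attribute")
    fields = xr.open_dataset(_require(outdir / "fields.nc", "attribute"),
                             engine="scipy").load()
    mean_map = ens.mean_map().mean(axis=0)  # annual mean of ensemble mean
    report = attr.attribution_report(xr.DataArray(mean_map), fields)
    report["coastal_correlations"].to_csv(outdir / "correlations_coastal.csv",
                                          index=False)
    report["open_correlations"].to_csv(outdir / "correlations_open.csv",
                                       index=False)
    report["bands"].to_csv(outdir / "band_averages.csv", index=False)
    fits = {k: report[k] for k in ("powerlaw", "npp", "mlr")}
    (outdir / "attribution_fits.json").write_text(json.dumps(fits, indent=2))
    return fits


def write_figures(outdir: Path) -> list[str]:
    """Optional diagnostic figures: flux distributions, skill, eps_tr(z)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    members = pd.read_csv(_require(outdir / "flux_members.csv", "report"))
    fig, ax = plt.subplots(figsize=(6, 4))
    regions = [c for c in ("near-shore", "outer shelf", "slope", "open ocean",
                           "global") if c in members]
    ax.violinplot([members[c] for c in regions], showmedians=True)
    ax.set_xticks(range(1, len(regions) + 1), regions, rotation=20)
    ax.set_ylabel("annual emission (Tg CH$_4$ yr$^{-1}$)")
    fig.tight_layout()
    fig.savefig(outdir / "flux_distributions.png", dpi=120)
    plt.close(fig)
    written.append("flux_distributions.png")

    skills_path = outdir / "member_skills.csv"
    if skills_path.exists():
        skills = pd.read_csv(skills_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        for fam, grp in skills.groupby("family"):
            ax.scatter(grp["norm_sd"], grp["R"], label=fam, alpha=0.7)
        ax.set_xlabel("normalized s.d.")
        ax.set_ylabel("validation correlation R")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "member_skill.png", dpi=120)
        plt.close(fig)
        written.append("member_skill.png")

    curve_path = outdir / "transfer_efficiency.csv"
    if curve_path.exists():
        curve = pd.read_csv(curve_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(curve["eps_tr"], curve["depth_m"])
        ax.invert_yaxis()
        ax.set_xlabel(r"transfer efficiency $\epsilon_{tr}$")
        ax.set_ylabel("release depth (m)")
        fig.tight_layout()
        fig.savefig(outdir / "transfer_efficiency.png", dpi=120)
        plt.close(fig)
        written.append("transfer_efficiency.png")
    return written


def stage_report(config: PipelineConfig, outdir: Path) -> dict:
    summary_path = _require(outdir / "flux_summary.csv", "report")
    members = pd.read_csv(_require(outdir / "flux_members.csv", "report"))
    summary = pd.read_csv(summary_path)
    ebsum = json.loads(_require(outdir / "ebullition_summary.json",
                                "report").read_text())
    fits = json.loads(_require(outdir / "attribution_fits.json",
                               "report").read_text())
    lines = ["# Ocean CH4 emission run report", ""]
    if len(members) == 0:
        lines.append("no members")
    else:
        lines.append("## Diffusive emissions (Tg CH4 yr^-1)")
        lines.append(summary.to_string(index=False))
        lines.append("")
        lines.append("## Ebullitive emissions")
        lines.append(
            f"depth-averaged transfer efficiency: "
            f"{ {k: round(v, 4) for k, v in ebsum['depth_averaged_efficiency'].items()} }"
        )
        lines.append(f"interval (best seafloor flux): "
                     f"{[round(v, 2) for v in ebsum['ebullitive_interval_best_Tg']]} Tg/yr")
        lines.append(f"interval (full seafloor range): "
                     f"{[round(v, 2) for v in ebsum['ebullitive_interval_full_Tg']]} Tg/yr")
        lines.append("")
        lines.append("## Total emissions (Tg CH4 yr^-1)")
        for name, t in ebsum["total_emissions_Tg"].items():
            lines.append(f"{name}: mean {t['mean']:.2f}, "
                         f"10-90th {t['p10']:.2f}-{t['p90']:.2f}")
        lines.append("")
        lines.append("## Attribution")
        pl = fits["powerlaw"]
        lines.append(f"coastal power law: dCH4 = {pl['amplitude']:.1f} "
                     f"z^{pl['exponent']:.2f} (R2 = {pl['r2']:.2f})")
        npp = fits["npp"]
        lines.append(f"open-ocean NPP fit: dCH4 = ({npp['slope'] * 1e3:.2f} NPP"
                     f" + {npp['intercept'] * 1e3:.1f})/1e3 (R2 = {npp['r2']:.2f})")
    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text)
    return {"report_path": str(outdir / "report.md")}


_STAGE_FUNCS = {
    "synthgen": stage_synthgen,
    "climatology": stage_climatology,
    "train": stage_train,
    "flux": stage_flux,
    "ebullition": stage_ebullition,
    "attribute": stage_attribute,
    "report": stage_report,
}


def run_stage(stage: str, config: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}")
    try:
        return _STAGE_FUNCS[stage](config, outdir)
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, str(err)) from err


def run_pipeline(config: PipelineConfig, outdir, stages=STAGES) -> dict:
    """Execute stages in order; returns the run manifest (also written)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.world.seed = stage_seed(config.seed, "world")
    manifest = {
        "config": config.to_dict(),
        "seeds": {s: stage_seed(config.seed, s) for s in stages},
        "stages": {},
    }
    for stage in stages:
        t0 = time.perf_counter()
        info = run_stage(stage, config, outdir)
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "info": {k: v for k, v in info.items()
                     if isinstance(v, (int, float, str))},
        }
    manifest["digests"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.suffix in (".csv", ".nc", ".json", ".md") and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
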