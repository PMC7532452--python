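"""Cohort-scale orchestration: simulate → analyze → report.

Each stage communicates with the next only through files (NIfTI images,
JSON sidecars, CSV tables) listed in a run manifest, so stages can be
rerun, resumed after interruption, and regenerated reproducibly from a
config and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import adc as adc_mod
from . import dce as dce_mod
from . import io as io_mod
from .experiments import _RECON_ROIS, _check_orderings, unit_region_fits
from .phantom import CohortSpec, default_cohort_spec, sample_cohort
from .presets import MODEL_CLASSES
from .spen import SpenSequenceParams, default_diffusion_modules, simulate_dwi_series

log = logging.getLogger("fetomri")

ANALYSIS_ROIS = _RECON_ROIS


@dataclass(frozen=True)
class RunConfig:
    """Plain-text run configuration; the master seed feeds every stage."""

    models: tuple[str, ...] = MODEL_CLASSES
    days: tuple[float, ...] | None = None  # None -> per-model defaults
    grid: int = 160
    pixel_size: float = 0.1875
    fov: float = 30.0
    n_interleaves: int = 5
    tp: float = 20.0
    r_factor: float = 450.0
    snr: float | None = 40.0
    n_dams: int | None = None
    units_per_dam: tuple[int, int] | None = None
    dce: bool = True
    dce_day: float = 14.5
    min_bins: int = 8
    slope_window: int = 3
    alpha: float = 0.05
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("models", "days", "units_per_dam"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def sequence_params(self) -> SpenSequenceParams:
        return SpenSequenceParams(
            fov=self.fov,
            matrix=self.grid,
            tp=self.tp,
            r_factor=self.r_factor,
            n_interleaves=self.n_interleaves,
        )

    def cohort_spec(self, model: str) -> CohortSpec:
        spec = default_cohort_spec(model, seed=self.seed)
        kw = dataclasses.asdict(spec)
        if self.days is not None:
            days = tuple(self.days)
            if model == "lname":
                days = tuple(d for d in days if d <= 16.5) or (min(self.days),)
            kw["gestational_days"] = days
        if self.n_dams is not None:
            kw["n_dams"] = self.n_dams
        if self.units_per_dam is not None:
            kw["units_per_dam"] = tuple(self.units_per_dam)
        kw["units_per_dam"] = tuple(kw["units_per_dam"])
        kw["gestational_days"] = tuple(kw["gestational_days"])
        return CohortSpec(**kw)


class Manifest:
    """Append-only record of every file a run wrote, with seeds and stamps."""

    def __init__(self, outdir: Path, config: RunConfig):
        self.path = Path(outdir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if self.data["config_hash"] != config.hash:
                raise ValueError("existing manifest belongs to a different config")
        else:
            self.data = dict(
                config_hash=config.hash,
                config=json.loads(config.to_json()),
                entries=[],
            )

    def has(self, key: str) -> bool:
        return any(e["key"] == key for e in self.data["entries"])

    def add(self, key: str, stage: str, files: list, **meta) -> None:
        self.data["entries"].append(
            dict(
                key=key,
                stage=stage,
                files=[str(f) for f in files],
                timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                **meta,
            )
        )
        self.save()

    def entries(self, stage: str) -> list[dict]:
        return [e for e in self.data["entries"] if e["stage"] == stage]

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=1))


def simulate(config: RunConfig, outdir: Path) -> Manifest:
    """Generate every cohort unit and its SPEN DWI (and optional DCE) data.

    Units already present in the manifest are skipped, making an
    interrupted run resumable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    params = config.sequence_params()
    dms = default_diffusion_modules()
    for model in config.models:
        spec = config.cohort_spec(model)
        phantoms = sample_cohort(spec, grid_shape=(config.grid, config.grid),
                                 pixel_size=config.pixel_size)
        for ph in phantoms:
            key = f"{model}/dam{ph.dam_id}/unit{ph.unit_id}/day{ph.gestational_day}"
            if manifest.has(key):
                continue
            t0 = time.time()
            udir = outdir / key
            paths = io_mod.save_phantom(ph, udir)
            series = simulate_dwi_series(
                ph, params, dms=dms, snr=config.snr, seed=config.seed
            )
            paths.update(io_mod.save_dwi_series(series, udir, config.pixel_size))
            files = list(paths.values())
            if config.dce and np.isclose(ph.gestational_day, config.dce_day):
                dseries = dce_mod.simulate_dce(
                    ph, dce_mod.FlashParams(), snr=None, seed=config.seed
                )
                files += list(
                    io_mod.save_dce_series(
                        dseries.signal, dseries.timestamps, udir, config.pixel_size
                    ).values()
                )
            manifest.add(
                key, "simulate", files,
                model=model, dam=ph.dam_id, unit=ph.unit_id,
                day=ph.gestational_day, seed=config.seed,
            )
            log.info("simulated %s in %.1fs", key, time.time() - t0)
    return manifest


def _unit_dirs(manifest: Manifest, outdir: Path):
    for e in manifest.entries("simulate"):
        yield e, Path(outdir) / e["key"]


def analyze(
    config: RunConfig, outdir: Path, stage: str = "both", make_plots: bool = False
) -> dict[str, Path]:
    """ADC and/or DCE analysis of a simulated run → cohort CSV tables."""
    if stage not in ("adc", "dce", "both"):
        raise ValueError("stage must be adc, dce or both")
    outdir = Path(outdir)
    manifest = Manifest(outdir, config)
    written: dict[str, Path] = {}

    if stage in ("adc", "both"):
        fits = []
        for e, udir in _unit_dirs(manifest, outdir):
            ph = io_mod.load_phantom(udir)
            series = io_mod.load_dwi_series(udir)
            amap = adc_mod.fit_adc(series)
            io_mod.save_nifti(amap.adc, udir / "adc.nii", config.pixel_size)
            fits.extend(unit_region_fits(ph, amap, e["model"], ANALYSIS_ROIS))
        table = adc_mod.longitudinal_summary(fits)
        breakdown = adc_mod.per_animal_breakdown(fits)
        unit_table = adc_mod.fits_to_frame(fits)
        written["adc_cohort_table"] = outdir / "adc_cohort_table.csv"
        table.to_csv(written["adc_cohort_table"], index=False, float_format="%.8g")
        written["adc_per_animal"] = outdir / "adc_per_animal.csv"
        breakdown.to_csv(written["adc_per_animal"], index=False, float_format="%.8g")
        written["adc_unit_fits"] = outdir / "adc_unit_fits.csv"
        unit_table.to_csv(written["adc_unit_fits"], index=False, float_format="%.8g")

        contrasts = []
        days = sorted(table.gestational_day.unique())
        for roi in ANALYSIS_ROIS:
            for day in days:
                for model in config.models:
                    if model == "wildtype":
                        continue
                    try:
                        wt = table[(table.model_class == "wildtype")]
                        other = table[(table.model_class == model)]
                        res = adc_mod.compare_models(wt, other, "mu", day, roi)
                    except ValueError:
                        continue
                    contrasts.append(
                        dict(roi_label=roi, gestational_day=day,
                             model_class=model, **res)
                    )
        written["adc_model_contrasts"] = outdir / "adc_model_contrasts.csv"
        pd.DataFrame(contrasts).to_csv(
            written["adc_model_contrasts"], index=False, float_format="%.8g"
        )
        if make_plots:
            written["adc_figure"] = _plot_longitudinal(table, outdir)

    if stage in ("dce", "both"):
        pairs = []
        for e, udir in _unit_dirs(manifest, outdir):
            if not (udir / "dce.nii").exists():
                continue
            ph = io_mod.load_phantom(udir)
            sig = np.moveaxis(io_mod.load_nifti(udir / "dce.nii"), -1, 0)
            ts = np.asarray(
                json.loads((udir / "dce_timestamps.json").read_text())["timestamps_s"]
            )
            series = dce_mod.DceSeries(
                signal=sig, timestamps=ts, params=dce_mod.FlashParams(),
                aif=dce_mod.AifModel(),
                t10_map=ph.truth_maps["t1"], k_map=ph.truth_maps["proton_density"],
            )
            pm = dce_mod.steepest_slope_perfusion(series, window=config.slope_window)
            io_mod.save_nifti(pm.f, udir / "perfusion.nii", config.pixel_size)
            pairs.append((pm, ph))
        if pairs:
            summary, per_unit = dce_mod.perfusion_roi_summary(pairs)
            written["perfusion_summary"] = outdir / "perfusion_summary.csv"
            summary.to_csv(written["perfusion_summary"], index=False,
                           float_format="%.8g")
            written["perfusion_units"] = outdir / "perfusion_units.csv"
            per_unit.to_csv(written["perfusion_units"], index=False,
                            float_format="%.8g")
    return written


def _plot_longitudinal(table: pd.DataFrame, outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(ANALYSIS_ROIS), figsize=(4 * len(ANALYSIS_ROIS), 3))
    for ax, roi in zip(np.atleast_1d(axes), ANALYSIS_ROIS):
        for model, g in table[table.roi_label == roi].groupby("model_class"):
            g = g.sort_values("gestational_day")
            ax.errorbar(g.gestational_day, g.mu_mean * 1e3, yerr=g.mu_spread * 1e3,
                        marker="o", capsize=3, label=model)
        ax.set_title(roi)
        ax.set_xlabel("gestational day")
        ax.set_ylabel("ADC (10$^{-3}$ mm$^2$/s)")
    axes_flat = np.atleast_1d(axes)
    axes_flat[0].legend(fontsize=7)
    fig.tight_layout()
    path = outdir / "adc_longitudinal.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def report(config: RunConfig, outdir: Path) -> dict:
    """Evaluate the run's designed directional properties and write a JSON
    plus human-readable summary; pure given the run's output files."""
    outdir = Path(outdir)
    table = pd.read_csv(outdir / "adc_cohort_table.csv")
    checks = _check_orderings(table)
    rep = dict(
        config_hash=config.hash,
        seed=config.seed,
        n_rows=len(table),
        checks={k: bool(v) for k, v in checks.items()},
        all_passed=bool(all(checks.values())) if checks else False,
    )
    perf_path = outdir / "perfusion_summary.csv"
    if perf_path.exists():
        perf = pd.read_csv(perf_path)

        def f_of(model, roi):
            sel = perf[(perf.model_class == model) & (perf.roi_label == roi)]
            return float(sel["f_mean"].iloc[0]) if len(sel) else np.nan

        rep["perfusion"] = {
            m: dict(
                labyrinth=f_of(m, "labyrinth"),
                decidua=f_of(m, "decidua"),
                liver_over_placenta=f_of(m, "fetal_liver") / f_of(m, "placenta"),
            )
            for m in perf.model_class.unique()
        }
    (outdir / "report.json").write_text(json.dumps(rep, indent=1, sort_keys=True))
    lines = [f"run {rep['config_hash']} (seed {config.seed})"]
    for k, v in rep["checks"].items():
        lines.append(f"  {'PASS' if v else 'FAIL'}  {k}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return rep
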