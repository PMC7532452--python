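"""Digital fetoplacental phantoms and cohort sampling.

A phantom is a stylized 2D coronal slice through one mouse fetoplacental
unit: a three-layered placental disc (decidua outermost, trophoblast in the
middle, labyrinth innermost), an adjacent amniotic sac containing a fetal
brain and a fetal liver, all embedded in maternal background tissue.  The
geometry is deliberately schematic — every downstream statistic depends only
on the labeled regions and their ground-truth parameter maps, not on
anatomical realism.

Cohorts mirror the emulated study design: several dams per pregnancy model,
several fetoplacental units per dam, scanned longitudinally over gestational
days E14.5–E19.5 with per-dam unit counts that never increase with age (late
in pregnancy fewer units fit the imaging field of view).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .presets import (
    COMPARTMENT_LABELS,
    GESTATIONAL_DAY_RANGE,
    MODEL_CLASSES,
    PLACENTAL_LAYERS,
    TissueCompartment,
    model_compartments,
)

TRUTH_MAP_NAMES = ("adc", "t1", "t2", "proton_density", "perfusion_f", "kep", "vb")

#: Within-compartment coefficient of variation for non-ADC parameters.
_RELAX_JITTER_CV = 0.05
_PERFUSION_JITTER_CV = 0.10

MIN_GRID = 64


@dataclass
class FetoplacentalPhantom:
    """Labeled tissue grid plus per-voxel ground-truth parameter maps.

    Row index is the SPEN/phase axis, column index the readout axis
    (0-based, row-major).  ``truth_maps`` holds one float grid per entry of
    :data:`TRUTH_MAP_NAMES`, consistent with ``compartments`` up to the
    configured per-voxel jitter.
    """

    label_map: np.ndarray
    pixel_size: float
    compartments: dict[int, TissueCompartment]
    gestational_day: float
    model_class: str
    truth_maps: dict[str, np.ndarray]
    seed: int
    dam_id: int | None = None
    unit_id: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def roi(self, label: str) -> np.ndarray:
        return ground_truth_roi(self, label)


def _disc(rows: np.ndarray, cols: np.ndarray, cr: float, cc: float, radius: float):
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2


def _ellipse(rows, cols, cr, cc, sr, sc):
    return ((rows - cr) / sr) ** 2 + ((cols - cc) / sc) ** 2 <= 1.0


def _build_label_map(grid_shape: tuple[int, int], gestational_day: float) -> np.ndarray:
    nr, nc = grid_shape
    g = min(nr, nc)
    dday = gestational_day - GESTATIONAL_DAY_RANGE[0]
    rows, cols = np.mgrid[0:nr, 0:nc].astype(float)

    lm = np.full(grid_shape, COMPARTMENT_LABELS["maternal_background"], dtype=np.int16)

    # Amniotic sac: ellipse, grows slightly with gestational age.
    grow = 1.0 + 0.03 * dday
    sac = _ellipse(rows, cols, 0.62 * nr, 0.50 * nc, 0.26 * g * grow, 0.22 * g * grow)
    lm[sac] = COMPARTMENT_LABELS["amniotic_fluid"]

    # Placental disc with three concentric layers; decidua is the outermost
    # (maternal-facing) ring, the labyrinth the innermost (fetal-facing) core.
    rp = 0.17 * g * (1.0 + 0.012 * dday)
    pr, pc = 0.22 * nr, 0.50 * nc
    r2 = (rows - pr) ** 2 + (cols - pc) ** 2
    lm[r2 <= rp**2] = COMPARTMENT_LABELS["decidua"]
    lm[r2 <= (0.78 * rp) ** 2] = COMPARTMENT_LABELS["trophoblast"]
    lm[r2 <= (0.50 * rp) ** 2] = COMPARTMENT_LABELS["labyrinth"]

    # Fetal organs inside the sac (fetal body itself is not modeled).
    brain = _disc(rows, cols, 0.53 * nr, 0.50 * nc, 0.07 * g * (1.0 + 0.05 * dday))
    liver = _disc(rows, cols, 0.71 * nr, 0.42 * nc, 0.065 * g * (1.0 + 0.04 * dday))
    placenta = lm >= COMPARTMENT_LABELS["decidua"]
    if np.any(brain & placenta) or np.any(liver & placenta) or np.any(brain & liver):
        raise ValueError("grid too small to host all compartments without overlap")
    lm[brain] = COMPARTMENT_LABELS["fetal_brain"]
    lm[liver] = COMPARTMENT_LABELS["fetal_liver"]
    return lm


def build_phantom(
    model_class: str,
    gestational_day: float,
    grid_shape: tuple[int, int] = (160, 160),
    pixel_size: float = 0.1875,
    seed: int | np.random.SeedSequence = 0,
    jitter: bool = True,
    unit_effects: dict[str, float] | None = None,
    dam_id: int | None = None,
    unit_id: int | None = None,
) -> FetoplacentalPhantom:
    """Generate one fetoplacental phantom.

    Parameters
    ----------
    model_class:
        One of ``wildtype``, ``enos_ko``, ``il10_ko``, ``lname``.
    gestational_day:
        Embryonic day in [14.5, 19.5].
    grid_shape, pixel_size:
        Grid dimensions (min 64x64) and isotropic pixel size in mm.
    seed:
        Integer or :class:`numpy.random.SeedSequence`; generation is a pure
        function of (arguments, seed).
    jitter:
        Apply within-compartment Gaussian heterogeneity (the configured
        coefficient of variation per compartment) to the truth maps.
    unit_effects:
        Optional per-compartment multiplicative biological effects (drawn by
        the cohort sampler so a given unit keeps its identity across days);
        drawn internally when absent.
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(
            f"unknown model_class {model_class!r}; expected one of {MODEL_CLASSES}"
        )
    lo, hi = GESTATIONAL_DAY_RANGE
    if not lo <= gestational_day <= hi:
        raise ValueError(f"gestational_day must lie in [{lo}, {hi}]")
    if min(grid_shape) < MIN_GRID:
        raise ValueError(f"grid too small: need at least {MIN_GRID}x{MIN_GRID}")

    if isinstance(seed, np.random.SeedSequence):
        ss = seed
        seed_int = int(ss.entropy if np.isscalar(ss.entropy) else ss.entropy[0])
    else:
        ss = np.random.SeedSequence(int(seed))
        seed_int = int(seed)
    rng = np.random.default_rng(ss)

    label_map = _build_label_map(grid_shape, gestational_day)
    compartments = model_compartments(model_class, gestational_day)

    if unit_effects is None:
        unit_effects = {
            name: 1.0 + compartments[lab].unit_cv * rng.standard_normal()
            for name, lab in COMPARTMENT_LABELS.items()
        }

    truth = {name: np.zeros(grid_shape) for name in TRUTH_MAP_NAMES}
    for name, lab in COMPARTMENT_LABELS.items():
        comp = compartments[lab]
        mask = label_map == lab
        n = int(mask.sum())
        eff = unit_effects.get(name, 1.0)
        base = {
            "adc": comp.adc * eff,
            "t1": comp.t1,
            "t2": comp.t2,
            "proton_density": comp.proton_density,
            "perfusion_f": comp.perfusion_f * eff,
            "kep": comp.kep,
            "vb": comp.vb,
        }
        cv = {
            "adc": comp.adc_cv,
            "t1": _RELAX_JITTER_CV,
            "t2": _RELAX_JITTER_CV,
            "proton_density": _RELAX_JITTER_CV,
            "perfusion_f": _PERFUSION_JITTER_CV,
            "kep": 0.0,
            "vb": 0.0,
        }
        for key in TRUTH_MAP_NAMES:
            vals = np.full(n, base[key])
            if jitter and cv[key] > 0 and base[key] != 0:
                vals = vals * (1.0 + cv[key] * rng.standard_normal(n))
            truth[key][mask] = vals
    np.clip(truth["adc"], 1e-6, None, out=truth["adc"])
    np.clip(truth["proton_density"], 0.0, 1.0, out=truth["proton_density"])
    np.clip(truth["perfusion_f"], 0.0, None, out=truth["perfusion_f"])

    return FetoplacentalPhantom(
        label_map=label_map,
        pixel_size=pixel_size,
        compartments=compartments,
        gestational_day=gestational_day,
        model_class=model_class,
        truth_maps=truth,
        seed=seed_int,
        dam_id=dam_id,
        unit_id=unit_id,
    )


def ground_truth_roi(phantom: FetoplacentalPhantom, label: str) -> np.ndarray:
    """Binary mask of one compartment (or the composite ``placenta``).

    Ground-truth masks stand in for the manual region drawing of an in-vivo
    analysis.
    """
    if label == "placenta":
        return np.isin(
            phantom.label_map, [COMPARTMENT_LABELS[n] for n in PLACENTAL_LAYERS]
        )
    if label not in COMPARTMENT_LABELS:
        raise ValueError(f"unknown label {label!r}")
    mask = phantom.label_map == COMPARTMENT_LABELS[label]
    if not mask.any():
        raise ValueError(f"label {label!r} absent from phantom")
    return mask


@dataclass(frozen=True)
class CohortSpec:
    """Design of one model's cohort: dams, units per dam, scan days."""

    model_class: str
    n_dams: int
    units_per_dam: tuple[int, int]
    gestational_days: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dams < 1:
            raise ValueError("n_dams must be >= 1")
        lo, hi = self.units_per_dam
        if not (1 <= lo <= hi):
            raise ValueError("units_per_dam range is empty or invalid")
        if len(self.gestational_days) == 0:
            raise ValueError("gestational_days must not be empty")


def _model_key(model_class: str) -> int:
    """Stable integer tag so different models draw independent substreams."""
    return zlib.crc32(model_class.encode()) % 2**31


#: Cohort designs mirroring the emulated study (dams and fetoplacental-unit
#: ranges per model; the l-NAME arm is scanned on two days only).
_DEFAULT_DESIGNS = {
    "wildtype": dict(n_dams=5, units_per_dam=(4, 7)),
    "enos_ko": dict(n_dams=5, units_per_dam=(5, 8)),
    "il10_ko": dict(n_dams=4, units_per_dam=(4, 8)),
    "lname": dict(n_dams=3, units_per_dam=(3, 4)),
}
_FULL_DAYS = (14.5, 15.5, 16.5, 17.5, 18.5, 19.5)
_LNAME_DAYS = (14.5, 16.5)


def default_cohort_spec(model_class: str, seed: int = 0) -> CohortSpec:
    if model_class not in _DEFAULT_DESIGNS:
        raise ValueError(f"unknown model_class {model_class!r}")
    days = _LNAME_DAYS if model_class == "lname" else _FULL_DAYS
    return CohortSpec(
        model_class=model_class,
        gestational_days=days,
        seed=seed,
        **_DEFAULT_DESIGNS[model_class],
    )


def plan_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-dam unit counts for every scan day.

    Counts start near the top of the configured range and are monotonically
    non-increasing with gestational day (units drop out of the field of view
    as pregnancy advances), never leaving ``units_per_dam``.
    """
    lo, hi = spec.units_per_dam
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _model_key(spec.model_class), 0xC0])
    )
    rows = []
    for dam in range(spec.n_dams):
        n = int(rng.integers(max(lo, hi - 1), hi + 1))
        for day in sorted(spec.gestational_days):
            rows.append(dict(dam=dam, day=day, n_units=n))
            if n > lo:
                n -= int(rng.random() < 0.45)
    return pd.DataFrame(rows)


def sample_cohort(
    spec: CohortSpec,
    grid_shape: tuple[int, int] = (160, 160),
    pixel_size: float = 0.1875,
) -> list[FetoplacentalPhantom]:
    """Generate one phantom per fetoplacental unit per dam per scan day.

    A unit keeps its biological identity (its per-compartment effect sizes)
    across days; unit ``u`` of a dam is present on a given day iff ``u`` is
    below that day's unit count, so later-day units are subsets of earlier
    ones.  All randomness derives from ``spec.seed`` via per-(dam, unit, day)
    substreams.
    """
    plan = plan_cohort(spec)
    day_index = {d: i for i, d in enumerate(sorted(set(spec.gestational_days)))}
    phantoms: list[FetoplacentalPhantom] = []
    for dam, sub in plan.groupby("dam"):
        max_units = int(sub["n_units"].max())
        effects = {}
        for unit in range(max_units):
            rng_u = np.random.default_rng(
                np.random.SeedSequence(
                    [spec.seed, _model_key(spec.model_class), int(dam), unit, 0xB10]
                )
            )
            comps = model_compartments(spec.model_class, spec.gestational_days[0])
            effects[unit] = {
                name: 1.0 + comps[lab].unit_cv * rng_u.standard_normal()
                for name, lab in COMPARTMENT_LABELS.items()
            }
        for _, row in sub.iterrows():
            day = float(row["day"])
            for unit in range(int(row["n_units"])):
                ss = np.random.SeedSequence(
                    [
                        spec.seed,
                        _model_key(spec.model_class),
                        int(dam),
                        unit,
                        day_index[day],
                    ]
                )
                phantoms.append(
                    build_phantom(
                        spec.model_class,
                        day,
                        grid_shape=grid_shape,
                        pixel_size=pixel_size,
                        seed=ss,
                        unit_effects=effects[unit],
                        dam_id=int(dam),
                        unit_id=unit,
                    )
                )
    return phantoms
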