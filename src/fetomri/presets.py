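"""Tissue-parameter presets for the four emulated pregnancy models.

The presets encode the *directional* structure of the emulated study —
amniotic fluid diffuses fastest, the trophoblast layer slowest among the
placental layers, knockout placentas sit below wildtype, the l-NAME model has
the broadest placental spread, and fetal-brain diffusivity falls (and its
spread narrows, fastest for wildtype) with gestational age.  Absolute
magnitudes are declared, editable assumptions shipped in ``data/presets.csv``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

MODEL_CLASSES = ("wildtype", "enos_ko", "il10_ko", "lname")

#: Compartment name -> integer label used in phantom label maps.
COMPARTMENT_LABELS = {
    "maternal_background": 0,
    "amniotic_fluid": 1,
    "decidua": 2,
    "trophoblast": 3,
    "labyrinth": 4,
    "fetal_brain": 5,
    "fetal_liver": 6,
}

LABEL_NAMES = {v: k for k, v in COMPARTMENT_LABELS.items()}

PLACENTAL_LAYERS = ("decidua", "trophoblast", "labyrinth")

GESTATIONAL_DAY_RANGE = (14.5, 19.5)


@dataclass(frozen=True)
class TissueCompartment:
    """Ground-truth MR and transport parameters of one tissue class.

    ``adc`` in mm^2/s, ``t1``/``t2`` in ms, ``perfusion_f`` and ``kep`` in
    s^-1, ``vb`` the blood-volume fraction seen by a non-extravasating agent.
    """

    label: str
    adc: float
    t1: float
    t2: float
    proton_density: float
    perfusion_f: float
    extravasation: bool
    kep: float = 0.0
    vb: float = 0.0
    adc_cv: float = 0.10
    unit_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in COMPARTMENT_LABELS:
            raise ValueError(f"unknown compartment label {self.label!r}")
        if not self.adc > 0:
            raise ValueError("adc must be positive")
        if not (self.t1 > self.t2 > 0):
            raise ValueError("relaxation times must satisfy t1 > t2 > 0")
        if not 0.0 <= self.proton_density <= 1.0:
            raise ValueError("proton_density must lie in [0, 1]")
        if self.perfusion_f < 0:
            raise ValueError("perfusion_f must be non-negative")


@lru_cache(maxsize=1)
def load_preset_table() -> pd.DataFrame:
    """Load the shipped preset table (one row per model x compartment)."""
    text = resources.files("fetomri").joinpath("data/presets.csv").read_text()
    df = pd.read_csv(io.StringIO(text), comment="#")
    df["extravasation"] = df["extravasation"].astype(bool)
    return df.set_index(["model", "compartment"], drop=False)


def compartment_preset(
    model_class: str, compartment: str, gestational_day: float
) -> TissueCompartment:
    """Day-resolved tissue parameters for one compartment of one model.

    Gestational-day dependence is linear in (day - E14.5) for both the mean
    ADC and its within-compartment coefficient of variation.
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(
            f"unknown model_class {model_class!r}; expected one of {MODEL_CLASSES}"
        )
    row = load_preset_table().loc[(model_class, compartment)]
    dday = gestational_day - GESTATIONAL_DAY_RANGE[0]
    adc = float(row["adc"] + row["adc_slope"] * dday)
    cv = float(max(row["adc_cv"] + row["adc_cv_slope"] * dday, 0.02))
    return TissueCompartment(
        label=compartment,
        adc=adc,
        t1=float(row["t1"]),
        t2=float(row["t2"]),
        proton_density=float(row["proton_density"]),
        perfusion_f=float(row["perfusion_f"]),
        extravasation=bool(row["extravasation"]),
        kep=float(row["kep"]),
        vb=float(row["vb"]),
        adc_cv=cv,
        unit_cv=float(row["unit_cv"]),
    )


def model_compartments(
    model_class: str, gestational_day: float
) -> dict[int, TissueCompartment]:
    """All compartments of one model at one gestational day, keyed by label id."""
    return {
        lab: compartment_preset(model_class, name, gestational_day)
        for name, lab in COMPARTMENT_LABELS.items()
    }
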