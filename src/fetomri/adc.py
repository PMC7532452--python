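"""Isotropic ADC mapping and per-compartment histogram statistics.

The diffusion signal is modeled as mono-exponential per direction,
S_d = S_0 * exp(-(b_d - b_0) * ADC_d), with the voxel's *effective* b-values
(the b≈0 acquisition itself carries a small, position-dependent weighting
from the encoding gradients).  The isotropic ADC is the arithmetic mean of
the three orthogonal directional maps (trace/3).  Region statistics follow
the emulated study's procedure: histogram the ADC values of each region of
interest, fit a Gaussian A*exp(-(x-μ)²/2σ²) to the histogram, then aggregate
the per-unit (μ, σ) across each cohort by gestational day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spen import DwiSeries


@dataclass
class AdcMap:
    """Voxelwise diffusivity fit: isotropic ADC, per-direction maps, the
    fitted b≈0 signal and a validity mask (b≈0 signal above the noise floor).

    Negative fitted ADCs (pure noise voxels) are kept — clamping them would
    bias region means upward; they are simply excluded from display."""

    adc: np.ndarray
    s0: np.ndarray
    directional_adc: np.ndarray  # (3, rows, cols)
    valid_mask: np.ndarray

    def display_adc(self) -> np.ndarray:
        out = np.where(self.valid_mask & (self.adc >= 0), self.adc, np.nan)
        return out


@dataclass
class RoiHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    roi_label: str = ""
    unit_id: int | None = None
    dam_id: int | None = None
    gestational_day: float | None = None
    n_voxels: int = 0
    binning: str = "freedman-diaconis(min 8)"

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if int(self.counts.sum()) != self.n_voxels:
            raise ValueError("counts must sum to n_voxels")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float
    goodness: float
    degenerate: bool = False


@dataclass
class UnitFit:
    """One region's Gaussian fit tagged with its cohort metadata."""

    fit: GaussianFit
    model_class: str
    dam_id: int
    unit_id: int
    gestational_day: float
    roi_label: str = ""


def estimate_background_sigma(image: np.ndarray, frac: float = 0.06) -> float:
    """Noise σ from the corner patches of a magnitude image (Rayleigh mean)."""
    n = max(2, int(round(min(image.shape) * frac)))
    corners = np.concatenate(
        [
            image[:n, :n].ravel(),
            image[:n, -n:].ravel(),
            image[-n:, :n].ravel(),
            image[-n:, -n:].ravel(),
        ]
    )
    return float(np.mean(corners) / np.sqrt(np.pi / 2.0))


def fit_adc(series: DwiSeries, noise_sigma: float | None = None) -> AdcMap:
    """Voxelwise log-ratio ADC fit from a b≈0 plus three directional DWIs.

    Uses each image's effective b-map so the encoding-gradient contribution
    to the b≈0 acquisition cancels exactly.  Voxels whose b≈0 signal falls
    below 3x the background noise estimate are flagged invalid.
    """
    i0 = [i for i, d in enumerate(series.modules) if d is None]
    if not i0:
        raise ValueError("series lacks a b≈0 acquisition")
    idir = [i for i, d in enumerate(series.modules) if d is not None]
    if len(idir) < 1:
        raise ValueError("series lacks diffusion-weighted acquisitions")
    s0 = series.images[i0[0]]
    b0 = series.bmaps[i0[0]]

    if noise_sigma is None:
        # prefer the series' recorded noise level; fall back to a corner
        # (air) estimate, the convention for user-supplied data
        noise_sigma = (
            series.noise_sigma
            if series.noise_sigma is not None
            else estimate_background_sigma(s0)
        )
    valid = s0 > 3.0 * noise_sigma

    eps = np.finfo(float).tiny
    dmaps = []
    for i in idir:
        sb = series.images[i]
        db = series.bmaps[i] - b0
        if np.any(db <= 0):
            raise ValueError("need at least two distinct effective b per voxel")
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.log(np.maximum(s0, eps) / np.maximum(sb, eps)) / db
        dmaps.append(d)
    directional = np.stack(dmaps)
    adc = directional.mean(axis=0)
    return AdcMap(adc=adc, s0=s0, directional_adc=directional, valid_mask=valid)


def roi_histogram(
    adc_map: AdcMap | np.ndarray,
    mask: np.ndarray,
    bin_edges: np.ndarray | None = None,
    min_bins: int = 8,
    **meta,
) -> RoiHistogram:
    """Histogram of ADC values over the valid voxels of a region.

    Default binning is Freedman–Diaconis with a floor of ``min_bins`` bins;
    pass explicit ``bin_edges`` to align histograms across regions.
    """
    if isinstance(adc_map, AdcMap):
        values = adc_map.adc[mask & adc_map.valid_mask]
    else:
        values = np.asarray(adc_map)[mask]
    if values.size == 0:
        raise ValueError("mask has no valid voxels")
    if bin_edges is None:
        if np.ptp(values) == 0:
            v = float(values[0])
            half = max(abs(v) * 0.05, 1e-12)
            bin_edges = np.linspace(v - half, v + half, min_bins + 1)
        else:
            bin_edges = np.histogram_bin_edges(values, bins="fd")
            if bin_edges.size - 1 < min_bins:
                bin_edges = np.histogram_bin_edges(values, bins=min_bins)
    counts, bin_edges = np.histogram(values, bins=bin_edges)
    return RoiHistogram(
        bin_edges=bin_edges,
        counts=counts,
        n_voxels=int(counts.sum()),
        **meta,
    )


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(hist: RoiHistogram) -> GaussianFit:
    """Least-squares Gaussian fit to histogram bin centers and counts.

    Requires at least 5 occupied bins.  A fit whose σ collapses below half
    the bin width is returned flagged ``degenerate`` rather than silently.
    """
    occupied = int(np.count_nonzero(hist.counts))
    if occupied < 5:
        raise ValueError(f"need >=5 occupied bins, got {occupied}")
    x = hist.centers
    raw = hist.counts.astype(float)
    scale = raw.max()
    c = raw / scale  # amplitude-normalized so the fit is scale-invariant
    w = c.sum()
    mu0 = float((x * c).sum() / w)
    var0 = float(((x - mu0) ** 2 * c).sum() / w)
    sigma0 = max(np.sqrt(var0), np.diff(hist.bin_edges).mean())
    a0 = float(c.max())
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            x,
            c,
            p0=(a0, mu0, sigma0),
            maxfev=10000,
        )
        a, mu, sigma = popt
        sigma = abs(float(sigma))
    except RuntimeError:
        a, mu, sigma = a0, mu0, sigma0
    resid = c - _gauss(x, a, mu, sigma)
    sst = float(((c - c.mean()) ** 2).sum())
    goodness = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    bw = float(np.diff(hist.bin_edges).mean())
    degenerate = sigma < bw / 2.0 or not (x.min() <= mu <= x.max())
    return GaussianFit(
        mu=float(mu),
        sigma=sigma,
        amplitude=float(a) * scale,
        goodness=goodness,
        degenerate=degenerate,
    )


def voxel_moments(adc_map: AdcMap | np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Raw-voxel mean and SD over a region (the moment-based counterpart of
    the histogram Gaussian fit)."""
    if isinstance(adc_map, AdcMap):
        values = adc_map.adc[mask & adc_map.valid_mask]
    else:
        values = np.asarray(adc_map)[mask]
    return float(values.mean()), float(values.std(ddof=1))


def fits_to_frame(fits: list[UnitFit]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            model_class=f.model_class,
            gestational_day=f.gestational_day,
            dam_id=f.dam_id,
            unit_id=f.unit_id,
            roi_label=f.roi_label,
            mu=f.fit.mu,
            sigma=f.fit.sigma,
            goodness=f.fit.goodness,
        )
        for f in fits
    )


def longitudinal_summary(fits: list[UnitFit]) -> pd.DataFrame:
    """Cohort table: per (model, day[, roi]) cross-unit mean and spread (SD)
    of the per-unit Gaussian μ and σ, with unit and dam counts."""
    df = fits_to_frame(fits)
    keys = ["model_class", "roi_label", "gestational_day"]
    rows = []
    for key, g in df.groupby(keys, sort=True):
        rows.append(
            dict(
                zip(keys, key),
                mu_mean=g["mu"].mean(),
                mu_spread=g["mu"].std(ddof=1) if len(g) > 1 else 0.0,
                sigma_mean=g["sigma"].mean(),
                sigma_spread=g["sigma"].std(ddof=1) if len(g) > 1 else 0.0,
                n_units=len(g),
                n_dams=g["dam_id"].nunique(),
            )
        )
    return pd.DataFrame(rows)


def per_animal_breakdown(fits: list[UnitFit]) -> pd.DataFrame:
    """The longitudinal summary grouped per dam — the animal-by-animal view
    used to inspect inter-litter variation."""
    df = fits_to_frame(fits)
    keys = ["model_class", "roi_label", "dam_id", "gestational_day"]
    rows = []
    for key, g in df.groupby(keys, sort=True):
        rows.append(
            dict(
                zip(keys, key),
                mu_mean=g["mu"].mean(),
                mu_spread=g["mu"].std(ddof=1) if len(g) > 1 else 0.0,
                sigma_mean=g["sigma"].mean(),
                sigma_spread=g["sigma"].std(ddof=1) if len(g) > 1 else 0.0,
                n_units=len(g),
            )
        )
    return pd.DataFrame(rows)


def variance_components(fits: list[UnitFit]) -> dict[str, float]:
    """One-way decomposition of per-unit μ variance into between-dam and
    within-dam components (method of moments)."""
    df = fits_to_frame(fits)
    grand = df["mu"].mean()
    between = 0.0
    within = 0.0
    n = len(df)
    for _, g in df.groupby("dam_id"):
        between += len(g) * (g["mu"].mean() - grand) ** 2
        within += ((g["mu"] - g["mu"].mean()) ** 2).sum()
    k = df["dam_id"].nunique()
    return dict(
        between_dam=between / max(k - 1, 1),
        within_dam=within / max(n - k, 1),
    )


def compare_models(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: str = "mu",
    day: float | None = None,
    roi_label: str | None = None,
) -> dict:
    """Unit-level two-sample comparison between two cohort tables.

    Welch's (unequal-variance) two-sided t-test on the per-unit Gaussian
    means (or σs), run from the cohorts' summary statistics.
    """
    if metric not in ("mu", "sigma"):
        raise ValueError("metric must be 'mu' or 'sigma'")

    def _row(tbl):
        sel = tbl
        if day is not None:
            sel = sel[np.isclose(sel["gestational_day"], day)]
        if roi_label is not None:
            sel = sel[sel["roi_label"] == roi_label]
        if len(sel) != 1:
            raise ValueError(
                f"expected exactly one matching row, got {len(sel)}"
            )
        return sel.iloc[0]

    ra, rb = _row(table_a), _row(table_b)
    na, nb = int(ra["n_units"]), int(rb["n_units"])
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 units per group")
    ma, mb = ra[f"{metric}_mean"], rb[f"{metric}_mean"]
    sa, sb = ra[f"{metric}_spread"], rb[f"{metric}_spread"]
    tt = stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=False)
    diff = float(ma - mb)
    return dict(
        difference=diff,
        direction="a>b" if diff > 0 else ("a<b" if diff < 0 else "a=b"),
        p_value=float(tt.pvalue),
        t_statistic=float(tt.statistic),
        n_a=na,
        n_b=nb,
    )
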