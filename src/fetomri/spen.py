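"""Forward simulation of multi-shot SPEN (and comparator EPI) diffusion MRI.

SPEN (spatiotemporal encoding) replaces Fourier phase encoding along one
axis by a frequency-swept (chirp) adiabatic inversion applied in an encoding
gradient, which stamps a quadratic phase profile onto the object.  An
oscillating readout samples k-space along the orthogonal axis while blipped
gradients rasterize the SPEN axis; a fine per-shot ``K_shot`` offset
interleaves several shots into one fully sampled acquisition.
Reconstruction inverts the known quadratic-phase encoding operator by a
regularized pseudo-inverse instead of an FFT, which is what confers SPEN its
robustness to off-resonance: each SPEN position is acquired at its own spin
echo, so static field offsets do not translate into the large bulk shifts
seen in EPI.

Diffusion weighting enters through effective b-maps obtained by integrating
the squared running gradient moment q(t, y) over the whole sequence, with
sign inversions at every refocusing event — including the chirp's
position-dependent inversion time, which is why b varies along the SPEN axis
and never reaches zero even without diffusion lobes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .phantom import FetoplacentalPhantom
from .units import GAMMA_RAD_PER_S_PER_G, MM_TO_CM, MS_TO_S, RAD2_PER_CM2_S_TO_S_PER_MM2

_GAMMA = GAMMA_RAD_PER_S_PER_G

# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DiffusionModule:
    """Bipolar diffusion-sensitizing gradient pair: δ, Δ in ms, amplitude in G/cm."""

    delta: float
    Delta: float
    g_amp: float
    orientation: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.delta <= self.Delta:
            raise ValueError("need 0 < delta <= Delta")
        if self.g_amp < 0:
            raise ValueError("g_amp must be non-negative")
        norm = math.sqrt(sum(c * c for c in self.orientation))
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ValueError("orientation must be a unit vector")


@dataclass(frozen=True)
class SpenSequenceParams:
    """Multi-shot SPEN acquisition description (times in ms, FOV in mm).

    ``r_factor`` is the chirp time-bandwidth product; the encoding gradient
    amplitude and per-line blip area are derived from (tp, r_factor, fov).
    """

    fov: float = 30.0
    matrix: int = 160
    tp: float = 20.0
    r_factor: float = 450.0
    n_interleaves: int = 5
    tr: float = 2000.0
    te: float = 37.0
    slice_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.fov <= 0 or self.tp <= 0:
            raise ValueError("fov and tp must be positive")
        if self.matrix % self.n_interleaves != 0:
            raise ValueError("matrix must be divisible by n_interleaves")

    @property
    def fov_cm(self) -> float:
        return self.fov * MM_TO_CM

    @property
    def g_enc(self) -> float:
        """Effective encoding gradient amplitude, G/cm (post-inversion moment
        convention: the residual SPEN-axis moment after the chirp is
        q(y) = -2 pi R y / L^2)."""
        return math.pi * self.r_factor / (_GAMMA * self.fov_cm * self.tp * MS_TO_S)

    @property
    def dk_fine(self) -> float:
        """Interleave (K_shot) k-increment along the SPEN axis, rad/cm.

        The assembled multi-shot raster samples the SPEN axis at Nyquist;
        each shot's blips advance by ``n_interleaves`` fine steps and the
        K_shot gradient supplies the per-shot fine offset."""
        return 2.0 * math.pi / self.fov_cm

    @property
    def g_acq_blip(self) -> float:
        """Per-line acquisition blip area, G*ms/cm."""
        return self.dk_fine * self.n_interleaves / _GAMMA / MS_TO_S

    @property
    def acq_duration_s(self) -> float:
        # full-refocusing design: the raster revisits each position at twice
        # its chirp inversion delay, so the acquisition lasts 2*tp
        return 2.0 * self.tp * MS_TO_S

    @property
    def esp_s(self) -> float:
        """Line spacing within a shot, s."""
        return self.acq_duration_s * self.n_interleaves / self.matrix

    @property
    def spen_positions_cm(self) -> np.ndarray:
        n = self.matrix
        return (np.arange(n) - n // 2) * (self.fov_cm / n)


@dataclass(frozen=True)
class EpiSequenceParams:
    """Interleaved EPI comparator (esp = echo spacing per phase line, ms)."""

    fov: float = 30.0
    matrix: int = 160
    esp: float = 0.5
    n_interleaves: int = 4
    tr: float = 2000.0
    te: float = 30.0

    def __post_init__(self) -> None:
        if self.matrix % self.n_interleaves != 0:
            raise ValueError("matrix must be divisible by n_interleaves")

    @property
    def fov_cm(self) -> float:
        return self.fov * MM_TO_CM


@dataclass
class GradientWaveform:
    """Uniformly sampled three-axis gradient waveform, G/cm."""

    dt: float
    g: np.ndarray  # (3, n_samples)

    def __post_init__(self) -> None:
        self.g = np.atleast_2d(np.asarray(self.g, dtype=float))
        if self.g.shape[0] != 3:
            raise ValueError("waveform must have three gradient axes")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("waveform amplitudes must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.g.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class ShotData:
    """Complex samples of one interleave: (readout samples x SPEN lines)."""

    samples: np.ndarray
    shot_index: int
    k_shot_offset: float
    line_k: np.ndarray
    line_times: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("shot samples must be finite")


@dataclass
class BMap:
    """Diffusion weighting in s/mm^2: scalar or per-position profile."""

    b: np.ndarray | float
    direction: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.b) < -1e-9):
            raise ValueError("b-values must be non-negative")


@dataclass
class DwiSeries:
    """Reconstructed diffusion-weighted image set with matching b-maps."""

    images: np.ndarray          # (n_acq, rows, cols), magnitude
    bmaps: np.ndarray           # (n_acq, rows, cols), s/mm^2
    modules: tuple              # DiffusionModule | None per acquisition
    nominal_b: tuple[float, ...]
    snr: float | None = None
    noise_sigma: float | None = None


# ---------------------------------------------------------------------------
# b-value physics


def bvalue_stejskal_tanner(dm: DiffusionModule) -> float:
    """Closed-form pulsed-gradient spin-echo b-value, s/mm^2."""
    delta = dm.delta * MS_TO_S
    Delta = dm.Delta * MS_TO_S
    q = _GAMMA * dm.g_amp * delta  # rad/cm
    return q * q * (Delta - delta / 3.0) * RAD2_PER_CM2_S_TO_S_PER_MM2


def pgse_waveform(
    dm: DiffusionModule, dt: float = 1e-6, lead: float = 1e-3
) -> tuple[GradientWaveform, list[float]]:
    """Rectangular PGSE pair with a hard refocusing pulse midway between lobes."""
    delta = dm.delta * MS_TO_S
    Delta = dm.Delta * MS_TO_S
    total = 2 * lead + Delta + delta
    t = np.arange(0.0, total, dt)
    env = np.zeros_like(t)
    env[(t >= lead) & (t < lead + delta)] = dm.g_amp
    env[(t >= lead + Delta) & (t < lead + Delta + delta)] = dm.g_amp
    g = np.outer(np.asarray(dm.orientation), env)
    t180 = lead + (Delta + delta) / 2.0
    return GradientWaveform(dt=dt, g=g), [t180]


def effective_bmap(
    waveform: GradientWaveform,
    refocusing_times,
    positions: np.ndarray | None = None,
    direction: tuple[float, float, float] | None = None,
) -> BMap:
    """Integrate b = ∫ q(t, y)^2 dt over the full waveform.

    ``refocusing_times`` is a sequence whose entries are either scalars (hard
    refocusing pulses, experienced simultaneously everywhere) or arrays of
    per-position inversion times (the chirp, which flips each SPEN position
    ``y`` at its own moment).  The running moment q accumulates the effective
    gradient g(t) * (-1)^(number of refocusings before t); any array entry
    makes the output a per-position profile (requiring ``positions`` only for
    bookkeeping of its length).
    """
    t = waveform.time
    dt = waveform.dt
    scalar_flips = [f for f in refocusing_times if np.isscalar(f)]
    array_flips = [np.asarray(f, dtype=float) for f in refocusing_times if not np.isscalar(f)]

    sign_t = np.ones_like(t)
    for f in scalar_flips:
        sign_t *= np.where(t >= f, -1.0, 1.0)

    if not array_flips:
        b = 0.0
        for ax in range(3):
            if not np.any(waveform.g[ax]):
                continue
            q = _GAMMA * np.cumsum(waveform.g[ax] * sign_t) * dt
            b += np.trapezoid(q * q, dx=dt)
        return BMap(b=float(b * RAD2_PER_CM2_S_TO_S_PER_MM2), direction=direction)

    n_pos = array_flips[0].shape[0]
    if len(array_flips) == 1:
        # Single position-dependent inversion at τ(y): with Q(t) the moment
        # accumulated under the scalar-flip sign history alone,
        # q(t, y) = Q(t) for t < τ and 2 Q(τ) - Q(t) afterwards, so
        # ∫ q² dt = ∫ Q² dt + 4 Q(τ)² (T - τ) - 4 Q(τ) ∫_τ^T Q dt —
        # all obtainable from 1D cumulative integrals.
        tau = array_flips[0]
        idx = np.clip(np.searchsorted(t, tau), 0, t.size - 1)
        b = np.zeros(n_pos)
        for ax in range(3):
            if not np.any(waveform.g[ax]):
                continue
            q = _GAMMA * np.cumsum(waveform.g[ax] * sign_t) * dt
            int_q = np.concatenate([[0.0], np.cumsum(q) * dt])
            int_q2 = np.concatenate([[0.0], np.cumsum(q * q) * dt])
            q_tau = q[idx]
            total = t[-1] + dt
            b += (
                int_q2[-1]
                + 4.0 * q_tau**2 * (total - t[idx])
                - 4.0 * q_tau * (int_q[-1] - int_q[idx])
            )
        return BMap(b=b * RAD2_PER_CM2_S_TO_S_PER_MM2, direction=direction)

    sign = np.broadcast_to(sign_t, (n_pos, t.size)).copy()
    for f in array_flips:
        sign *= np.where(t[None, :] >= f[:, None], -1.0, 1.0)
    b = np.zeros(n_pos)
    for ax in range(3):
        if not np.any(waveform.g[ax]):
            continue
        q = _GAMMA * np.cumsum(waveform.g[ax][None, :] * sign, axis=1) * dt
        b += np.trapezoid(q * q, dx=dt, axis=1)
    return BMap(b=b * RAD2_PER_CM2_S_TO_S_PER_MM2, direction=direction)


def spen_sequence_waveform(
    params: SpenSequenceParams,
    dm: DiffusionModule | None = None,
    dt: float = 1e-6,
) -> tuple[GradientWaveform, list]:
    """Assemble the full SPEN sequence gradient timeline for b-map integration.

    Timeline: (optional) diffusion block with a hard 180 between its lobes,
    then the chirp period with the encoding gradient on the SPEN axis (per-
    position inversion times), then the acquisition raster gradient sweeping
    the SPEN axis.  The readout oscillation has zero net moment per line and
    is omitted from the integral.
    """
    gap = 0.5e-3
    delta = (dm.delta * MS_TO_S) if dm else 0.0
    Delta = (dm.Delta * MS_TO_S) if dm else 0.0
    t_diff = (gap + Delta + delta + gap) if dm else 0.0
    tp = params.tp * MS_TO_S
    ta = params.acq_duration_s
    total = t_diff + tp + ta
    t = np.arange(0.0, total, dt)
    g = np.zeros((3, t.size))
    flips: list = []

    if dm is not None:
        env = np.zeros_like(t)
        env[(t >= gap) & (t < gap + delta)] = dm.g_amp
        env[(t >= gap + Delta) & (t < gap + Delta + delta)] = dm.g_amp
        g += np.outer(np.asarray(dm.orientation), env)
        flips.append(gap + (Delta + delta) / 2.0)

    y = params.spen_positions_cm
    L = params.fov_cm
    # chirp: encoding gradient on the SPEN axis; position y inverted at
    # t_diff + tp*(y/L + 1/2)
    chirp_on = (t >= t_diff) & (t < t_diff + tp)
    g[1, chirp_on] += params.g_enc
    flips.append(t_diff + tp * (y / L + 0.5))

    # acquisition raster: constant gradient rastering the SPEN axis
    # (total blip area = Nyquist step x matrix)
    acq_on = t >= t_diff + tp
    g_ras = 2.0 * math.pi * params.matrix / (L * _GAMMA * ta)
    g[1, acq_on] += g_ras

    return GradientWaveform(dt=dt, g=g), flips


@lru_cache(maxsize=64)
def spen_bmap_profile(
    params: SpenSequenceParams, dm: DiffusionModule | None
) -> np.ndarray:
    """Cached effective b(y) profile (s/mm^2) along the SPEN axis."""
    wf, flips = spen_sequence_waveform(params, dm)
    bm = effective_bmap(wf, flips, direction=dm.orientation if dm else None)
    return np.asarray(bm.b)


# ---------------------------------------------------------------------------
# encoding operators


@lru_cache(maxsize=16)
def _spen_operator(params: SpenSequenceParams):
    """Quadratic-phase encoding pieces shared by encode and reconstruct."""
    n = params.matrix
    k_shots = params.n_interleaves
    y = params.spen_positions_cm
    L = params.fov_cm
    phi = -(math.pi * params.r_factor / L**2) * y**2
    dk = params.dk_fine
    n_lines = n // k_shots
    # coarse raster per shot; shot s adds a fine K_shot offset s*dk
    j = np.arange(n_lines)
    k_coarse = dk * k_shots * (j - n_lines / 2.0)
    t_lines = j * params.esp_s  # within-shot acquisition times
    # per-position echo delay relative to acquisition start (flip at tau,
    # echo at 2*tau - tp after the chirp began)
    tp = params.tp * MS_TO_S
    tau = tp * (y / L + 0.5)
    return y, phi, k_coarse, t_lines, tau, dk, tp


@lru_cache(maxsize=16)
def _spen_recon_matrix(params: SpenSequenceParams, lam: float | None, subset: tuple):
    """Regularized pseudo-inverse of the assembled SPEN encoding operator."""
    y, phi, k_coarse, _, _, dk, _ = _spen_operator(params)
    ks = []
    for s in subset:
        ks.append(k_coarse + s * dk)
    k_all = np.sort(np.concatenate(ks))
    A = np.exp(1j * (phi[None, :] + k_all[:, None] * y[None, :]))
    smax = np.linalg.svd(A, compute_uv=False)[0]
    lam_eff = (1e-3 * smax) if lam is None else lam
    n = params.matrix
    return np.linalg.solve(
        A.conj().T @ A + (lam_eff**2) * np.eye(n), A.conj().T
    )


def encode_spen_shot(
    phantom_image: np.ndarray,
    params: SpenSequenceParams,
    dm: DiffusionModule | None = None,
    shot_index: int = 0,
    b0_offmap: np.ndarray | None = None,
    adc_map: np.ndarray | None = None,
    seed: int | None = None,
    snr: float | None = None,
) -> ShotData:
    """Simulate one SPEN interleave of a (complex) object.

    The object magnitude is attenuated voxelwise by exp(-b(y) * ADC) using
    the effective b-map when a diffusion module is present; the chirp's
    quadratic phase and the shot's fine K_shot offset (a phase ramp on the
    object) are applied; the readout axis is sampled as Fourier lines.

    Off-resonance: a frequency offset Δf is swept through by the chirp at a
    shifted moment, so the spin is encoded as if displaced along the SPEN
    axis by Δf · tp · L / R — the standard SPEN distortion, small because
    the chirp bandwidth R/tp is large.  The additional evolution phase
    between each position's inversion and its acquisition refocuses at that
    position's spin echo (the fully-refocused timing) and is modeled as
    refocused.
    """
    img = np.asarray(phantom_image, dtype=complex)
    n = params.matrix
    if img.shape != (n, n):
        raise ValueError(f"phantom_image shape {img.shape} != matrix {(n, n)}")
    if b0_offmap is not None and np.shape(b0_offmap) != img.shape:
        raise ValueError("b0_offmap shape mismatch")
    if not 0 <= shot_index < params.n_interleaves:
        raise ValueError("shot_index out of range")

    y, phi, k_coarse, t_lines, tau, dk, tp = _spen_operator(params)

    if dm is not None:
        b_y = spen_bmap_profile(params, dm)
        if adc_map is not None:
            img = img * np.exp(-b_y[:, None] * adc_map)

    if b0_offmap is not None:
        # chirp-displacement distortion: resample the object at the
        # apparent (shifted) SPEN positions
        shift_pix = (
            np.asarray(b0_offmap) * tp * n / params.r_factor
        )  # Δf·tp·L/R in voxels
        rows = np.arange(n, dtype=float)[:, None] - shift_pix
        cols = np.broadcast_to(np.arange(n, dtype=float)[None, :], (n, n))
        from scipy.ndimage import map_coordinates

        img = map_coordinates(
            img.real, [rows, cols], order=1, mode="constant"
        ) + 1j * map_coordinates(img.imag, [rows, cols], order=1, mode="constant")

    # K_shot interleave offset: a fine phase ramp on the object
    ramp = np.exp(1j * (shot_index * dk) * y)
    obj = img * ramp[:, None]

    A = np.exp(1j * (phi[None, :] + k_coarse[:, None] * y[None, :]))
    inner = A @ obj  # (n_lines, n_ro)
    samples = np.fft.fft(inner, axis=1, norm="ortho").T  # (n_ro, n_lines)

    if snr is not None and np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = np.mean(np.abs(samples)) / snr
        samples = samples + sigma * (
            rng.standard_normal(samples.shape)
            + 1j * rng.standard_normal(samples.shape)
        )

    return ShotData(
        samples=samples,
        shot_index=shot_index,
        k_shot_offset=shot_index * dk,
        line_k=k_coarse + shot_index * dk,
        line_times=t_lines,
    )


def reconstruct_spen(
    shots: list[ShotData],
    params: SpenSequenceParams,
    lam: float | None = None,
    return_complex: bool = False,
    allow_partial: bool = False,
) -> np.ndarray:
    """Invert the SPEN acquisition: inverse Fourier along readout, then a
    ridge-regularized pseudo-inverse of the quadratic-phase operator along
    the SPEN axis.  Requires all ``n_interleaves`` shots with distinct
    K_shot offsets unless ``allow_partial``."""
    indices = tuple(sorted(s.shot_index for s in shots))
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate shot offsets")
    if not allow_partial and indices != tuple(range(params.n_interleaves)):
        raise ValueError(
            f"need all {params.n_interleaves} distinct shots, got {indices}"
        )
    order = np.argsort([s.shot_index for s in shots])
    shots = [shots[i] for i in order]

    rows = np.concatenate([s.samples.T for s in shots], axis=0)  # (lines, n_ro)
    k_all = np.concatenate([s.line_k for s in shots])
    rows = rows[np.argsort(k_all)]

    inner = np.fft.ifft(rows, axis=1, norm="ortho")
    ainv = _spen_recon_matrix(params, lam, tuple(sorted(indices)))
    rec = ainv @ inner
    return rec if return_complex else np.abs(rec)


# ---------------------------------------------------------------------------
# EPI comparator


def encode_epi(
    phantom_image: np.ndarray,
    params: EpiSequenceParams,
    dm: DiffusionModule | None = None,
    b0_offmap: np.ndarray | None = None,
    adc_map: np.ndarray | None = None,
    seed: int | None = None,
    snr: float | None = None,
) -> list[ShotData]:
    """Interleaved 2D Fourier (EPI) encoding of a complex object.

    Off-resonance Δf accrues phase linearly over the echo train, displacing
    signal along the phase axis by Δf x (per-shot acquisition duration)
    voxels after reconstruction.
    """
    img = np.asarray(phantom_image, dtype=complex)
    n = params.matrix
    if img.shape != (n, n):
        raise ValueError(f"phantom_image shape {img.shape} != matrix {(n, n)}")
    if b0_offmap is not None and np.shape(b0_offmap) != img.shape:
        raise ValueError("b0_offmap shape mismatch")

    if dm is not None and adc_map is not None:
        img = img * np.exp(-bvalue_stejskal_tanner(dm) * adc_map)

    L = params.fov_cm
    y = (np.arange(n) - n // 2) * (L / n)
    esp = params.esp * MS_TO_S
    K = params.n_interleaves
    rng = np.random.default_rng(seed)
    out = []
    for s in range(K):
        m = np.arange(s, n, K)  # global phase-encode line indices
        k = (2.0 * math.pi / L) * (m - n / 2)
        t = (m // K) * esp
        A = np.exp(1j * k[:, None] * y[None, :])
        if b0_offmap is None:
            inner = A @ img
        else:
            inner = np.empty((m.size, n), dtype=complex)
            for jj in range(m.size):
                inner[jj] = A[jj] @ (img * np.exp(1j * 2 * np.pi * b0_offmap * t[jj]))
        samples = np.fft.fft(inner, axis=1, norm="ortho").T
        if snr is not None and np.isfinite(snr):
            sigma = np.mean(np.abs(samples)) / snr
            samples = samples + sigma * (
                rng.standard_normal(samples.shape)
                + 1j * rng.standard_normal(samples.shape)
            )
        out.append(
            ShotData(
                samples=samples,
                shot_index=s,
                k_shot_offset=float(k[0]),
                line_k=k,
                line_times=t,
            )
        )
    return out


def reconstruct_epi(
    shots: list[ShotData],
    params: EpiSequenceParams,
    return_complex: bool = False,
) -> np.ndarray:
    """Assemble interleaves and invert by 2D inverse Fourier transform."""
    n = params.matrix
    indices = sorted(s.shot_index for s in shots)
    if indices != list(range(params.n_interleaves)):
        raise ValueError("missing or duplicate EPI interleaves")
    rows = np.concatenate([s.samples.T for s in shots], axis=0)
    k_all = np.concatenate([s.line_k for s in shots])
    rows = rows[np.argsort(k_all)]
    inner = np.fft.ifft(rows, axis=1, norm="ortho")
    L = params.fov_cm
    y = (np.arange(n) - n // 2) * (L / n)
    k = (2.0 * math.pi / L) * (np.arange(n) - n / 2)
    A = np.exp(1j * k[:, None] * y[None, :])
    rec = A.conj().T @ inner / n
    return rec if return_complex else np.abs(rec)


def epi_offresonance_shift_voxels(params: EpiSequenceParams, df_hz: float) -> float:
    """Analytic bulk displacement along the phase axis for a uniform offset."""
    return df_hz * params.esp * MS_TO_S * params.matrix / params.n_interleaves


# ---------------------------------------------------------------------------
# noise and series simulation


def add_rician_noise(
    data: np.ndarray,
    snr: float | None = None,
    seed: int = 0,
    sigma: float | None = None,
) -> np.ndarray:
    """Add independent complex Gaussian noise (σ = mean signal / SNR).

    Complex input stays complex; real input is returned as the magnitude of
    signal-plus-noise (Rician).
    """
    data = np.asarray(data)
    if sigma is None:
        if snr is None or not np.isfinite(snr):
            return data.copy()
        if snr <= 0:
            raise ValueError("snr must be positive")
        sigma = float(np.mean(np.abs(data))) / snr
    rng = np.random.default_rng(seed)
    noise = sigma * (
        rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
    )
    if np.iscomplexobj(data):
        return data + noise
    return np.abs(data + noise)


def relaxation_weighted_image(
    phantom: FetoplacentalPhantom, tr_ms: float, te_ms: float
) -> np.ndarray:
    """Static signal scale: proton density with T2/TE and T1/TR weighting
    folded into one per-voxel factor (no echo-train relaxation modeling)."""
    t = phantom.truth_maps
    return (
        t["proton_density"]
        * np.exp(-te_ms / np.maximum(t["t2"], 1e-6))
        * (1.0 - np.exp(-tr_ms / np.maximum(t["t1"], 1e-6)))
    )


def default_diffusion_modules(
    g_amp: float = 33.0, delta: float = 3.2, Delta: float = 10.0
) -> tuple:
    """b≈0 plus three orthogonal directions at the nominal b≈750 setting."""
    return (
        None,
        DiffusionModule(delta, Delta, g_amp, (1.0, 0.0, 0.0)),
        DiffusionModule(delta, Delta, g_amp, (0.0, 1.0, 0.0)),
        DiffusionModule(delta, Delta, g_amp, (0.0, 0.0, 1.0)),
    )


def simulate_dwi_series(
    phantom: FetoplacentalPhantom,
    params: SpenSequenceParams,
    dms: tuple | None = None,
    snr: float | None = None,
    seed: int = 0,
    b0_offmap: np.ndarray | None = None,
) -> DwiSeries:
    """Full SPEN DWI acquisition of a phantom: one reconstructed magnitude
    image and matching effective b-map per diffusion setting.

    The diffusion list must include a b≈0 entry (``None``); noise of the
    requested image-domain SNR (referenced to the b≈0 image) is added to the
    complex reconstruction before taking the magnitude.
    """
    if dms is None:
        dms = default_diffusion_modules()
    if not any(d is None for d in dms):
        raise ValueError("diffusion list must include a b≈0 (None) entry")
    n = params.matrix
    if phantom.shape != (n, n):
        raise ValueError("phantom grid does not match sequence matrix")

    base = relaxation_weighted_image(phantom, params.tr, params.te).astype(complex)
    adc = phantom.truth_maps["adc"]

    images, bmaps, nominal = [], [], []
    sigma_ref = None
    rng = np.random.default_rng(np.random.SeedSequence([seed, phantom.seed % (2**31)]))
    for dm in dms:
        b_y = spen_bmap_profile(params, dm)
        img = base * np.exp(-b_y[:, None] * adc)
        shots = [
            encode_spen_shot(
                img, params, dm=None, shot_index=s, b0_offmap=b0_offmap
            )
            for s in range(params.n_interleaves)
        ]
        rec = reconstruct_spen(shots, params, return_complex=True)
        if snr is not None and np.isfinite(snr):
            if sigma_ref is None:
                sigma_ref = float(np.mean(np.abs(rec))) / snr
            rec = rec + sigma_ref * (
                rng.standard_normal(rec.shape) + 1j * rng.standard_normal(rec.shape)
            )
        images.append(np.abs(rec))
        bmaps.append(np.broadcast_to(b_y[:, None], (n, n)).copy())
        nominal.append(bvalue_stejskal_tanner(dm) if dm else 0.0)

    return DwiSeries(
        images=np.stack(images),
        bmaps=np.stack(bmaps),
        modules=tuple(dms),
        nominal_b=tuple(nominal),
        snr=snr,
        noise_sigma=sigma_ref,
    )
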