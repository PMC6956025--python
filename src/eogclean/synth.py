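"""Semi-simulated EEG benchmark generator.

Emulates the semi-simulated construction used to validate ocular-artifact
removal: an artifact-free multichannel EEG recording plus vertical/horizontal
ocular source traces added with known per-channel propagation coefficients,

    contaminated[i, :] = pure[i, :] + a[i] * veog + b[i] * heog,

together with ground-truth event peak times.  Because the propagation
coefficients and the event times are known exactly, every stage of the
pipeline — identification, peak detection, selective correction — can be
scored without any external dataset.

The pure-EEG model is itself a linear mixture, the regime the unmixing
method assumes: burst-modulated, band-limited sources with a steep (1/f²
power) spectrum and smooth topographies on a 2-D projection of the 10–20
electrode layout (several of them over the frontal region, since frontal
cortex is always active), two amplitude-modulated alpha-band (8–12 Hz)
oscillators with posterior topographies plus a small global far-field gain,
and a weak independent sensor-noise floor per channel.  The smooth
topographies are blended toward their orthogonal polar factor until the
mixing matrix is well conditioned — honouring the invertible-mixing
precondition of the separation model — and channel amplitudes come out at
resting eyes-closed scale (~12–25 µV RMS).

Blinks are squared-cosine bumps (200–400 ms wide, 100–400 µV at the source);
saccades are smoothed step pulses with a 0.5–1 s plateau.  Default
propagation coefficients decay exponentially with a channel's distance from
the eyes on the same 2-D layout: the vertical (blink) profile is the summed
proximity of both eyes, the horizontal (saccade) profile their signed
difference (left-positive), mirroring the opposite polarity of horizontal
eye movements over the two hemispheres.

All randomness flows from a single seed through named substreams, so each
piece of a dataset is reproducible piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.linalg as la
from scipy import signal as sps

from .recording import Recording

__all__ = [
    "CHANNELS_1020",
    "FRONTAL_1020",
    "POS_1020",
    "SyntheticDataset",
    "gen_pure_eeg",
    "gen_eog_sources",
    "contaminate",
    "veog_propagation",
    "heog_propagation",
    "make_dataset",
    "gen_ica_toy",
]

#: Standard 19-electrode 10–20 layout, front to back.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]

#: Forehead channels used for ocular-component identification.
FRONTAL_1020 = ["Fp1", "Fp2", "F7", "F8"]

#: 2-D scalp projection of the 19 channel positions (nose up, unit radius).
POS_1020 = np.array([
    (-0.31, 0.95), (0.31, 0.95),
    (-0.81, 0.59), (-0.42, 0.48), (0.0, 0.50), (0.42, 0.48), (0.81, 0.59),
    (-1.0, 0.0), (-0.5, 0.0), (0.0, 0.0), (0.5, 0.0), (1.0, 0.0),
    (-0.81, -0.59), (-0.42, -0.48), (0.0, -0.50), (0.42, -0.48), (0.81, -0.59),
    (-0.31, -0.95), (0.31, -0.95),
])

_EYE_L = np.array([-0.35, 1.35])
_EYE_R = np.array([0.35, 1.35])

_STREAMS = {"pure": 1, "eog": 2, "coef": 3, "toy": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


def _positions(n_channels: int) -> np.ndarray:
    """Channel positions: the 10–20 set, or rings of electrodes beyond 19."""
    if n_channels <= len(POS_1020):
        return POS_1020[:n_channels]
    extra = n_channels - len(POS_1020)
    angles = np.linspace(0, 2 * np.pi, extra, endpoint=False) + np.pi / 2
    ring = 0.75 * np.column_stack([np.cos(angles), np.sin(angles)])
    return np.vstack([POS_1020, ring])


@dataclass
class SyntheticDataset:
    """One semi-simulated benchmark dataset with ground truth."""

    pure: Recording
    veog: np.ndarray
    heog: np.ndarray
    a: np.ndarray
    b: np.ndarray
    contaminated: Recording
    truth: dict
    seed: int


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float] = (1.0, 47.0),
                exponent: float = 2.0) -> np.ndarray:
    """Band-limited 1/f-family noise of unit RMS via spectral shaping.

    ``exponent`` is the power-spectral-density slope alpha in PSD ∝
    1/f^alpha; the default alpha=2 matches the steep low-frequency roll-off
    of resting scalp EEG.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = (rng.standard_normal(freqs.size)
                + 1j * rng.standard_normal(freqs.size))
    amp = np.zeros_like(freqs)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    amp[inside] = freqs[inside] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * amp, n=n)
    return x / x.std()


def _burst_env(rng: np.random.Generator, n: int, fs: float,
               f_lp: float = 1.0, floor: float = 0.25) -> np.ndarray:
    """Slow non-negative burst envelope; makes a source super-Gaussian."""
    sos = sps.butter(2, f_lp, btype="lowpass", fs=fs, output="sos")
    env = np.abs(sps.sosfiltfilt(sos, rng.standard_normal(n)))
    return env / env.std() + floor


def _condition_mixing(M: np.ndarray, target_cond: float = 12.0) -> np.ndarray:
    """Blend smooth topography columns toward their orthogonal polar factor.

    Smooth scalp profiles are near-collinear; this finds the smallest blend
    that brings the condition number below ``target_cond`` so the mixture is
    comfortably invertible, then re-normalizes the columns.
    """
    U, _, Vt = la.svd(M, full_matrices=False)
    Q = U @ Vt
    lo, hi = 0.0, 1.0
    for _ in range(40):
        beta = 0.5 * (lo + hi)
        if la.cond((1 - beta) * M + beta * Q) > target_cond:
            lo = beta
        else:
            hi = beta
    Mc = (1 - hi) * M + hi * Q
    return Mc / la.norm(Mc, axis=0, keepdims=True)


def gen_pure_eeg(n_channels: int = 19, fs: float = 200.0, duration_s: float = 120.0,
                 seed: int = 0, labels: list[str] | None = None,
                 mean_rms_uV: float = 18.0) -> Recording:
    """Generate an artifact-free multichannel EEG-like recording.

    Deterministic per seed.  Every channel carries an alpha bump (8–12 Hz)
    over a steep-spectrum background; channels are correlated through the
    shared cortical-like sources.
    """
    rng = _rng(seed, "pure")
    k = n_channels
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    pos = _positions(k)
    if labels is None:
        labels = (CHANNELS_1020[:k] if k <= len(CHANNELS_1020)
                  else CHANNELS_1020 + [f"ch{i}" for i in range(len(CHANNELS_1020), k)])

    n_src = max(2, k - 5)
    n_frontal = min(5, n_src // 2)
    cols = []
    for i in range(n_src):
        if i < n_frontal:
            c = np.array([rng.uniform(-0.9, 0.9), rng.uniform(0.45, 1.1)])
        else:
            c = rng.uniform(-1.1, 1.1, 2)
        width = rng.uniform(0.6, 1.0)
        g = np.exp(-0.5 * np.sum((pos - c) ** 2, axis=1) / width ** 2)
        if rng.random() < 0.5:  # dipolar pattern: subtract a shifted lobe
            ang = rng.uniform(0, 2 * np.pi)
            c2 = c + rng.uniform(0.4, 0.8) * np.array([np.cos(ang), np.sin(ang)])
            g = g - rng.uniform(0.5, 1.0) * np.exp(
                -0.5 * np.sum((pos - c2) ** 2, axis=1) / width ** 2)
        cols.append(g / la.norm(g))
    M = _condition_mixing(np.array(cols).T)
    M = M * rng.uniform(0.85, 1.15, n_src)[None, :]

    src = np.empty((n_src, n))
    for i in range(n_src):
        x = _pink_noise(rng, n, fs) * _burst_env(rng, n, fs)
        src[i] = x / x.std()

    alpha = np.empty((2, n))
    alpha_gain = np.zeros((k, 2))
    for j in range(2):
        f_alpha = rng.uniform(8.0, 12.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = np.sin(2.0 * np.pi * f_alpha * t + phase) * _burst_env(rng, n, fs)
        alpha[j] = wave / wave.std()
        c = np.array([rng.uniform(-0.6, 0.6), rng.uniform(-1.1, -0.4)])  # posterior
        width = rng.uniform(0.5, 0.9)
        g = np.exp(-0.5 * np.sum((pos - c) ** 2, axis=1) / width ** 2)
        # small global far-field share so every channel shows an alpha bump
        alpha_gain[:, j] = (g / la.norm(g) + 0.15) * rng.uniform(1.0, 1.3)

    data = M @ src + alpha_gain @ alpha
    ch_rms = np.maximum(data.std(axis=1), 0.3 * data.std(axis=1).mean())
    for i in range(k):
        data[i] += 0.1 * ch_rms[i] * _pink_noise(rng, n, fs, exponent=1.0)
    data *= mean_rms_uV / data.std(axis=1).mean()
    return Recording(data=data, fs=fs, labels=list(labels),
                     meta={"synthetic": True, "seed": seed})


def _draw_times(rng: np.random.Generator, n_events: int, duration_s: float,
                margin_s: float, min_gap_s: float) -> np.ndarray:
    """Random event times with a minimum gap, by rejection sampling."""
    times: list[float] = []
    attempts = 0
    while len(times) < n_events and attempts < 20000:
        attempts += 1
        t = rng.uniform(margin_s, duration_s - margin_s)
        if all(abs(t - u) >= min_gap_s for u in times):
            times.append(t)
    return np.sort(np.array(times))


def gen_eog_sources(fs: float = 200.0, duration_s: float = 120.0,
                    blink_rate_per_min: float = 12.0,
                    saccade_rate_per_min: float = 2.0,
                    blink_amp_uV: tuple[float, float] = (100.0, 400.0),
                    saccade_amp_uV: tuple[float, float] = (50.0, 150.0),
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate vertical (blink) and horizontal (saccade) ocular source traces.

    Returns ``(veog, heog, truth)`` where ``truth`` maps ``"veog"``/``"heog"``
    to arrays of event peak times in seconds.  Event times within each source
    are at least 0.8 s apart (comfortably above the 0.5 s peak-spacing rule)
    and blink peaks are aligned to the sample grid.
    """
    rng = _rng(seed, "eog")
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    veog = np.zeros(n)
    heog = np.zeros(n)

    n_blinks = int(round(blink_rate_per_min * duration_s / 60.0))
    blink_times = _draw_times(rng, n_blinks, duration_s, margin_s=1.0, min_gap_s=0.8)
    blink_times = np.round(blink_times * fs) / fs
    for tc in blink_times:
        width = rng.uniform(0.2, 0.4)
        amp = rng.uniform(*blink_amp_uV)
        mask = np.abs(t - tc) < width / 2.0
        veog[mask] += amp * np.cos(np.pi * (t[mask] - tc) / width) ** 2

    n_sacc = int(round(saccade_rate_per_min * duration_s / 60.0))
    sacc_times = _draw_times(rng, n_sacc, duration_s, margin_s=1.5, min_gap_s=1.6)
    sacc_times = np.round(sacc_times * fs) / fs
    for tc in sacc_times:
        plateau = rng.uniform(0.5, 1.0)
        amp = rng.uniform(*saccade_amp_uV)
        ramp = 0.1
        rel = np.abs(t - tc)
        pulse = np.zeros(n)
        flat = rel <= plateau / 2.0
        edge = (rel > plateau / 2.0) & (rel < plateau / 2.0 + ramp)
        pulse[flat] = 1.0
        pulse[edge] = np.cos(np.pi * (rel[edge] - plateau / 2.0) / (2.0 * ramp)) ** 2
        heog += amp * pulse

    truth = {"veog": blink_times, "heog": sacc_times}
    return veog, heog, truth


def veog_propagation(n_channels: int = 19, peak: float = 1.0,
                     tau: float = 0.5) -> np.ndarray:
    """Blink propagation: summed exponential proximity to both eyes.

    Non-negative, maximal at the prefrontal channels, decaying toward the
    back of the head; ``peak`` is the coefficient at the strongest channel.
    """
    pos = _positions(n_channels)
    d_l = la.norm(pos - _EYE_L, axis=1)
    d_r = la.norm(pos - _EYE_R, axis=1)
    v = np.exp(-d_l / tau) + np.exp(-d_r / tau)
    return peak * v / v.max()


def heog_propagation(n_channels: int = 19, peak: float = 0.5,
                     tau: float = 0.5) -> np.ndarray:
    """Saccade propagation: signed left/right eye proximity difference.

    Positive over the left hemisphere, negative over the right, zero on the
    midline — the antisymmetric topography of horizontal eye movements.
    """
    pos = _positions(n_channels)
    d_l = la.norm(pos - _EYE_L, axis=1)
    d_r = la.norm(pos - _EYE_R, axis=1)
    h = np.exp(-d_l / tau) - np.exp(-d_r / tau)
    return peak * h / np.abs(h).max()


def contaminate(pure: Recording, veog: np.ndarray, heog: np.ndarray,
                a: np.ndarray, b: np.ndarray) -> Recording:
    """Exact additive mixture of ocular sources into a pure recording."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size != pure.n_channels or b.size != pure.n_channels:
        raise ValueError("propagation coefficient vectors must have one entry per channel")
    if veog.size != pure.n_samples or heog.size != pure.n_samples:
        raise ValueError("ocular source traces must match the recording length")
    data = pure.data + np.outer(a, veog) + np.outer(b, heog)
    return pure.copy(data=data, contaminated=True)


def make_dataset(n_channels: int = 19, fs: float = 200.0, duration_s: float = 120.0,
                 blink_rate_per_min: float = 12.0, saccade_rate_per_min: float = 2.0,
                 a_peak: float = 1.0, b_peak: float = 0.5, tau: float = 0.5,
                 seed: int = 0) -> SyntheticDataset:
    """Build one complete semi-simulated dataset with ground truth."""
    pure = gen_pure_eeg(n_channels=n_channels, fs=fs, duration_s=duration_s, seed=seed)
    veog, heog, truth = gen_eog_sources(
        fs=fs, duration_s=duration_s, blink_rate_per_min=blink_rate_per_min,
        saccade_rate_per_min=saccade_rate_per_min, seed=seed,
    )
    a = veog_propagation(n_channels, peak=a_peak, tau=tau)
    b = heog_propagation(n_channels, peak=b_peak, tau=tau)
    contaminated = contaminate(pure, veog, heog, a, b)
    return SyntheticDataset(pure=pure, veog=veog, heog=heog, a=a, b=b,
                            contaminated=contaminated, truth=truth, seed=seed)


def gen_ica_toy(n_sources: int = 3, n_samples: int = 20000,
                seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Laplacian-source toy problem for checking blind source separation.

    Returns ``(sources, mixing, mixture)`` with unit-variance, independent
    (super-Gaussian) Laplacian sources and a random well-conditioned mixing
    matrix (condition number < 10).
    """
    rng = _rng(seed, "toy")
    sources = rng.laplace(size=(n_sources, n_samples)) / np.sqrt(2.0)
    sources = sources - sources.mean(axis=1, keepdims=True)
    sources /= sources.std(axis=1, keepdims=True)
    for _ in range(100):
        mixing = rng.standard_normal((n_sources, n_sources))
        if la.cond(mixing) < 10.0:
            break
    else:
        raise RuntimeError("failed to draw a well-conditioned mixing matrix")
    return sources, mixing, mixing @ sources
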