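"""Forward simulator for dyadic two-wavelength fNIRS co-viewing cohorts.

The generator emulates the measurement chain the analysis inverts: each
subject's "true" per-channel oxy-haemoglobin change is a haemodynamic
(double-gamma HRF convolved) response to the seven emotive video blocks,
split into a dyad-shared component and a subject-individual component with
mixing weight kappa (the inter-brain coupling strength),

    dHbO_true(subject) = kappa * shared + (1 - kappa) * individual(subject),

on top of which subject-independent physiological noise (cardiac,
respiratory and low-frequency oscillations), white noise, linear drift and
occasional motion spikes are added.  Deoxy-haemoglobin is the usual
anticorrelated mirror, dHbR = -dHbO_true / 3, plus its own small noise.
Concentrations are mapped to 760/850 nm optical densities with the same
Beer-Lambert geometry the preprocessing inverts, so the conversion
round-trips exactly in the noise-free case.

Coupling is linked to the dyad's relationship-satisfaction difference
``delta_sat`` through a linear link with Gaussian scatter,

    kappa = clip(beta0 + beta1 * delta_sat + N(0, sigma), 0, 1),

so a positive beta1 makes mismatched couples more coupled, which downstream
should surface as a negative regression coefficient of the DTW distance
index on the satisfaction difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .optics import ChannelGeometry, od_from_hemo
from .ras import LIKERT_MAX, LIKERT_MIN, N_ITEMS, RASResponse, REVERSE_SCORED_ITEMS
from .recording import ANALYSIS_CHANNELS, RawDyadRecording, SubjectRecording
from .schedule import CONDITION_CATEGORY, TOTAL_DURATION_S, make_schedule


@dataclass(frozen=True)
class CouplingLink:
    """Linear link from satisfaction difference to coupling strength."""

    beta0: float = 0.2
    beta1: float = 0.35
    sigma: float = 0.05


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF: peak at 6 s, undershoot at 16 s, ratio 1/6."""

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    undershoot_ratio: float = 6.0
    dispersion_s: float = 1.0
    duration_s: float = 32.0


@dataclass(frozen=True)
class NoiseParams:
    """Amplitudes (uM) and frequencies (Hz) of the physiological noise model.

    Cardiac and respiratory components are sinusoids with random phase;
    the low-frequency (Mayer-wave) component is a stochastic narrowband
    oscillation around ``lowfreq_hz`` with the same power as a sinusoid of
    amplitude ``lowfreq_uM``.
    """

    cardiac_hz: float = 1.1
    cardiac_uM: float = 0.3
    respiratory_hz: float = 0.25
    respiratory_uM: float = 0.2
    lowfreq_hz: float = 0.1
    lowfreq_uM: float = 0.25
    white_uM: float = 0.05
    drift_uM: float = 0.5
    hbr_white_uM: float = 0.02


@dataclass(frozen=True)
class SpikeParams:
    """Motion-spike model: Poisson arrivals, 1-3 sample width, large amplitude."""

    rate_per_min: float = 0.2
    magnitude_uM: tuple[float, float] = (5.0, 15.0)
    max_width_samples: int = 3


@dataclass(frozen=True)
class IndividualParams:
    """Subject-specific deviation from the shared response.

    ``amp_jitter`` is the SD of the multiplicative response-amplitude
    variation drawn independently per channel and per block (attention and
    habituation fluctuate over the session); ``wander_uM`` is the RMS of a
    slow (low-pass filtered) individual signal.
    """

    amp_jitter: float = 0.3
    wander_uM: float = 0.3
    wander_cutoff_hz: float = 0.05


@dataclass(frozen=True)
class QualityParams:
    """Generation of gain / coefficient-of-variation channel metadata."""

    p_bad: float = 0.05
    gain_good: tuple[int, int] = (1, 8)
    gain_bad: tuple[int, int] = (9, 12)
    cv_good: tuple[float, float] = (1.0, 7.0)
    cv_bad: tuple[float, float] = (8.0, 15.0)


@dataclass(frozen=True)
class RASParams:
    """Satisfaction-score generation: per-role means and between-subject SD."""

    mean_a: float = 4.3
    mean_b: float = 4.4
    between_sd: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated cohort.

    Defaults reproduce the co-viewing design: 15 analysed dyads, 7.81 Hz
    sampling, the 7-block (60 s fixation + 114 s video) paradigm, and the
    eight ventral-PFC channels.
    """

    n_dyads: int = 15
    sampling_rate: float = 7.81
    channels: tuple[int, ...] = ANALYSIS_CHANNELS
    #: Condition response amplitudes in uM of dHbO.
    amplitudes_uM: tuple[tuple[str, float], ...] = (
        ("positive", 0.5),
        ("negative", 0.5),
        ("baseline", 0.2),
    )
    coupling: CouplingLink = CouplingLink()
    hrf: HRFParams = HRFParams()
    noise: NoiseParams = NoiseParams()
    spikes: SpikeParams = SpikeParams()
    individual: IndividualParams = IndividualParams()
    quality: QualityParams = QualityParams()
    ras: RASParams = RASParams()
    channel_amp_sigma: float = 0.2
    geometry: ChannelGeometry = ChannelGeometry()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValidationError(f"n_dyads must be >= 1, got {self.n_dyads}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if any(a < 0 for _, a in self.amplitudes_uM):
            raise ValidationError("condition amplitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(math.floor(TOTAL_DURATION_S * self.sampling_rate))

    @property
    def amplitude_map(self) -> dict[str, float]:
        return dict(self.amplitudes_uM)


def dyad_seed_from_master(master_seed: int, dyad_index: int) -> int:
    """Stable per-dyad seed: SeedSequence(master, spawn_key=(index,)), 31-bit."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(dyad_index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def double_gamma_hrf(sampling_rate: float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Canonical double-gamma HRF kernel sampled at ``sampling_rate``, peak = 1."""
    t = np.arange(0.0, params.duration_s, 1.0 / sampling_rate)
    d = params.dispersion_s

    def gamma_bump(mode_s: float) -> np.ndarray:
        k = mode_s / d  # mode of t**k * exp(-t/d) is k*d
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.exp(k * np.log(np.where(t > 0, t / mode_s, 1.0)) - (t - mode_s) / d)
        g[t <= 0] = 0.0
        return g

    h = gamma_bump(params.peak_s) - gamma_bump(params.undershoot_s) / params.undershoot_ratio
    return h / np.max(h)


def _block_regressors_uncached(
    sequence_label: str,
    sampling_rate: float,
    hrf: HRFParams,
    n_samples: int,
) -> np.ndarray:
    """(n_blocks, n_samples) unit-amplitude HRF-convolved boxcar per video block."""
    schedule = make_schedule(sequence_label)
    kernel = double_gamma_hrf(sampling_rate, hrf)
    blocks = schedule.video_blocks
    out = np.zeros((len(blocks), n_samples))
    for k, block in enumerate(blocks):
        start = int(math.floor(block.onset_s * sampling_rate))
        stop = min(start + int(math.floor(block.duration_s * sampling_rate)), n_samples)
        box = np.zeros(n_samples)
        box[start:stop] = 1.0
        out[k] = sps.fftconvolve(box, kernel)[:n_samples]
    return out


_block_regressors = lru_cache(maxsize=32)(_block_regressors_uncached)


def _block_amplitudes(sequence_label: str, amplitudes: dict[str, float]) -> np.ndarray:
    schedule = make_schedule(sequence_label)
    return np.array(
        [amplitudes[CONDITION_CATEGORY[b.condition]] for b in schedule.video_blocks]
    )


def draw_kappa(link: CouplingLink, delta_sat: float, rng: np.random.Generator) -> float:
    """Coupling strength kappa = clip(beta0 + beta1*ds + N(0, sigma), 0, 1)."""
    k = link.beta0 + link.beta1 * delta_sat + rng.normal(0.0, link.sigma)
    return float(np.clip(k, 0.0, 1.0))


def _items_for_score(target: float, rng: np.random.Generator) -> RASResponse:
    """Integer RAS items whose keyed mean is within 1/(2*7) of ``target``.

    Builds keyed (already reverse-corrected) items around the target, then
    un-keys items 4 and 7 so that scoring the response reproduces the keyed
    mean.  A few mean-preserving +1/-1 swaps add item-level variety.
    """
    target = float(np.clip(target, LIKERT_MIN, LIKERT_MAX))
    base = int(round(target))
    keyed = np.full(N_ITEMS, base, dtype=int)
    delta = int(round(target * N_ITEMS)) - base * N_ITEMS
    step = 1 if delta > 0 else -1
    idx = rng.permutation(N_ITEMS)
    for i in idx[: abs(delta)]:
        keyed[i] += step
    # mean-preserving jitter
    for _ in range(4):
        i, j = rng.integers(0, N_ITEMS, size=2)
        if i != j and keyed[i] < LIKERT_MAX and keyed[j] > LIKERT_MIN:
            keyed[i] += 1
            keyed[j] -= 1
    keyed = np.clip(keyed, LIKERT_MIN, LIKERT_MAX)
    items = [
        int(LIKERT_MAX + 1 - keyed[i - 1]) if i in REVERSE_SCORED_ITEMS else int(keyed[i - 1])
        for i in range(1, N_ITEMS + 1)
    ]
    return RASResponse(tuple(items))


def _lowpass_noise(
    rng: np.random.Generator, shape: tuple[int, int], cutoff_hz: float, fs: float
) -> np.ndarray:
    """Unit-RMS smooth noise: white noise low-passed below ``cutoff_hz``."""
    white = rng.standard_normal(shape)
    sos = sps.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    smooth = sps.sosfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(smooth**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return smooth / rms


def _narrowband_noise(
    rng: np.random.Generator, shape: tuple[int, int], center_hz: float, fs: float
) -> np.ndarray:
    """Unit-RMS stochastic oscillation in a band of +-20% around ``center_hz``."""
    white = rng.standard_normal(shape)
    sos = sps.butter(2, (0.8 * center_hz, 1.2 * center_hz), btype="bandpass", fs=fs, output="sos")
    nb = sps.sosfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(nb**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return nb / rms


def simulate_dyad(
    config: SimConfig,
    delta_sat: float,
    dyad_seed: int,
    sequence_label: str = "A",
    dyad_id: str = "dyad00",
    scores: Optional[tuple[float, float]] = None,
) -> RawDyadRecording:
    """Simulate one dyad's raw two-wavelength recording.

    ``delta_sat`` drives the coupling strength through the configured link;
    ``scores`` optionally fixes the two satisfaction scores (otherwise they
    are drawn consistently with ``delta_sat``).  The same
    ``(config, delta_sat, dyad_seed)`` always yields an identical recording.
    """
    rng = np.random.default_rng(dyad_seed)
    fs = config.sampling_rate
    n = config.n_samples
    n_ch = len(config.channels)
    t = np.arange(n) / fs

    kappa = draw_kappa(config.coupling, delta_sat, rng)

    regressors = _block_regressors(sequence_label, fs, config.hrf, n)
    block_amp = _block_amplitudes(sequence_label, config.amplitude_map)
    n_blocks = regressors.shape[0]
    ch_amp = rng.lognormal(0.0, config.channel_amp_sigma, size=n_ch)
    # shared condition-locked response: (n_ch, n)
    shared = ch_amp[:, None] * (block_amp @ regressors)[None, :]

    if scores is None:
        score_a = float(np.clip(rng.normal(config.ras.mean_a, config.ras.between_sd), 1, 7))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        score_b = float(np.clip(score_a + sign * delta_sat, 1, 7))
    else:
        score_a, score_b = scores

    nz = config.noise
    ind = config.individual
    subjects = []
    for label, score in (("a", score_a), ("b", score_b)):
        # per-channel, per-block response-amplitude jitter
        amp_jit = rng.normal(1.0, ind.amp_jitter, size=(n_ch, n_blocks))
        wander = (
            ind.wander_uM * _lowpass_noise(rng, (n_ch, n), ind.wander_cutoff_hz, fs)
            if ind.wander_uM > 0
            else 0.0
        )
        individual = ch_amp[:, None] * ((amp_jit * block_amp) @ regressors) + wander
        hbo_true = kappa * shared + (1.0 - kappa) * individual

        phases = rng.uniform(0, 2 * np.pi, size=(2, n_ch, 1))
        noise = (
            nz.cardiac_uM * np.sin(2 * np.pi * nz.cardiac_hz * t + phases[0])
            + nz.respiratory_uM * np.sin(2 * np.pi * nz.respiratory_hz * t + phases[1])
        )
        if nz.lowfreq_uM > 0:
            noise += (
                nz.lowfreq_uM
                / np.sqrt(2.0)
                * _narrowband_noise(rng, (n_ch, n), nz.lowfreq_hz, fs)
            )
        noise += nz.white_uM * rng.standard_normal((n_ch, n))
        noise += nz.drift_uM * rng.uniform(-1, 1, size=(n_ch, 1)) * (t / t[-1])[None, :]

        hbo = hbo_true + noise
        # motion spikes
        sp = config.spikes
        n_spikes = rng.poisson(sp.rate_per_min * TOTAL_DURATION_S / 60.0, size=n_ch)
        for c in range(n_ch):
            for _ in range(int(n_spikes[c])):
                pos = int(rng.integers(0, n))
                width = int(rng.integers(1, sp.max_width_samples + 1))
                mag = rng.uniform(*sp.magnitude_uM) * (1 if rng.random() < 0.5 else -1)
                hbo[c, pos : pos + width] += mag

        hbr = -hbo_true / 3.0
        if nz.hbr_white_uM > 0:
            hbr = hbr + nz.hbr_white_uM * rng.standard_normal((n_ch, n))

        od760, od850 = od_from_hemo(hbo, hbr, config.geometry)

        q = config.quality
        gain: dict[int, float] = {}
        cv: dict[int, dict[int, float]] = {}
        bad = rng.random(n_ch) < q.p_bad
        bad_kind = rng.random(n_ch) < 0.5  # True -> bad gain, False -> bad CV
        bad_wl = rng.integers(0, 2, size=n_ch)  # which wavelength carries the bad CV
        for c, ch in enumerate(config.channels):
            if bad[c] and bad_kind[c]:
                gain[ch] = float(rng.integers(q.gain_bad[0], q.gain_bad[1] + 1))
            else:
                gain[ch] = float(rng.integers(q.gain_good[0], q.gain_good[1] + 1))
            cv[ch] = {}
            for wi, wl in enumerate((760, 850)):
                if bad[c] and not bad_kind[c] and wi == bad_wl[c]:
                    cv[ch][wl] = float(rng.uniform(*q.cv_bad))
                else:
                    cv[ch][wl] = float(rng.uniform(*q.cv_good))

        od = {
            ch: {760: od760[c].copy(), 850: od850[c].copy()}
            for c, ch in enumerate(config.channels)
        }
        subjects.append(
            SubjectRecording(
                label=label,
                od=od,
                gain=gain,
                cv=cv,
                ras=_items_for_score(score, rng),
            )
        )

    schedule = make_schedule(sequence_label)
    return RawDyadRecording(
        dyad_id=dyad_id,
        sequence_label=sequence_label,
        sampling_rate=fs,
        subjects=(subjects[0], subjects[1]),
        video_onsets_s=schedule.video_onsets_s,
        sim_truth={
            "kappa": kappa,
            "delta_sat": float(delta_sat),
            "score_a": score_a,
            "score_b": score_b,
            "dyad_seed": int(dyad_seed),
        },
    )


def simulate_cohort(config: SimConfig) -> list[RawDyadRecording]:
    """Simulate ``config.n_dyads`` dyads.

    Satisfaction scores are drawn per subject (truncated Gaussians around
    the per-role means), sequence labels are assigned round-robin over
    A, B, C and then shuffled with a seeded permutation, and each dyad gets
    a seed derived reproducibly from the master seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1 << 20,)))
    n = config.n_dyads
    labels = [("A", "B", "C")[i % 3] for i in range(n)]
    labels = [labels[i] for i in rng.permutation(n)]
    recordings = []
    for i in range(n):
        score_a = float(np.clip(rng.normal(config.ras.mean_a, config.ras.between_sd), 1, 7))
        score_b = float(np.clip(rng.normal(config.ras.mean_b, config.ras.between_sd), 1, 7))
        recordings.append(
            simulate_dyad(
                config,
                delta_sat=abs(score_a - score_b),
                dyad_seed=dyad_seed_from_master(config.seed, i),
                sequence_label=labels[i],
                dyad_id=f"dyad{i:02d}",
                scores=(score_a, score_b),
            )
        )
    return recordings


def noise_free(config: SimConfig) -> SimConfig:
    """Copy of ``config`` with every stochastic signal component silenced."""
    return replace(
        config,
        noise=NoiseParams(
            cardiac_uM=0.0,
            respiratory_uM=0.0,
            lowfreq_uM=0.0,
            white_uM=0.0,
            drift_uM=0.0,
            hbr_white_uM=0.0,
        ),
        spikes=SpikeParams(rate_per_min=0.0),
        individual=IndividualParams(amp_jitter=0.0, wander_uM=0.0),
        coupling=replace(config.coupling, sigma=0.0),
    )
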