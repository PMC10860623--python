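"""Synthetic cohorts: sibling-structured phenotypes and two-channel MEG-like signals.

Every downstream stage (spectral parameterization, beta-event extraction,
heritability estimation) is exercised against this generator, whose ground
truth is known exactly.

Phenotypes
----------
A subject's phenotype is ``mean + g + e`` with additive genetic value ``g``
and residual ``e``. Full siblings share half their genes, so the genetic
values of sibs correlate at 0.5:

    g_i = sqrt(0.5) * a_family + sqrt(0.5) * a_i,   a ~ N(0, h2 * V_p)

giving var(g) = h2*V_p and cov(g_i, g_j) = 0.5*h2*V_p within a family.

Signals
-------
Each subject contributes a planar-gradiometer-like channel pair: an
aperiodic 1/f background (Gaussian noise spectrally shaped so its one-sided
PSD is 10^offset * f^(-chi)) plus a train of transient beta bursts —
Hanning-windowed sinusoids near 20 Hz with Poisson onsets — mixed into the
two channels with fixed orthogonal weights (cos theta, sin theta).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "PhenoGenConfig",
    "BurstDist",
    "SignalGenConfig",
    "simulate_phenotype",
    "simulate_sensor_pair",
    "simulate_cohort",
]


@dataclass(frozen=True)
class PhenoGenConfig:
    """Ground-truth generative parameters for one heritable phenotype."""

    h2_true: float = 0.5
    mean: float = 0.0
    total_variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError(f"h2_true must be in [0, 1], got {self.h2_true}")
        if self.total_variance <= 0:
            raise ValueError("total_variance must be positive")


def simulate_phenotype(ped: Pedigree, cfg: PhenoGenConfig,
                       rng: np.random.Generator | None = None) -> pd.Series:
    """Draw one phenotype per subject with sibling covariance 0.5*h2*V_p.

    Returns a Series indexed by subject id. Reproducible from ``cfg.seed``
    unless an explicit ``rng`` is passed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h2, vp = cfg.h2_true, cfg.total_variance
    sg = np.sqrt(h2 * vp)
    values = np.empty(ped.n_subjects)
    pos = 0
    for members in ped.families.values():
        m = len(members)
        a_fam = rng.normal(0.0, sg)
        a_ind = rng.normal(0.0, sg, size=m)
        g = np.sqrt(0.5) * a_fam + np.sqrt(0.5) * a_ind
        e = rng.normal(0.0, np.sqrt((1.0 - h2) * vp), size=m)
        values[pos:pos + m] = cfg.mean + g + e
        pos += m
    order = [s for members in ped.families.values() for s in members]
    return pd.Series(values, index=order, name="phenotype").reindex(ped.subjects)


@dataclass(frozen=True)
class BurstDist:
    """Named scalar distribution for burst amplitude or duration.

    ``lognormal`` is parameterized by its median and log-space sigma
    (right-skewed, mean > median); ``fixed`` always returns ``median``.
    """

    name: str = "lognormal"
    median: float = 1.0
    sigma: float = 0.4

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "lognormal":
            return self.median * np.exp(rng.normal(0.0, self.sigma, size=size))
        if self.name == "fixed":
            return np.full(size, self.median)
        raise ValueError(f"unknown distribution {self.name!r}")

    @property
    def mean(self) -> float:
        if self.name == "lognormal":
            return self.median * np.exp(self.sigma ** 2 / 2.0)
        return self.median


@dataclass(frozen=True)
class SignalGenConfig:
    """Generative parameters for one subject's two-channel recording.

    The aperiodic offset is log10 of PSD in (signal unit)^2/Hz; with
    signals in T/cm the study-like offset is around -23. Burst amplitudes
    default to roughly five times the in-band background envelope so that
    events stand out the way sensorimotor beta events do over the 1/f floor.
    """

    sampling_rate: float = 600.0
    duration: float = 180.0
    aperiodic_offset: float = -23.0
    aperiodic_exponent: float = 1.05
    beta_freq: float = 20.0
    burst_rate: float = 1.0
    burst_amp_dist: BurstDist = field(
        default_factory=lambda: BurstDist("lognormal", median=6e-12, sigma=0.4))
    burst_dur_dist: BurstDist = field(
        default_factory=lambda: BurstDist("lognormal", median=0.20, sigma=0.75))
    mixing_angle_deg: float = 45.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 47.0:
            raise ValueError("sampling_rate must exceed twice the 47 Hz analysis band")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be >= 0")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def _aperiodic_background(cfg: SignalGenConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise whose one-sided PSD is 10^offset * f^(-chi); DC zeroed."""
    n = cfg.n_samples
    fs = cfg.sampling_rate
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target = np.zeros_like(freqs)
    target[1:] = 10.0 ** cfg.aperiodic_offset * freqs[1:] ** (-cfg.aperiodic_exponent)
    # E|X_k|^2 = S(f_k) * fs * n / 2 makes the periodogram match the target PSD.
    scale = np.sqrt(target * fs * n / 2.0)
    z = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    z /= np.sqrt(2.0)
    spec = scale * z
    spec[0] = 0.0
    if n % 2 == 0:  # Nyquist bin must be real for a real signal
        spec[-1] = np.sqrt(target[-1] * fs * n / 2.0) * rng.normal()
    return np.fft.irfft(spec, n=n)


def _burst_train(cfg: SignalGenConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """Sum of Hanning-enveloped sinusoids with Poisson onsets.

    Returns the source waveform and a table of the drawn bursts
    (onset s, duration s, amplitude), overlaps summed linearly.
    """
    n = cfg.n_samples
    fs = cfg.sampling_rate
    out = np.zeros(n)
    n_bursts = rng.poisson(cfg.burst_rate * cfg.duration)
    cols = {"onset": np.empty(n_bursts), "duration": np.empty(n_bursts),
            "amplitude": np.empty(n_bursts)}
    if n_bursts == 0:
        return out, pd.DataFrame(cols)
    onsets = np.sort(rng.uniform(0.0, cfg.duration, size=n_bursts))
    durs = cfg.burst_dur_dist.sample(rng, n_bursts)
    amps = cfg.burst_amp_dist.sample(rng, n_bursts)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_bursts)
    for t0, dur, amp, phi in zip(onsets, durs, amps, phases):
        i0 = int(round(t0 * fs))
        m = min(max(int(round(dur * fs)), 2), n - i0)
        if m < 2:
            continue
        t = np.arange(m) / fs
        env = np.hanning(m)
        out[i0:i0 + m] += amp * env * np.cos(2.0 * np.pi * cfg.beta_freq * t + phi)
    return out, pd.DataFrame({"onset": onsets, "duration": durs, "amplitude": amps})


def simulate_sensor_pair(cfg: SignalGenConfig,
                         rng: np.random.Generator | None = None,
                         return_bursts: bool = False):
    """Two-channel recording, shape ``(2, n_samples)``.

    The burst source projects onto the channels with weights
    (cos theta, sin theta); each channel has its own independent aperiodic
    background. Bit-reproducible from ``cfg.noise_seed``. With
    ``return_bursts=True`` also returns the ground-truth burst table.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.noise_seed)
    theta = np.deg2rad(cfg.mixing_angle_deg)
    source, bursts = _burst_train(cfg, rng)
    ch1 = np.cos(theta) * source + _aperiodic_background(cfg, rng)
    ch2 = np.sin(theta) * source + _aperiodic_background(cfg, rng)
    signals = np.vstack([ch1, ch2])
    if return_bursts:
        return signals, bursts
    return signals


def _subject_rng(root_seed: int, subject_id: str, salt: str = "") -> np.random.Generator:
    """Independent, stable stream per subject: root seed + CRC32 of the id."""
    key = zlib.crc32(f"{subject_id}|{salt}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=root_seed,
                                                        spawn_key=(key,)))


#: Maps a subject's heritable phenotype values into its signal config.
Link = Callable[[SignalGenConfig, Mapping[str, float]], SignalGenConfig]


def identity_exponent_link(base: SignalGenConfig,
                           pheno: Mapping[str, float]) -> SignalGenConfig:
    """Default link: the heritable phenotype 'exponent' sets the 1/f slope."""
    return replace(base, aperiodic_exponent=float(pheno["exponent"]))


def simulate_cohort(
    ped: Pedigree,
    pheno_cfgs: Mapping[str, PhenoGenConfig],
    link: Link,
    base_cfg: SignalGenConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Signals plus ground truth for a whole sibling cohort.

    Each named phenotype in ``pheno_cfgs`` is drawn with its own family
    covariance; ``link`` folds a subject's phenotype values into its
    ``SignalGenConfig``. Returns ``(signals, truth)`` where ``signals`` maps
    subject id -> (2, n) array and ``truth`` is a subjects x parameters
    DataFrame holding the generating values.

    Raises ``ValueError`` naming the subject if the link yields an invalid
    configuration.
    """
    if base_cfg is None:
        base_cfg = SignalGenConfig()
    phenos = {
        name: simulate_phenotype(ped, cfg, rng=_subject_rng(seed, name, "pheno"))
        for name, cfg in pheno_cfgs.items()
    }
    signals: dict[str, np.ndarray] = {}
    rows = []
    for sid in ped.subjects:
        row = {name: float(vals.loc[sid]) for name, vals in phenos.items()}
        try:
            cfg = link(base_cfg, row)
        except Exception as exc:  # noqa: BLE001 - re-raise with subject context
            raise ValueError(f"link failed for subject {sid!r}: {exc}") from exc
        if not isinstance(cfg, SignalGenConfig):
            raise ValueError(f"link for subject {sid!r} did not return a SignalGenConfig")
        signals[sid] = simulate_sensor_pair(cfg, rng=_subject_rng(seed, sid, "signal"))
        truth_row = {"subject": sid, "family": ped.family_of[sid],
                     "aperiodic_offset": cfg.aperiodic_offset,
                     "aperiodic_exponent": cfg.aperiodic_exponent,
                     "beta_freq": cfg.beta_freq,
                     "burst_rate": cfg.burst_rate,
                     "burst_amp_median": cfg.burst_amp_dist.median,
                     "burst_dur_median": cfg.burst_dur_dist.median}
        truth_row.update({f"pheno_{k}": v for k, v in row.items()})
        rows.append(truth_row)
    truth = pd.DataFrame(rows).set_index("subject")
    return signals, truth
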