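"""Synthetic multichannel signals with known, planted coupling structure.

Every downstream stage (connectivity, thresholding, graph metrics,
group statistics) can be tested against ground truth without real data:

- *phase_lag* pairs share a band-limited carrier whose copy is rotated
  by a constant phase offset in the analytic domain, so the pair has a
  constant nonzero lag: PLI = 1 at zero noise, while leakage-style
  zero-lag mixing (lag 0) is invisible to PLI by construction.
- *envelope_share* pairs ride independent carriers modulated by slow
  envelopes built from a common and an independent component mixed so
  the envelope correlation equals a requested target.  Carriers are
  normalized to unit modulus so the planted slow envelope *is* what the
  Hilbert envelope measures; raw band-pass noise carriers would add
  Rayleigh-distributed intrinsic envelope fluctuations that attenuate
  the planted correlation.
- *none* pairs are independent band-limited noise (the null).

``gen_study`` assembles three groups of 19-channel recordings where a
per-(group, band) effect multiplier scales the number of planted
coupled pairs, emulating band-specific hyper-/hypo-connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from eegfc.errors import ConfigurationError
from eegfc.montage import MONTAGE_19
from eegfc.signal_prep import BANDS, BandDefinition, Recording

COUPLING_MODES = ("phase_lag", "envelope_share", "none")

#: PLI bands get phase-lag couplings, AEC-c bands envelope-share couplings.
PLI_BANDS = ("delta", "theta")

#: Relative amplitude of the slow-envelope modulation in envelope_share mode.
ENVELOPE_MOD_DEPTH = 0.4
ENVELOPE_FLOOR = 0.05


@dataclass(frozen=True)
class CouplingSpec:
    """Ground truth for one planted channel pair."""

    channel_pair: tuple[int, int]
    mode: str
    lag_radians: float = np.pi / 2
    envelope_corr: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in COUPLING_MODES:
            raise ConfigurationError(
                f"unknown coupling mode {self.mode!r}; expected one of {COUPLING_MODES}"
            )
        i, j = self.channel_pair
        if i == j or i < 0 or j < 0:
            raise ConfigurationError(f"channel pair must be two distinct indices, got {i, j}")
        if self.mode == "phase_lag":
            if self.lag_radians == 0.0:
                warnings.warn(
                    "phase_lag coupling with zero lag: planted coupling is a pure "
                    "zero-lag (volume-conduction-like) share, invisible to PLI",
                    stacklevel=2,
                )
            elif not 0 < self.lag_radians < np.pi:
                raise ConfigurationError(
                    f"lag_radians must lie in (0, pi), got {self.lag_radians}"
                )
        if self.mode == "envelope_share" and not 0 <= self.envelope_corr <= 1:
            raise ConfigurationError(f"envelope_corr must be in [0, 1], got {self.envelope_corr}")


@dataclass(frozen=True)
class SyntheticStudySpec:
    """A three-group study design with band-specific planted effects.

    ``band_effects`` maps ``(group_label, band_name)`` to a multiplier on
    the number of planted coupled pairs in that band (1.0 = baseline of
    ``base_pairs`` disjoint pairs; >1 denser, <1 sparser coupling).
    Defaults emulate the clinical recording setup: 19-channel 10-20
    montage at 500 Hz, 60 s per subject.
    """

    n_subjects_per_group: tuple[int, int, int] = (36, 23, 29)
    group_labels: tuple[str, str, str] = ("AD", "FTD", "HC")
    band_effects: dict = field(default_factory=dict)
    fs: float = 500.0
    duration_s: float = 60.0
    seed: int = 0
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")
    base_pairs: int = 4
    envelope_corr: float = 0.9
    epoch_length_s: float = 12.288

    def __post_init__(self) -> None:
        if len(self.n_subjects_per_group) != 3 or len(self.group_labels) != 3:
            raise ConfigurationError("exactly three groups required")
        if any(n <= 0 for n in self.n_subjects_per_group):
            raise ConfigurationError("every group needs at least one subject")
        high = max(BANDS[b].high for b in self.bands)
        if self.fs <= 2 * high:
            raise ConfigurationError(
                f"fs={self.fs} must exceed twice the highest band edge ({high} Hz)"
            )
        if self.duration_s < self.epoch_length_s:
            raise ConfigurationError(
                f"duration {self.duration_s} s shorter than one epoch ({self.epoch_length_s} s)"
            )


@dataclass
class SyntheticStudy:
    """Generated recordings plus the planted ground truth per subject."""

    recordings: list[Recording]
    ground_truth: dict[str, dict[str, list[CouplingSpec]]]  # subject -> band -> couplings
    spec: SyntheticStudySpec


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    sos = butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / max(x.std(), np.finfo(float).tiny)

def _unit_carrier(rng: np.random.Generator, n: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Constant-envelope carrier: phase of band-limited noise, unit modulus."""
    z = hilbert(_band_noise(rng, n, fs, band))
    return np.real(z / np.abs(z))


def _slow_envelope_parts(
    rng: np.random.Generator, n: int, fs: float, cutoff: float, k: int
) -> np.ndarray:
    """k independent standardized slow processes (low-pass noise below the band)."""
    sos = butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    out = sosfiltfilt(sos, rng.standard_normal((k, n)), axis=1)
    sd = out.std(axis=1, keepdims=True)
    return out / np.maximum(sd, np.finfo(float).tiny)


def _shared_envelopes(
    rng: np.random.Generator, n: int, fs: float, band: BandDefinition, corr: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two positive slow envelopes with Pearson correlation ~= corr.

    Each envelope mixes a common and an independent standardized slow
    process with weights sqrt(corr) and sqrt(1-corr); the mix is affinely
    shifted positive (correlation is affine-invariant; the rare clip at
    the floor perturbs it negligibly).
    """
    cutoff = min(1.0, band.low / 2)
    common, e1, e2 = _slow_envelope_parts(rng, n, fs, cutoff, 3)
    w = np.sqrt(corr)
    v = np.sqrt(1 - corr)
    env1 = np.clip(1.0 + ENVELOPE_MOD_DEPTH * (w * common + v * e1), ENVELOPE_FLOOR, None)
    env2 = np.clip(1.0 + ENVELOPE_MOD_DEPTH * (w * common + v * e2), ENVELOPE_FLOOR, None)
    return env1, env2


_DEFAULT_BAND = {"phase_lag": BANDS["theta"], "none": BANDS["theta"],
                 "envelope_share": BANDS["alpha"]}


def gen_coupled_pair(
    fs: float,
    duration_s: float,
    spec: CouplingSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    band: BandDefinition | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two equal-length signals realizing one planted coupling.

    ``noise_sd`` adds independent white noise (relative to the
    unit-variance planted component) to each channel.  Deterministic for
    a fixed seed.
    """
    n = int(round(duration_s * fs))
    if n < 2:
        raise ConfigurationError(f"duration {duration_s} s at fs={fs} gives < 2 samples")
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd}")
    band = band or _DEFAULT_BAND[spec.mode]
    rng = np.random.default_rng(seed)
    if spec.mode == "phase_lag":
        c = _band_noise(rng, n, fs, band)
        x = c
        if spec.lag_radians == 0.0:
            y = c.copy()  # exact zero-lag share: the volume-conduction null case
        else:
            y = np.real(hilbert(c) * np.exp(-1j * spec.lag_radians))
    elif spec.mode == "envelope_share":
        env1, env2 = _shared_envelopes(rng, n, fs, band, spec.envelope_corr)
        x = env1 * _unit_carrier(rng, n, fs, band)
        y = env2 * _unit_carrier(rng, n, fs, band)
    else:  # none
        x = _band_noise(rng, n, fs, band)
        y = _band_noise(rng, n, fs, band)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
        y = y + noise_sd * rng.standard_normal(n)
    return x, y


def _planted_pairs(rng: np.random.Generator, n_channels: int, k: int) -> list[tuple[int, int]]:
    """k disjoint channel pairs chosen uniformly (disjoint so couplings compose)."""
    perm = rng.permutation(n_channels)
    return [(int(perm[2 * i]), int(perm[2 * i + 1])) for i in range(k)]


def gen_study(spec: SyntheticStudySpec, pair_noise_sd: float = 0.2) -> SyntheticStudy:
    """Generate a full three-group study with planted band-specific effects.

    Per subject and band, ``round(base_pairs * effect)`` disjoint channel
    pairs (capped at floor(n_channels/2)) are planted — phase-lag
    couplings in the PLI bands (delta, theta), envelope-share couplings
    elsewhere; all remaining channels carry independent band-limited
    noise.  Band components are summed per channel.  Reproducible for a
    fixed ``spec.seed``.
    """
    n_ch = len(MONTAGE_19)
    max_pairs = n_ch // 2
    n_samples = int(round(spec.duration_s * spec.fs))
    root = np.random.SeedSequence(spec.seed)
    recordings: list[Recording] = []
    ground_truth: dict[str, dict[str, list[CouplingSpec]]] = {}
    subj_seeds = root.spawn(sum(spec.n_subjects_per_group))
    s_idx = 0
    for group, n_subj in zip(spec.group_labels, spec.n_subjects_per_group):
        for k_subj in range(n_subj):
            subject_id = f"{group}_{k_subj:03d}"
            rng = np.random.default_rng(subj_seeds[s_idx])
            s_idx += 1
            data = np.zeros((n_ch, n_samples))
            truth: dict[str, list[CouplingSpec]] = {}
            for band_name in spec.bands:
                band = BANDS[band_name]
                effect = float(spec.band_effects.get((group, band_name), 1.0))
                if effect < 0:
                    raise ConfigurationError(f"negative effect for {(group, band_name)}")
                k = min(max(int(round(spec.base_pairs * effect)), 0), max_pairs)
                pairs = _planted_pairs(rng, n_ch, k)
                comp = np.zeros((n_ch, n_samples))
                couplings: list[CouplingSpec] = []
                used: set[int] = set()
                for i, j in pairs:
                    if band_name in PLI_BANDS:
                        cs = CouplingSpec(
                            channel_pair=(i, j),
                            mode="phase_lag",
                            lag_radians=float(rng.uniform(0.35 * np.pi, 0.65 * np.pi)),
                        )
                    else:
                        cs = CouplingSpec(
                            channel_pair=(i, j),
                            mode="envelope_share",
                            envelope_corr=spec.envelope_corr,
                        )
                    x, y = gen_coupled_pair(
                        spec.fs,
                        spec.duration_s,
                        cs,
                        noise_sd=pair_noise_sd,
                        seed=int(rng.integers(2**31)),
                        band=band,
                    )
                    comp[i], comp[j] = x, y
                    used.update((i, j))
                    couplings.append(cs)
                for ch in range(n_ch):
                    if ch not in used:
                        comp[ch] = _band_noise(rng, n_samples, spec.fs, band)
                data += comp
                truth[band_name] = couplings
            recordings.append(
                Recording(
                    data=data,
                    fs=spec.fs,
                    channel_labels=MONTAGE_19,
                    subject_id=subject_id,
                    group=group,
                )
            )
            ground_truth[subject_id] = truth
    return SyntheticStudy(recordings=recordings, ground_truth=ground_truth, spec=spec)
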