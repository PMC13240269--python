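"""Synthetic two-group EEG with a planted band-limited phase-coupling effect.

The generator emulates the structure of a task-EEG case/control study:
two groups of subjects, each contributing many 2-s epochs of multichannel
oscillatory activity plus broadband noise.  The discriminative signal is
planted as theta-band phase coupling between designated channel pairs
(by default fronto-parietal): within each coupled pair the second channel
shares the first channel's oscillatory phase up to a von Mises-distributed
offset with group-specific concentration kappa.  Because the resultant
length of a von Mises variable is I1(kappa)/I0(kappa), the phase-locking
value of a coupled pair has a closed-form target
(:func:`expected_plv_von_mises`), which makes every downstream stage
testable against an analytic oracle.

The phase offset is held piecewise-constant over short blocks (default
0.1 s) rather than redrawn every sample: per-sample white jitter would be
averaged away by any band-pass filter whose memory exceeds a few samples,
erasing the planted group contrast from filtered data, while block-held
jitter keeps the sample-level von Mises law (each block is one i.i.d.
draw) and survives filtering.

Uncoupled channels carry independent oscillations whose frequency wanders
within the carrier band (redrawn every epoch-length block), so their
pairwise phase relation decorrelates and their PLV stays near the
independence floor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import special

from .errors import ConfigError, ParameterError
from .preprocess import BandSpec, Recording

__all__ = [
    "REGION_ORDER",
    "DEFAULT_CHANNELS",
    "SynthConfig",
    "Dataset",
    "region_for_channel",
    "default_channel_roles",
    "expected_plv_von_mises",
    "sample_coupled_phase_offsets",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

#: Canonical ordering of scalp regions, used for deterministic feature naming.
REGION_ORDER: tuple[str, ...] = ("frontal", "central", "parietal", "occipital", "temporal")

#: A 16-channel 10-20 subset standing in for a high-density montage.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T7", "T8", "Pz", "Fz",
)

_PREFIX_REGION = {"F": "frontal", "C": "central", "P": "parietal",
                  "O": "occipital", "T": "temporal"}


def region_for_channel(label: str) -> str:
    """Map a 10-20 channel label to its scalp region by name prefix.

    ``Fp*`` is frontal; otherwise the leading letter decides, which also
    covers the z-line (Fz frontal, Cz central, Pz parietal, Oz occipital).
    """
    if label[:2].lower() == "fp":
        return "frontal"
    region = _PREFIX_REGION.get(label[0].upper())
    if region is None:
        raise ConfigError(f"cannot infer region for channel {label!r}")
    return region


def default_channel_roles(labels: Sequence[str]) -> dict[str, str]:
    return {lab: region_for_channel(lab) for lab in labels}


def expected_plv_von_mises(kappa: float) -> float:
    """Closed-form PLV of a von Mises phase difference: I1(kappa)/I0(kappa).

    The phase-locking value of a pair whose phase difference is von Mises
    distributed with concentration kappa equals the mean resultant length
    of that distribution.  Uses exponentially scaled Bessel functions so
    the ratio stays finite for large kappa.
    """
    if not np.isfinite(kappa) or kappa < 0:
        raise ParameterError(f"kappa must be finite and >= 0, got {kappa}")
    return float(special.i1e(kappa) / special.i0e(kappa))


def sample_coupled_phase_offsets(
    kappa: float,
    n_samples: int,
    rng: np.random.Generator,
    hold: int = 1,
) -> np.ndarray:
    """Draw the phase-offset series planted between a coupled channel pair.

    Offsets are i.i.d. von Mises(0, kappa) draws, each held for ``hold``
    consecutive samples.  This is the exact series the generator injects, so
    its empirical resultant length converges to I1(kappa)/I0(kappa).
    """
    if kappa < 0:
        raise ParameterError(f"kappa must be >= 0, got {kappa}")
    if hold < 1:
        raise ParameterError(f"hold must be >= 1, got {hold}")
    n_blocks = -(-n_samples // hold)
    draws = rng.vonmises(0.0, kappa, size=n_blocks)
    return np.repeat(draws, hold)[:n_samples]


@dataclass
class SynthConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror a small case/control EEG study: 19 patients (P) vs 24
    controls (HC), ~500 two-second epochs per subject, theta-band (4-8 Hz)
    fronto-parietal coupling that is strong in controls (kappa=6) and weak
    in patients (kappa=1), i.e. reduced long-range theta synchronisation in
    the patient group.
    """

    n_subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"P": 19, "HC": 24}
    )
    n_epochs_per_subject: int = 500
    n_channels: int = 16
    fs: float = 250.0
    epoch_len_s: float = 2.0
    channel_labels: Sequence[str] = DEFAULT_CHANNELS
    channel_roles: Mapping[str, str] | None = None
    coupled_pairs: Sequence[tuple[str, str]] = (("F3", "P3"), ("F4", "P4"))
    kappa_group: Mapping[str, float] = field(
        default_factory=lambda: {"P": 1.0, "HC": 6.0}
    )
    background_pairs: Sequence[tuple[str, str]] = (
        ("Fp1", "Fp2"), ("C3", "C4"), ("O1", "O2"), ("T7", "T8"),
    )
    background_kappa: float = 20.0
    carrier_band: BandSpec = BandSpec("theta", 4.0, 8.0)
    osc_amplitude: float = 1.0
    noise_sd: float = 1.0
    one_over_f_exponent: float = 0.0
    jitter_hold_samples: int = 50
    freq_wander_s: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        labels = list(self.channel_labels)
        if self.n_channels != len(labels):
            if tuple(self.channel_labels) == DEFAULT_CHANNELS:
                # custom channel count with default labels: synthesise labels
                labels = [f"Ch{i:02d}" for i in range(self.n_channels)]
            else:
                raise ConfigError(
                    f"n_channels={self.n_channels} but {len(labels)} labels given"
                )
        self.channel_labels = labels
        if self.n_channels < 2:
            raise ConfigError("need at least 2 channels")
        for g, n in self.n_subjects_per_group.items():
            if n < 1:
                raise ConfigError(f"group {g!r}: need >= 1 subject, got {n}")
        if self.n_epochs_per_subject < 1:
            raise ConfigError("need >= 1 epoch per subject")
        spe = self.epoch_len_s * self.fs
        if abs(spe - round(spe)) > 1e-9 or round(spe) < 8:
            raise ConfigError(
                f"epoch_len_s*fs must be an integer >= 8, got {spe}"
            )
        for g, k in self.kappa_group.items():
            if not np.isfinite(k) or k < 0:
                raise ConfigError(f"group {g!r}: kappa must be finite >= 0, got {k}")
        if set(self.kappa_group) != set(self.n_subjects_per_group):
            raise ConfigError("kappa_group and n_subjects_per_group keys differ")
        slaved: set[str] = set()
        for a, b in list(self.coupled_pairs) + list(self.background_pairs):
            if a == b:
                raise ConfigError(f"self-pair ({a!r}, {a!r}) not allowed")
            for c in (a, b):
                if c not in self.channel_labels:
                    raise ConfigError(f"coupled pair references unknown channel {c!r}")
            if b in slaved:
                raise ConfigError(
                    f"channel {b!r} is the driven member of more than one pair"
                )
            slaved.add(b)
        if self.background_kappa < 0 or not np.isfinite(self.background_kappa):
            raise ConfigError("background_kappa must be finite >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.jitter_hold_samples < 1:
            raise ConfigError("jitter_hold_samples must be >= 1")
        if self.freq_wander_s * self.fs < 1:
            raise ConfigError("freq_wander_s must cover at least one sample")
        if self.channel_roles is None:
            self.channel_roles = default_channel_roles(self.channel_labels)

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_len_s * self.fs))

    @property
    def groups(self) -> list[str]:
        return list(self.n_subjects_per_group)


@dataclass
class Dataset:
    """A generated cohort plus the names of the planted features."""

    recordings: list[Recording]
    truth: list[str]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.recordings]
        if len(set(ids)) != len(ids):
            raise ConfigError("subject IDs must be unique")
        if self.recordings:
            ref = self.recordings[0]
            for r in self.recordings:
                if r.channel_labels != ref.channel_labels or r.fs != ref.fs:
                    raise ConfigError("all recordings must share channel set and fs")


def _wandering_phase(
    n: int,
    block: int,
    lo: float,
    hi: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integrated phase of an oscillation with band-limited frequency wander.

    The instantaneous frequency is redrawn uniformly inside the band every
    ``block`` samples, so two independent channels drift apart within a
    single epoch and their phase-locking stays near the independence floor.
    """
    n_blocks = -(-n // block)
    # keep the instantaneous frequency safely inside the band
    margin = 0.1 * (hi - lo)
    freqs = rng.uniform(lo + margin, hi - margin, size=n_blocks)
    f_t = np.repeat(freqs, block)[:n]
    return 2.0 * np.pi * np.cumsum(f_t) / fs + rng.uniform(0, 2 * np.pi)


def _broadband_noise(
    shape: tuple[int, int], sd: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    if exponent == 0:
        return sd * white
    # shape the spectrum as 1/f^exponent, then renormalise to the target sd
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0)
    gain = np.ones_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    gain[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=n, axis=-1)
    shaped *= sd / shaped.std(axis=-1, keepdims=True)
    return shaped


def generate_dataset(cfg: SynthConfig) -> Dataset:
    """Simulate the cohort described by ``cfg``; deterministic given its seed.

    Returns the recordings plus ``truth``: the feature-table column names in
    which the group difference is planted (empty when kappa is identical
    across groups or no pairs are coupled).
    """
    spe = cfg.samples_per_epoch
    n_samples = cfg.n_epochs_per_subject * spe
    labels = list(cfg.channel_labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    band = cfg.carrier_band

    total = sum(cfg.n_subjects_per_group.values())
    seeds = iter(np.random.SeedSequence(cfg.seed).spawn(total))

    recordings: list[Recording] = []
    for group in cfg.groups:
        kappa = float(cfg.kappa_group[group])
        n_subj = cfg.n_subjects_per_group[group]
        for s in range(n_subj):
            rng = np.random.default_rng(next(seeds))
            block = max(1, int(round(cfg.freq_wander_s * cfg.fs)))
            theta = np.empty((cfg.n_channels, n_samples))
            for ch in range(cfg.n_channels):
                theta[ch] = _wandering_phase(
                    n_samples, block, band.lo, band.hi, cfg.fs, rng
                )
            # group-invariant background coupling (volume conduction /
            # homologous-pair synchrony): same concentration in every group
            for a, b in cfg.background_pairs:
                delta = sample_coupled_phase_offsets(
                    cfg.background_kappa, n_samples, rng,
                    hold=cfg.jitter_hold_samples,
                )
                theta[idx[b]] = theta[idx[a]] + delta
            for a, b in cfg.coupled_pairs:
                delta = sample_coupled_phase_offsets(
                    kappa, n_samples, rng, hold=cfg.jitter_hold_samples
                )
                theta[idx[b]] = theta[idx[a]] + delta
            data = cfg.osc_amplitude * np.cos(theta)
            data += _broadband_noise(
                data.shape, cfg.noise_sd, cfg.one_over_f_exponent, rng
            )
            recordings.append(
                Recording(
                    subject_id=f"{group}{s + 1:02d}",
                    group=group,
                    fs=cfg.fs,
                    channel_labels=labels,
                    data=data,
                )
            )

    truth = _planted_feature_names(cfg)
    return Dataset(recordings=recordings, truth=truth)


def _planted_feature_names(cfg: SynthConfig) -> list[str]:
    kappas = set(float(k) for k in cfg.kappa_group.values())
    if len(kappas) <= 1 or not cfg.coupled_pairs:
        return []
    roles = dict(cfg.channel_roles)
    names: list[str] = []
    order = {r: i for i, r in enumerate(REGION_ORDER)}
    for a, b in cfg.coupled_pairs:
        ra, rb = roles[a], roles[b]
        r1, r2 = sorted((ra, rb), key=lambda r: order.get(r, len(order)))
        for measure in ("plv", "coh"):
            name = f"{measure}_{cfg.carrier_band.name}_{r1}-{r2}"
            if name not in names:
                names.append(name)
    return names


# ---------------------------------------------------------------------------
# On-disk fixture format: one TSV per subject with a '#'-prefixed header
# (subject, group, fs, channel labels) followed by a channels x samples
# numeric matrix.
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, directory: str | Path, fmt: str = "%.8g") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in dataset.recordings:
        path = directory / f"{rec.subject_id}.tsv"
        with io.open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# subject\t{rec.subject_id}\n")
            fh.write(f"# group\t{rec.group}\n")
            fh.write(f"# fs\t{rec.fs:.10g}\n")
            fh.write("# channels\t" + "\t".join(rec.channel_labels) + "\n")
            np.savetxt(fh, rec.data, fmt=fmt, delimiter="\t")
    (directory / "truth.txt").write_text("\n".join(dataset.truth) + "\n")
    return directory


def read_dataset(directory: str | Path) -> Dataset:
    directory = Path(directory)
    recordings = []
    for path in sorted(directory.glob("*.tsv")):
        header: dict[str, str] = {}
        with io.open(path, "r", encoding="utf-8") as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                pos = fh.tell()
                key, _, value = line[1:].strip().partition("\t")
                header[key.strip()] = value
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        recordings.append(
            Recording(
                subject_id=header["subject"],
                group=header["group"],
                fs=float(header["fs"]),
                channel_labels=header["channels"].split("\t"),
                data=data,
            )
        )
    truth_file = directory / "truth.txt"
    truth = (
        [l for l in truth_file.read_text().splitlines() if l]
        if truth_file.exists()
        else []
    )
    return Dataset(recordings=recordings, truth=truth)
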