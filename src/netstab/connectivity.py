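"""Per-epoch phase-locking and coherence connectivity matrices.

Two complementary coupling measures are computed channel-pair-wise:

* **Phase-locking value (PLV)** — the magnitude of the time-averaged unit
  phasor of the instantaneous phase difference,
  ``PLV_ij = |mean_t exp(i(phi_i(t) - phi_j(t)))|``.  Phase is extracted
  from band-limited signals via the analytic signal (Hilbert transform);
  a fraction of samples at each epoch edge is discarded to suppress
  filter/Hilbert transients.

* **Magnitude-squared coherence** — ``|S_ij(f)|^2 / (S_ii(f) S_jj(f))``
  from Welch cross-spectral densities (1-s Hann segments, 50% overlap
  inside each 2-s epoch), averaged over the in-band frequency bins.  The
  cross-spectral matrix over *all* channel pairs is computed in one
  vectorised pass; on a single pair it matches ``scipy.signal.coherence``
  with the same settings.

Both measures live in [0, 1], are symmetric with unit diagonal, and are
averaged across a subject's epochs to give subject-level connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DataError, ParameterError
from .preprocess import BandSpec

__all__ = [
    "ConnectivityMatrix",
    "instantaneous_phase",
    "plv_matrix",
    "plv_matrices",
    "csd_welch",
    "coherence_matrix",
    "band_coherence_matrices",
    "average_connectivity",
    "connectivity_to_tsv",
    "connectivity_from_tsv",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel coupling matrix for one subject and band."""

    subject_id: str
    band: str
    measure: str  # "plv" | "coh"
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise DataError("connectivity matrix must be symmetric")
        if v.min() < -1e-10 or v.max() > 1 + 1e-10:
            raise DataError("connectivity values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise DataError("diagonal must be 1 (self-coupling)")
        self.values = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 1.0)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Analytic-signal phase of band-limited data, wrapped to (-pi, pi].

    Works on any (..., samples) array; the Hilbert transform is taken along
    the last axis.  All-zero channels have undefined phase and are flagged
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.all(x == 0.0, axis=-1)):
        warnings.warn(
            "all-zero signal: instantaneous phase undefined", RuntimeWarning
        )
    return np.angle(signal.hilbert(x, axis=-1))


def plv_matrix(phases: np.ndarray, min_samples: int = 8) -> np.ndarray:
    """Pairwise phase-locking values from a channels x samples phase array."""
    out = plv_matrices(phases[None, ...], min_samples=min_samples)
    return out[0]


def plv_matrices(phases: np.ndarray, min_samples: int = 8) -> np.ndarray:
    """Vectorised PLV over a stack of epochs: (epochs, channels, samples)."""
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 3:
        raise DataError("expected (epochs, channels, samples)")
    t = phases.shape[-1]
    if t < min_samples:
        raise DataError(f"need >= {min_samples} samples for a PLV estimate, got {t}")
    z = np.exp(1j * phases)
    # PLV_ij = |(1/T) sum_t z_i z_j*|
    c = np.einsum("eit,ejt->eij", z, z.conj()) / t
    plv = np.abs(c)
    plv = np.clip(plv, 0.0, 1.0)
    idx = np.arange(phases.shape[1])
    plv[:, idx, idx] = 1.0
    return plv


def _welch_params(fs: float, t: int, nperseg: int | None, noverlap: int | None):
    if nperseg is None:
        nperseg = min(int(round(fs)), t)  # 1-s segments by default
    if noverlap is None:
        noverlap = nperseg // 2
    if noverlap >= nperseg:
        raise ParameterError("noverlap must be < nperseg")
    step = nperseg - noverlap
    n_seg = 1 + (t - nperseg) // step if t >= nperseg else 0
    if n_seg < 2:
        raise DataError(
            f"epoch of {t} samples yields {n_seg} Welch segment(s); need >= 2"
        )
    return nperseg, noverlap, step, n_seg


def csd_welch(
    x: np.ndarray,
    fs: float,
    nperseg: int | None = None,
    noverlap: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch cross-spectral density matrix for all channel pairs at once.

    ``x`` is (..., channels, samples); returns (freqs, S) with S of shape
    (..., channels, channels, n_freqs).  Hann window, constant detrend per
    segment — the same conventions as ``scipy.signal.csd`` defaults.
    """
    x = np.asarray(x, dtype=float)
    t = x.shape[-1]
    nperseg, noverlap, step, n_seg = _welch_params(fs, t, nperseg, noverlap)
    win = signal.get_window("hann", nperseg)
    scale = 1.0 / (fs * (win * win).sum())
    starts = np.arange(n_seg) * step
    # (..., ch, n_seg, nperseg)
    segs = np.stack([x[..., s : s + nperseg] for s in starts], axis=-2)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(segs * win, axis=-1)
    # S_ij(f) = <X_i(f) X_j(f)*>, one-sided scaling as in scipy
    s = np.einsum("...isf,...jsf->...ijf", spec, spec.conj()) / n_seg
    s *= scale
    nf = spec.shape[-1]
    one_sided = np.ones(nf)
    one_sided[1:] = 2.0
    if nperseg % 2 == 0:
        one_sided[-1] = 1.0
    s *= one_sided
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, s


def _band_mean_coherence(
    freqs: np.ndarray, s: np.ndarray, band: BandSpec
) -> np.ndarray:
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not mask.any():
        raise ParameterError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) has no resolvable bins"
        )
    sb = s[..., mask]
    auto = np.real(np.einsum("...iif->...if", sb))
    denom = auto[..., :, None, :] * auto[..., None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sb) ** 2 / denom
    coh = np.nan_to_num(coh, nan=0.0, posinf=0.0)
    out = coh.mean(axis=-1)
    out = np.clip((out + np.swapaxes(out, -1, -2)) / 2.0, 0.0, 1.0)
    idx = np.arange(out.shape[-1])
    out[..., idx, idx] = 1.0
    return out


def coherence_matrix(
    epoch_signal: np.ndarray,
    band: BandSpec,
    fs: float,
    nperseg: int | None = None,
    noverlap: int | None = None,
) -> np.ndarray:
    """Band-averaged magnitude-squared coherence between all channel pairs."""
    epoch_signal = np.asarray(epoch_signal, dtype=float)
    if epoch_signal.ndim != 2:
        raise DataError("expected (channels, samples)")
    freqs, s = csd_welch(epoch_signal, fs, nperseg, noverlap)
    return _band_mean_coherence(freqs, s, band)


def band_coherence_matrices(
    epochs: np.ndarray,
    bands: Sequence[BandSpec],
    fs: float,
    nperseg: int | None = None,
    noverlap: int | None = None,
) -> dict[str, np.ndarray]:
    """Coherence per epoch for several bands from one shared CSD pass.

    ``epochs`` is (epochs, channels, samples); returns band name ->
    (epochs, channels, channels).
    """
    freqs, s = csd_welch(np.asarray(epochs, dtype=float), fs, nperseg, noverlap)
    return {b.name: _band_mean_coherence(freqs, s, b) for b in bands}


def average_connectivity(
    per_epoch: Sequence[np.ndarray] | np.ndarray,
    subject_id: str = "",
    band: str = "",
    measure: str = "",
) -> ConnectivityMatrix:
    """Element-wise mean of per-epoch matrices -> subject-level connectivity."""
    arr = np.asarray(per_epoch, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise DataError("need at least one epoch matrix of consistent shape")
    return ConnectivityMatrix(subject_id, band, measure, arr.mean(axis=0))


def connectivity_to_tsv(
    cm: ConnectivityMatrix, channel_labels: Sequence[str], path: str | Path
) -> None:
    df = pd.DataFrame(cm.values, index=list(channel_labels), columns=list(channel_labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def connectivity_from_tsv(
    path: str | Path, subject_id: str = "", band: str = "", measure: str = ""
) -> tuple[ConnectivityMatrix, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return (
        ConnectivityMatrix(subject_id, band, measure, df.to_numpy()),
        [str(c) for c in df.columns],
    )
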