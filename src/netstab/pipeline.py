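"""End-to-end pipeline: configuration, orchestration and run artifacts.

A run executes the stages in order — acquire (simulate or load), filter,
re-reference, epoch, band-decompose, connectivity (PLV + coherence),
subject-level averaging, graph features, stability-selected nested CV —
and writes a self-contained run directory:

    config.yaml            resolved configuration snapshot
    connectivity/          per-subject, per-band/measure TSV matrices
    features.tsv           the feature table (subject_id, label, columns)
    stability_ranking.tsv  cross-fold feature ranking (mu, sigma, score)
    shap_summary.tsv       per-fold mean |Shapley value| per selected feature
    metrics.json           per-fold and pooled metrics with bootstrap CIs
    metrics.txt            aligned human-readable metrics table
    run.log                per-fold hyperparameters and selected features
    run_complete.json      written last; marks the run as valid

Every output file is written atomically (temp file + rename), and the
completion marker is only written after all stages succeed, so a crashed
run never leaves tables that look valid.  Identical config + seed gives
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from . import connectivity as conn
from . import preprocess as pre
from .errors import ConfigError
from .modeling import CVConfig, NestedCVResult, nested_cv
from .network import FeatureTable, build_feature_table
from .preprocess import BandSpec, DEFAULT_BANDS, Recording
from .synthetic import Dataset, SynthConfig, generate_dataset, read_dataset

__all__ = ["PipelineConfig", "run_pipeline", "extract_connectivity", "preprocess_recording"]

logger = logging.getLogger("netstab")


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    source: str = "simulate"  # "simulate" or a fixture directory path
    synth: SynthConfig = field(default_factory=SynthConfig)
    bands: Sequence[BandSpec] = DEFAULT_BANDS
    measures: Sequence[str] = ("plv", "coh")
    bandpass: tuple[float, float] = (1.0, 40.0)
    notch_hz: float | None = 50.0
    epoch_len_s: float = 2.0
    edge_trim: float = 0.1  # fraction of samples dropped per epoch edge for PLV
    threshold_p: float | None = None
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigError("at least one analysis band is required")
        bands = sorted(self.bands, key=lambda b: b.lo)
        for a, b in zip(bands, bands[1:]):
            if b.lo < a.hi:
                raise ConfigError(
                    f"overlapping band edges: {a.name} ends at {a.hi} Hz but "
                    f"{b.name} starts at {b.lo} Hz"
                )
        lo, hi = self.bandpass
        if not (0 < lo < hi):
            raise ConfigError(f"invalid bandpass ({lo}, {hi})")
        for m in self.measures:
            if m not in ("plv", "coh"):
                raise ConfigError(f"unknown connectivity measure {m!r}")
        if not (0 <= self.edge_trim < 0.5):
            raise ConfigError("edge_trim must be in [0, 0.5)")
        if self.source != "simulate" and not Path(self.source).is_dir():
            raise ConfigError(f"input directory not found: {self.source!r}")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        def unpack(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [unpack(v) for v in obj]
            if isinstance(obj, Mapping):
                return {k: unpack(v) for k, v in obj.items()}
            return obj
        d = {f.name: unpack(getattr(self, f.name)) for f in dataclasses.fields(self)}
        d["bands"] = [[b.name, b.lo, b.hi] for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        def as_band(b):
            if isinstance(b, BandSpec):
                return b
            if isinstance(b, Mapping):
                return BandSpec(**b)
            return BandSpec(*b)

        kwargs = dict(raw)
        if "bands" in kwargs:
            kwargs["bands"] = [as_band(b) for b in kwargs["bands"]]
        if "synth" in kwargs and isinstance(kwargs["synth"], Mapping):
            synth = dict(kwargs["synth"])
            if "carrier_band" in synth:
                synth["carrier_band"] = as_band(synth["carrier_band"])
            if "coupled_pairs" in synth:
                synth["coupled_pairs"] = [tuple(p) for p in synth["coupled_pairs"]]
            kwargs["synth"] = SynthConfig(**synth)
        if "cv" in kwargs and isinstance(kwargs["cv"], Mapping):
            kwargs["cv"] = CVConfig(**kwargs["cv"])
        if "bandpass" in kwargs:
            kwargs["bandpass"] = tuple(kwargs["bandpass"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls.from_dict(raw)


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    """Write via a temp file in the same directory, then rename into place."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    tmp = Path(tmp)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def preprocess_recording(
    rec: Recording, cfg: PipelineConfig
) -> tuple[pre.EpochArray, dict[str, pre.EpochArray]]:
    """Broadband cleaning + band decomposition, epoched.

    Returns the broadband epochs (for coherence) and one epoch array per
    analysis band (for phase extraction).  Band filtering happens on the
    continuous signal before epoching, confining transients to the
    recording edges.
    """
    lo, hi = cfg.bandpass
    rec = pre.bandpass_filter(rec, lo, hi)
    if cfg.notch_hz is not None and cfg.notch_hz < rec.fs / 2:
        rec = pre.notch_filter(rec, cfg.notch_hz)
    rec = pre.ica_hook(rec)
    rec = pre.rereference_average(rec)
    broadband = pre.epoch(rec, cfg.epoch_len_s)
    per_band = {
        name: pre.epoch(band_rec, cfg.epoch_len_s)
        for name, band_rec in pre.band_decompose_recording(rec, cfg.bands).items()
    }
    return broadband, per_band


def extract_connectivity(
    recordings: Sequence[Recording], cfg: PipelineConfig
) -> dict[str, dict[tuple[str, str], conn.ConnectivityMatrix]]:
    """Subject-level PLV and coherence matrices for every band."""
    out: dict[str, dict[tuple[str, str], conn.ConnectivityMatrix]] = {}
    for rec in recordings:
        broadband, per_band = preprocess_recording(rec, cfg)
        per_subject: dict[tuple[str, str], conn.ConnectivityMatrix] = {}
        if "plv" in cfg.measures:
            for band_name, ep in per_band.items():
                phases = conn.instantaneous_phase(ep.epochs)
                trim = int(round(cfg.edge_trim * phases.shape[-1]))
                if trim:
                    phases = phases[..., trim:-trim]
                mats = conn.plv_matrices(phases)
                per_subject[("plv", band_name)] = conn.average_connectivity(
                    mats, rec.subject_id, band_name, "plv"
                )
        if "coh" in cfg.measures:
            by_band = conn.band_coherence_matrices(
                broadband.epochs, list(cfg.bands), rec.fs
            )
            for band_name, mats in by_band.items():
                per_subject[("coh", band_name)] = conn.average_connectivity(
                    mats, rec.subject_id, band_name, "coh"
                )
        out[rec.subject_id] = per_subject
        logger.debug("connectivity done for %s (%d epochs)", rec.subject_id,
                     broadband.n_epochs)
    return out


def _load_recordings(cfg: PipelineConfig) -> Dataset:
    if cfg.source == "simulate":
        synth = dataclasses.replace(cfg.synth, seed=cfg.seed)
        return generate_dataset(synth)
    return read_dataset(cfg.source)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write the run directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    try:
        _atomic_write(
            out / "config.yaml",
            lambda p: p.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False)),
        )
        dataset = _load_recordings(cfg)
        logger.info(
            "dataset: %d recordings, truth=%s", len(dataset.recordings), dataset.truth
        )

        connectivity = extract_connectivity(dataset.recordings, cfg)
        ref = dataset.recordings[0]
        conn_dir = out / "connectivity"
        for sid, mats in connectivity.items():
            for (measure, band), cm in mats.items():
                _atomic_write(
                    conn_dir / f"{sid}_{measure}_{band}.tsv",
                    lambda p, cm=cm: conn.connectivity_to_tsv(
                        cm, ref.channel_labels, p
                    ),
                )

        labels = {r.subject_id: r.group for r in dataset.recordings}
        table = build_feature_table(
            connectivity,
            labels,
            ref.channel_labels,
            dict(cfg.synth.channel_roles)
            if cfg.source == "simulate"
            else {c: r for c, r in _roles_for(ref.channel_labels).items()},
            measures=cfg.measures,
            bands=[b.name for b in cfg.bands],
            threshold_p=cfg.threshold_p,
        )
        _atomic_write(out / "features.tsv", table.to_tsv)

        cv = dataclasses.replace(cfg.cv, seed=cfg.seed)
        result = nested_cv(table, cv, truth_hint=dataset.truth)
        _atomic_write(out / "stability_ranking.tsv", result.ranking.to_tsv)
        _atomic_write(
            out / "metrics.json", lambda p: Path(p).write_text(result.metrics.to_json())
        )
        _atomic_write(
            out / "metrics.txt",
            lambda p: Path(p).write_text(result.metrics.to_text(cv.model) + "\n"),
        )
        if result.shap_summary is not None:
            _atomic_write(
                out / "shap_summary.tsv",
                lambda p: result.shap_summary.to_csv(
                    p, sep="\t", index=False, float_format="%.6g"
                ),
            )
        _atomic_write(
            out / "run_complete.json",
            lambda p: Path(p).write_text(
                json.dumps({"seed": cfg.seed, "n_subjects": len(labels),
                            "truth": dataset.truth})
            ),
        )
        logger.info("run complete: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _roles_for(channel_labels: Sequence[str]) -> dict[str, str]:
    from .synthetic import default_channel_roles

    return default_channel_roles(channel_labels)
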