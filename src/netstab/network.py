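"""Graph-theoretic features of weighted connectivity networks.

Each subject/band/measure connectivity matrix is treated as a weighted
undirected graph on the channels (edge weight = coupling strength in
[0, 1], zero diagonal).  Graphs are kept fully weighted by default — no
proportional thresholding — since a retention fraction would be an extra
free parameter; thresholding is available behind ``threshold_p``.

Metrics follow the standard weighted-network definitions:

* strength (weighted degree)        s_i   = sum_j w_ij
* clustering coefficient (Onnela)   C_i   = (1/(k_i(k_i-1))) *
                                            sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3),
                                            w' = w / max(w)
* shortest paths use edge length 1/w (stronger coupling = shorter path)
* global efficiency                 E     = mean over i!=j of 1/d_ij
                                            (unreachable pairs contribute 0)
* characteristic path length        L     = mean over i!=j of d_ij

The feature table condenses these into one row per subject: region-pair
mean connectivity for every unordered region pair (e.g. mean theta PLV
over all frontal x parietal channel pairs), plus per-band/measure global
efficiency, characteristic path length, network-mean clustering and
network-mean strength.  Column names follow ``<measure>_<band>_<descriptor>``
(e.g. ``plv_theta_frontal-parietal``, ``coh_alpha_geff``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectivity import ConnectivityMatrix
from .errors import DataError, GraphDisconnectedError, ParameterError
from .synthetic import REGION_ORDER

__all__ = [
    "WeightedGraph",
    "FeatureTable",
    "to_graph",
    "strength_centrality",
    "clustering_coefficient",
    "global_efficiency",
    "characteristic_path_length",
    "build_feature_table",
    "SUMMARY_METRICS",
]

#: Descriptor names of the per-graph summary metrics, in emission order.
SUMMARY_METRICS: tuple[str, ...] = ("geff", "cpl", "clust", "strength")


@dataclass
class WeightedGraph:
    """Undirected weighted graph: symmetric weights, zero diagonal."""

    nodes: list[str]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DataError("weight matrix must be square")
        if len(self.nodes) != w.shape[0]:
            raise DataError("node count must match weight matrix size")
        if not np.allclose(w, w.T, atol=1e-10):
            raise DataError("weight matrix must be symmetric")
        if w.min() < 0:
            raise DataError("weights must be non-negative")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return len(self.nodes)


def to_graph(
    cm: ConnectivityMatrix | np.ndarray,
    nodes: Sequence[str] | None = None,
    threshold_p: float | None = None,
) -> WeightedGraph:
    """Turn a connectivity matrix into a weighted graph (diagonal zeroed).

    With ``threshold_p`` in (0, 1], only the strongest ``round(p * m)`` of
    the m off-diagonal edges are retained.  Ties at the cutoff are resolved
    deterministically by ascending (row, column) index order: among
    equal-weight edges the one appearing earlier in the upper triangle is
    kept first.
    """
    if isinstance(cm, ConnectivityMatrix):
        values = cm.values
    else:
        values = np.asarray(cm, dtype=float)
        if not np.allclose(values, values.T, atol=1e-10):
            raise DataError("connectivity input must be symmetric")
    n = values.shape[0]
    if nodes is None:
        nodes = [f"n{i}" for i in range(n)]
    w = values.copy()
    np.fill_diagonal(w, 0.0)
    if threshold_p is not None:
        if not (0 < threshold_p <= 1):
            raise ParameterError(f"threshold_p must be in (0, 1], got {threshold_p}")
        iu, ju = np.triu_indices(n, k=1)
        m = len(iu)
        keep = int(round(threshold_p * m))
        # stable sort on (-weight, i, j): equal weights keep earlier edges
        order = np.lexsort((ju, iu, -w[iu, ju]))
        kept = order[:keep]
        mask = np.zeros((n, n), dtype=bool)
        mask[iu[kept], ju[kept]] = True
        mask |= mask.T
        w = np.where(mask, w, 0.0)
    return WeightedGraph(list(nodes), w)


def strength_centrality(g: WeightedGraph) -> np.ndarray:
    """Weighted degree of each node: row sums of the weight matrix."""
    return g.weights.sum(axis=1)


def clustering_coefficient(g: WeightedGraph) -> np.ndarray:
    """Onnela weighted clustering coefficient per node, in [0, 1].

    Weights are normalised by the network maximum; nodes with fewer than
    two neighbours have coefficient 0 by convention.  On a binary graph this
    reduces to the fraction of closed triangles.
    """
    w = g.weights
    wmax = w.max()
    if wmax == 0:
        return np.zeros(g.n)
    w_hat = np.cbrt(w / wmax)
    tri = np.einsum("ij,jh,hi->i", w_hat, w_hat, w_hat)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
    return np.clip(c, 0.0, 1.0)


def _distance_matrix(g: WeightedGraph) -> np.ndarray:
    # edge length = 1/weight; csgraph treats zeros in a dense matrix as absent
    with np.errstate(divide="ignore"):
        lengths = np.where(g.weights > 0, 1.0 / g.weights, 0.0)
    return shortest_path(lengths, method="auto", directed=False)


def global_efficiency(g: WeightedGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Unreachable pairs contribute zero; with weights <= 1 the value lies in
    [0, 1] (1 for a complete unit-weight graph).
    """
    if g.n < 2:
        raise DataError("global efficiency needs >= 2 nodes")
    d = _distance_matrix(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (g.n * (g.n - 1)))


def characteristic_path_length(
    g: WeightedGraph, on_disconnected: str = "raise"
) -> float:
    """Mean shortest-path length over ordered node pairs (lengths 1/w).

    Undefined on a disconnected graph; pass ``on_disconnected="largest"``
    to compute the value on the largest connected component instead (a
    warning flags the fallback).
    """
    if g.n < 2:
        raise DataError("characteristic path length needs >= 2 nodes")
    d = _distance_matrix(g)
    off = ~np.eye(g.n, dtype=bool)
    if np.isinf(d[off]).any():
        if on_disconnected == "largest":
            n_comp, labels = connected_components(
                (g.weights > 0).astype(int), directed=False
            )
            sizes = np.bincount(labels)
            keep = labels == sizes.argmax()
            if keep.sum() < 2:
                raise GraphDisconnectedError(
                    "largest component has < 2 nodes; path length undefined"
                )
            warnings.warn(
                "graph disconnected: characteristic path length computed on "
                f"largest component ({keep.sum()}/{g.n} nodes)",
                RuntimeWarning,
            )
            sub = WeightedGraph(
                [n for n, k in zip(g.nodes, keep) if k],
                g.weights[np.ix_(keep, keep)],
            )
            return characteristic_path_length(sub, on_disconnected="raise")
        raise GraphDisconnectedError(
            "graph is disconnected; characteristic path length is undefined "
            "(re-run with on_disconnected='largest' to use the largest "
            "connected component, flagged in output)"
        )
    return float(d[off].mean())


@dataclass
class FeatureTable:
    """Named feature columns per observation, plus labels and subject IDs.

    ``features`` rows are observations (one per subject, or one per epoch
    when epoch-level granularity is requested); ``subjects`` gives the
    subject ID of each row and ``labels`` its group label.
    """

    features: pd.DataFrame
    labels: pd.Series
    subjects: pd.Series

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise DataError("feature table contains missing values")
        if self.features.columns.duplicated().any():
            raise DataError("feature column names must be unique")
        if not (len(self.features) == len(self.labels) == len(self.subjects)):
            raise DataError("features, labels, subjects must align row-wise")

    @property
    def n_rows(self) -> int:
        return len(self.features)

    def subject_level(self) -> bool:
        return self.subjects.is_unique

    def to_tsv(self, path: str | Path) -> None:
        df = self.features.copy()
        df.insert(0, "label", self.labels.to_numpy())
        df.insert(0, "subject_id", self.subjects.to_numpy())
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        if "label" not in df.columns or "subject_id" not in df.columns:
            raise DataError("feature TSV must carry 'subject_id' and 'label' columns")
        subjects = df.pop("subject_id").astype(str)
        labels = df.pop("label").astype(str)
        return cls(features=df.astype(float), labels=labels, subjects=subjects)


def _region_channel_indices(
    channel_labels: Sequence[str], region_map: Mapping[str, str]
) -> dict[str, np.ndarray]:
    regions: dict[str, list[int]] = {}
    for i, lab in enumerate(channel_labels):
        if lab not in region_map:
            raise DataError(f"channel {lab!r} missing from region map")
        regions.setdefault(region_map[lab], []).append(i)
    for r, idxs in regions.items():
        if len(idxs) == 0:
            raise DataError(f"region {r!r} has no channels")
    order = {r: i for i, r in enumerate(REGION_ORDER)}
    ordered = sorted(regions, key=lambda r: (order.get(r, len(order)), r))
    return {r: np.asarray(regions[r]) for r in ordered}


def _region_pair_mean(values: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float | None:
    if ia is ib or np.array_equal(ia, ib):
        if len(ia) < 2:
            return None  # a single-channel region has no within-region pairs
        sub = values[np.ix_(ia, ia)]
        iu, ju = np.triu_indices(len(ia), k=1)
        return float(sub[iu, ju].mean())
    return float(values[np.ix_(ia, ib)].mean())


def build_feature_table(
    connectivity: Mapping[str, Mapping[tuple[str, str], ConnectivityMatrix]],
    labels: Mapping[str, str],
    channel_labels: Sequence[str],
    region_map: Mapping[str, str],
    measures: Sequence[str] = ("plv", "coh"),
    bands: Sequence[str] = ("delta", "theta", "alpha", "beta"),
    threshold_p: float | None = None,
) -> FeatureTable:
    """Assemble the per-subject feature table from connectivity matrices.

    ``connectivity`` maps subject ID -> {(measure, band): ConnectivityMatrix}.
    Column order is deterministic: measures x bands x (region pairs in
    canonical region order, then the four summary metrics).
    """
    regions = _region_channel_indices(channel_labels, region_map)
    region_names = list(regions)
    pairs = [
        (region_names[i], region_names[j])
        for i in range(len(region_names))
        for j in range(i, len(region_names))
    ]
    subjects = list(connectivity)
    rows: list[dict[str, float]] = []
    for sid in subjects:
        row: dict[str, float] = {}
        for measure in measures:
            for band in bands:
                key = (measure, band)
                if key not in connectivity[sid]:
                    raise DataError(f"subject {sid!r} lacks {measure}/{band} matrix")
                cm = connectivity[sid][key]
                values = cm.values
                for r1, r2 in pairs:
                    mean = _region_pair_mean(values, regions[r1], regions[r2])
                    if mean is not None:
                        row[f"{measure}_{band}_{r1}-{r2}"] = mean
                g = to_graph(cm, nodes=channel_labels, threshold_p=threshold_p)
                row[f"{measure}_{band}_geff"] = global_efficiency(g)
                row[f"{measure}_{band}_cpl"] = characteristic_path_length(
                    g, on_disconnected="largest"
                )
                row[f"{measure}_{band}_clust"] = float(
                    clustering_coefficient(g).mean()
                )
                row[f"{measure}_{band}_strength"] = float(
                    strength_centrality(g).mean()
                )
        rows.append(row)
    features = pd.DataFrame(rows, index=pd.RangeIndex(len(subjects)))
    label_series = pd.Series([labels[s] for s in subjects], name="label")
    return FeatureTable(
        features=features,
        labels=label_series,
        subjects=pd.Series(subjects, name="subject_id"),
    )
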