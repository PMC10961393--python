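"""Intra-V1 correlation matrices and classifier feature vectors.

Within-subject matrices are plain Pearson correlations over the
concatenated stimulation epochs of one condition.  Common-response (CR)
matrices correlate one subject's series with the grand-average series of
the remaining subjects (both directions, averaged), which suppresses
subject-idiosyncratic activity.  Matrices are vectorized over the upper
triangle, Fisher r-to-z transformed, and negative values are set to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import ConditionSeries
from .retinotopy import RetinotopicMap, subnetwork_label

R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    subject_id: str
    condition: str
    scheme: str
    values: np.ndarray  # vertex x vertex, symmetric, zero diagonal

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    values: np.ndarray  # rectified Fisher z per edge, length V(V-1)/2
    subject_id: str = ""
    condition: str = ""
    scheme: str = ""


@dataclass(frozen=True)
class SubNetworkPartition:
    """Sub-network label per upper-triangle edge (fixed row-major order)."""

    edge_i: np.ndarray
    edge_j: np.ndarray
    labels: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.labels.size


def edge_pairs(n_vertices: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical upper-triangle (i < j) edge order, row-major."""
    return np.triu_indices(n_vertices, k=1)


def _standardize(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores and a mask of zero-variance columns."""
    mu = data.mean(axis=0)
    sd = data.std(axis=0)
    dead = sd < 1e-14
    z = (data - mu) / np.where(dead, 1.0, sd)
    z[:, dead] = 0.0
    return z, dead


def _finalize(values: np.ndarray, dead: np.ndarray) -> np.ndarray:
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance vertices; rows/columns set to 0",
            stacklevel=3,
        )
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return values


def within_subject_matrix(series: ConditionSeries) -> ConnectivityMatrix:
    """Pearson correlations between all vertex pairs, diagonal zeroed."""
    data = series.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    z, dead = _standardize(data)
    values = z.T @ z / data.shape[0]
    return ConnectivityMatrix(
        subject_id=series.subject_id,
        condition=series.condition,
        scheme=series.scheme,
        values=_finalize(values, dead),
    )


def common_response_matrix(
    series: ConditionSeries, others: list[ConditionSeries]
) -> ConnectivityMatrix:
    """Correlation of one subject with the grand average of the others.

    M1[a, b] = corr(S_i[:, a], G[:, b]) with G the mean series over the
    n-1 other subjects; the result is (M1 + M1') / 2 with zero diagonal.
    """
    if len(others) < 1:
        raise ValueError("need at least 2 subjects for a CR matrix")
    data = series.data
    for other in others:
        if other.condition != series.condition:
            raise ValueError("CR combines same-condition series only")
        if other.data.shape != data.shape:
            raise ValueError("series length/vertex mismatch across subjects")
    grand = np.mean([o.data for o in others], axis=0)
    zi, dead_i = _standardize(data)
    zg, dead_g = _standardize(grand)
    values = zi.T @ zg / data.shape[0]
    return ConnectivityMatrix(
        subject_id=series.subject_id,
        condition=series.condition,
        scheme="CR",
        values=_finalize(values, dead_i | dead_g),
    )


def to_features(matrix: ConnectivityMatrix) -> FeatureVector:
    """Upper triangle -> Fisher z -> rectify negatives to zero."""
    values = matrix.values
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    i, j = edge_pairs(matrix.n_vertices)
    r = values[i, j]
    if np.any(np.abs(r) > R_CLIP):
        warnings.warn("|r| ~ 1 edges clipped before the Fisher transform",
                      stacklevel=2)
        r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    return FeatureVector(
        values=np.maximum(z, 0.0),
        subject_id=matrix.subject_id,
        condition=matrix.condition,
        scheme=matrix.scheme,
    )


def partition_subnetworks(rmap: RetinotopicMap) -> SubNetworkPartition:
    """Label every edge by the unordered quadrant pair of its endpoints."""
    quad = rmap.quadrant
    i, j = edge_pairs(rmap.n_vertices)
    labels = np.array(
        [subnetwork_label(quad[a], quad[b]) for a, b in zip(i, j)], dtype=object
    )
    return SubNetworkPartition(edge_i=i, edge_j=j, labels=labels)
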