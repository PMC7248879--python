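"""Ultrafast shape recognition (USR) featurization of tertiary structures.

A structure is summarized by 12 numbers: for each of four reference points
— the molecular centroid (ctd), the closest atom to ctd (cst), the farthest
atom from ctd (fct) and the farthest atom from fct (ftf) — the mean,
variance and skewness of the distribution of atom distances to that point.
The descriptor is invariant to rigid-body motion and to atom order (up to
tie-breaking of the reference points), which makes Euclidean distances in
the 12-dimensional feature space a cheap proxy for structural dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import Ensemble, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "REFERENCE_POINT_NAMES",
    "FEATURE_NAMES",
    "USRFeatures",
    "USRScoreMatrix",
    "reference_points",
    "usr_features",
    "usr_distance",
    "feature_matrix",
    "usr_score_matrix",
    "feature_table",
]

REFERENCE_POINT_NAMES = ("ctd", "cst", "fct", "ftf")
_MOMENT_NAMES = ("mean", "var", "skew")
FEATURE_NAMES = tuple(
    f"{p}_{m}" for p in REFERENCE_POINT_NAMES for m in _MOMENT_NAMES
)

# below this central second moment the distance distribution is treated as
# degenerate and skewness defined as 0
_DEGENERATE_M2 = 1e-12


@dataclass(frozen=True)
class USRFeatures:
    """The 12-dimensional USR shape descriptor of one structure.

    ``values`` holds, for each reference point in order (ctd, cst, fct,
    ftf), the (mean, variance, skewness) of the atom-distance distribution;
    distances in Angstrom.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (12,):
            raise ValueError(f"USR features must be a 12-vector, got {vals.shape}")
        if not np.isfinite(vals).all():
            raise ValueError("USR features must be finite")
        if (vals[1::3] < 0).any():
            raise ValueError("variance features must be non-negative")
        object.__setattr__(self, "values", vals)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class USRScoreMatrix:
    """Pairwise USR scores: feature-space distances normalized to [0, 1].

    ``raw_max`` records the normalization constant (the maximum raw pairwise
    feature distance, in Angstrom-feature units) so scores can be mapped
    back to raw distances.
    """

    ids: list[str]
    scores: np.ndarray
    raw_max: float

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        n = len(self.ids)
        if s.shape != (n, n):
            raise ValueError("score matrix shape does not match id count")
        if not np.allclose(s, s.T):
            raise ValueError("score matrix must be symmetric")
        if np.abs(np.diagonal(s)).max() > 1e-12:
            raise ValueError("score matrix diagonal must be zero")
        if s.min() < 0 or s.max() > 1 + 1e-12:
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return len(self.ids)


def reference_points(
    structure: Structure, selection: str = "all_atoms"
) -> dict[str, np.ndarray]:
    """Locate the four USR reference points of a structure.

    ctd is the arithmetic mean of the selected coordinates; cst/fct are the
    selected atoms minimizing/maximizing distance to ctd; ftf is the atom
    maximizing distance to fct. Ties are broken by lowest atom index.
    """
    coords = structure.select(selection)
    if len(coords) == 0:
        raise ValueError("empty atom selection")
    ctd = coords.mean(axis=0)
    d_ctd = np.linalg.norm(coords - ctd, axis=1)
    cst = coords[int(np.argmin(d_ctd))]
    fct = coords[int(np.argmax(d_ctd))]
    d_fct = np.linalg.norm(coords - fct, axis=1)
    ftf = coords[int(np.argmax(d_fct))]
    return {"ctd": ctd, "cst": cst, "fct": fct, "ftf": ftf}


def _moments(distances: np.ndarray) -> tuple[float, float, float]:
    """Mean, population variance and skewness g1 = m3 / m2^{3/2}."""
    mu = distances.mean()
    centered = distances - mu
    m2 = np.mean(centered**2)
    if m2 < _DEGENERATE_M2:
        return float(mu), float(m2), 0.0
    m3 = np.mean(centered**3)
    return float(mu), float(m2), float(m3 / m2**1.5)


def usr_features(structure: Structure, selection: str = "all_atoms") -> USRFeatures:
    """Compute the 12 USR features of one structure."""
    coords = structure.select(selection)
    points = reference_points(structure, selection)
    values = []
    for name in REFERENCE_POINT_NAMES:
        distances = np.linalg.norm(coords - points[name], axis=1)
        values.extend(_moments(distances))
    return USRFeatures(np.array(values))


def usr_distance(f1: USRFeatures | np.ndarray, f2: USRFeatures | np.ndarray) -> float:
    """Euclidean distance between two 12-dimensional USR descriptors."""
    a = np.asarray(f1, dtype=float)
    b = np.asarray(f2, dtype=float)
    if a.shape != (12,) or b.shape != (12,):
        raise ValueError("USR descriptors must be 12-vectors")
    return float(np.linalg.norm(a - b))


def feature_matrix(ensemble: Ensemble, selection: str = "all_atoms") -> np.ndarray:
    """Stack per-structure USR descriptors into an (n, 12) array."""
    return np.array([usr_features(s, selection).values for s in ensemble])


def usr_score_matrix(
    ensemble: Ensemble, selection: str = "all_atoms"
) -> USRScoreMatrix:
    """Pairwise USR scores for an ensemble, min-max normalized to [0, 1].

    The raw pairwise feature distances are divided by their maximum; the
    maximum entry is therefore 1 whenever at least two structures differ.
    """
    if len(ensemble) < 2:
        raise ValueError("USR score matrix requires at least 2 structures")
    feats = feature_matrix(ensemble, selection)
    raw = pdist(feats)
    raw_max = float(raw.max())
    if raw_max == 0.0:
        logger.warning(
            "all structures have identical USR features; all scores set to 0"
        )
        scores = np.zeros((len(ensemble), len(ensemble)))
    else:
        scores = squareform(raw / raw_max)
    return USRScoreMatrix(ids=ensemble.ids, scores=scores, raw_max=raw_max)


def feature_table(ensemble: Ensemble, selection: str = "all_atoms") -> pd.DataFrame:
    """Feature-table export: one row per structure, named USR columns."""
    feats = feature_matrix(ensemble, selection)
    df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    df.insert(0, "id", ensemble.ids)
    return df
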