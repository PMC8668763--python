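"""Reduced multidimensional trait space: Gower dissimilarity + PCoA.

Each fuzzy modality is treated as a quantitative variable; the Gower
dissimilarity between two taxa is the mean range-normalised absolute
difference over usable modalities. Classical scaling (principal coordinates)
embeds the dissimilarity matrix into ``m`` Euclidean axes; because Gower
distances are generally non-Euclidean, a square-root (default) or Cailliez
correction is applied before double-centering. The quality of the reduced
space is the fraction of positive-eigenvalue variation captured by the
retained axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .core_data import TraitMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["DistanceMatrix", "TraitSpace", "gower_distance", "pcoa", "space_quality"]


class InsufficientDataError(ValueError):
    """Fewer complete observations than the operation requires."""


class DegenerateSpaceError(ValueError):
    """No positive eigenvalue: the dissimilarity matrix carries no geometry."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise dissimilarities among taxa; symmetric, zero diagonal, in [0, 1]."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have zero diagonal")
        if d.min() < -1e-12 or d.max() > 1 + 1e-9:
            raise ValidationError("Gower dissimilarities must lie in [0, 1]")

    def submatrix(self, taxa: list[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(tuple(taxa), self.d[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.taxa), columns=list(self.taxa))


@dataclass(frozen=True)
class TraitSpace:
    """Taxon coordinates on the first ``m`` principal axes.

    ``eigenvalues`` holds the full non-increasing spectrum of the centered
    matrix; ``coords`` has exactly ``m`` columns; ``quality`` is the retained
    fraction of positive-eigenvalue variation.
    """

    taxa: tuple[str, ...]
    coords: np.ndarray
    eigenvalues: np.ndarray
    m: int
    quality: float
    correction: str

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.taxa), self.m):
            raise ValidationError("coords must be taxa x m")
        ev = np.asarray(self.eigenvalues)
        if np.any(np.diff(ev) > 1e-9):
            raise ValidationError("eigenvalues must be non-increasing")
        if not (0.0 <= self.quality <= 1.0 + 1e-12):
            raise ValidationError("quality must lie in [0, 1]")

    def subset(self, taxa: list[str]) -> np.ndarray:
        idx = [self.taxa.index(t) for t in taxa]
        return self.coords[idx]

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coords,
            index=list(self.taxa),
            columns=[f"axis_{k+1}" for k in range(self.m)],
        )


def gower_distance(
    traits: TraitMatrix, range_mode: str = "empirical"
) -> DistanceMatrix:
    """Gower dissimilarity over fuzzy trait modalities.

    d(i, j) = mean over usable modalities k of |x_ik - x_jk| / range_k.

    range_mode 'empirical' uses the observed range per modality and drops
    zero-range modalities; 'theoretical' fixes every range at 1 (fuzzy scores
    live in [0, 1]), so constant modalities contribute zero difference.
    Taxa with a missing trait-group block are excluded (logged).
    """
    if range_mode not in ("empirical", "theoretical"):
        raise ValueError(f"unknown range_mode {range_mode!r}")
    keep = traits.complete_taxa()
    dropped = set(traits.taxa) - set(keep)
    if dropped:
        logger.warning("gower_distance: excluding %d taxa with missing traits", len(dropped))
    if len(keep) < 2:
        raise InsufficientDataError("need >= 2 taxa with complete traits")
    x = traits.values.loc[keep].to_numpy(dtype=float)
    if range_mode == "empirical":
        rng = x.max(axis=0) - x.min(axis=0)
        usable = rng > 0
        if not usable.any():
            raise InsufficientDataError("all modalities have zero range")
        x = x[:, usable]
        rng = rng[usable]
    else:
        rng = np.ones(x.shape[1])
    xn = x / rng
    diff = np.abs(xn[:, None, :] - xn[None, :, :])
    d = diff.mean(axis=2)
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, 1.0)
    return DistanceMatrix(tuple(keep), d)


def _cailliez_constant(d: np.ndarray) -> float:
    # smallest c such that d + c (off-diagonal) is Euclidean: largest real
    # eigenvalue of the 2n x 2n companion problem (Cailliez 1983)
    n = d.shape[0]
    d1 = -0.5 * d**2
    d2 = -0.5 * d
    j = np.eye(n) - np.ones((n, n)) / n
    w1 = j @ d1 @ j
    w2 = j @ d2 @ j
    block = np.block(
        [[np.zeros((n, n)), 2.0 * w1], [-np.eye(n), -4.0 * w2]]
    )
    ev = np.linalg.eigvals(block)
    c = float(np.max(ev.real))
    return max(c, 0.0)


def pcoa(d: DistanceMatrix, m: int = 13, correction: str = "sqrt") -> TraitSpace:
    """Principal-coordinates embedding of a dissimilarity matrix.

    Applies the chosen negative-eigenvalue correction ('sqrt' embeds
    sqrt(d), 'cailliez' adds the Cailliez constant, 'none' uses d as is),
    double-centers -0.5 * D^2, eigen-decomposes, and keeps the first ``m``
    axes with positive eigenvalues (coordinates are eigenvectors scaled by
    the square root of their eigenvalue). If fewer than ``m`` positive
    eigenvalues exist, ``m`` is reduced with a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    dm = d.d.copy()
    if correction == "sqrt":
        dm = np.sqrt(dm)
    elif correction == "cailliez":
        c = _cailliez_constant(dm)
        off = ~np.eye(dm.shape[0], dtype=bool)
        dm[off] = dm[off] + c
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    b = 0.5 * (b + b.T)
    vals, vecs = eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    tol = max(abs(vals[0]), 1.0) * 1e-10
    n_pos = int(np.sum(vals > tol))
    if n_pos == 0:
        raise DegenerateSpaceError("no positive eigenvalue in centered matrix")
    m_eff = min(m, n_pos)
    if m_eff < m:
        logger.warning("pcoa: only %d positive eigenvalues; reducing m from %d", n_pos, m)
    coords = vecs[:, :m_eff] * np.sqrt(vals[:m_eff])
    pos = vals[vals > tol]
    quality = float(pos[:m_eff].sum() / pos.sum())
    return TraitSpace(
        taxa=d.taxa,
        coords=coords,
        eigenvalues=vals,
        m=m_eff,
        quality=quality,
        correction=correction,
    )


def space_quality(space: TraitSpace) -> float:
    """Retained fraction: sum of kept positive eigenvalues / sum of all positive."""
    vals = np.asarray(space.eigenvalues)
    tol = max(abs(vals[0]), 1.0) * 1e-10
    pos = vals[vals > tol]
    if pos.size == 0:
        raise DegenerateSpaceError("no positive eigenvalue")
    return float(pos[: space.m].sum() / pos.sum())
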