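"""Distance-based functional diversity metrics computed per community.

All metrics operate on taxa embedded in the reduced trait space (or directly
on the Gower matrix for RaoQ and distinctiveness):

* FRic — convex-hull volume of the present taxa, standardised by the pool
  ("overarching") hull so values are comparable across years.
* FEve — regularity of abundance along the minimum spanning tree linking the
  present taxa.
* FDiv — abundance-weighted deviance from the mean distance to the centre of
  gravity of the hull vertices.
* FDis — abundance-weighted mean distance to the abundance-weighted centroid.
* RaoQ — expected dissimilarity between two random individuals,
  sum_ij p_i p_j d_ij, optionally scaled by the series maximum.
* CWM — abundance-weighted mean trait value per modality.
* FDist — abundance-weighted mean distance of one taxon to all others in its
  community (functional distinctiveness).

Hull-based metrics fall back to the first S-1 axes when a year's richness S
does not exceed the space dimension m (a hull needs > m points in m-D).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .core_data import CommunityMatrix, TraitMatrix
from .trait_space import DistanceMatrix, TraitSpace

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityFD",
    "functional_richness",
    "functional_evenness",
    "functional_divergence",
    "functional_dispersion",
    "rao_q",
    "community_weighted_mean",
    "functional_distinctiveness",
    "redundancy_slope",
    "community_fd",
    "fd_table",
]


class InsufficientSpeciesError(ValueError):
    """Too few taxa for the requested metric."""


@dataclass
class CommunityFD:
    """Per-year record of the functional diversity metric suite."""

    year: int
    richness: int
    fric_raw: float
    fric: float
    feve: float
    fdiv: float
    fdis: float
    raoq_raw: float
    raoq: float = np.nan  # filled once the series maximum is known
    cwm: pd.Series = field(default=None, repr=False)  # type: ignore[assignment]
    fdist_per_taxon: pd.Series = field(default=None, repr=False)  # type: ignore[assignment]
    fdist_mean: float = np.nan


def _affine_rank(pts: np.ndarray) -> int:
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    tol = max(pts.shape) * (sv[0] if sv.size else 0.0) * 1e-10
    return int(np.sum(sv > max(tol, 1e-300)))


def _hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume; 1-D degenerates to the range of the points.

    Genuinely flat point sets (affine rank below the ambient dimension) raise
    QhullError; near-degenerate but full-rank sets are retried with a 1e-12
    jitter used for hull construction only.
    """
    pts = np.asarray(points, dtype=float)
    n, dim = pts.shape
    if n <= dim:
        raise QhullError(f"need > {dim} points in {dim}-D")
    if dim == 1:
        v = float(np.ptp(pts[:, 0]))
        if v == 0:
            raise QhullError("all points coincident")
        return v
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        if _affine_rank(pts) < dim:
            raise
        rng = np.random.default_rng(0)
        return float(ConvexHull(pts + rng.normal(0, 1e-12, pts.shape), qhull_options="QJ").volume)


#: Default dimensionality cap for convex-hull construction. Qhull cost grows
#: roughly sixfold per added dimension, so hulls use the leading axes (which
#: carry most eigenvalue mass) while distance-based metrics keep the full space.
DEFAULT_HULL_DIM = 6


def _effective_coords(
    space: TraitSpace, present: list[str], hull_dim: int | None = DEFAULT_HULL_DIM
) -> np.ndarray:
    """Present-taxon coordinates on the axes a hull can be built in.

    The hull needs strictly more points than dimensions, so the subspace is
    the first min(hull_dim, m, S-1) axes.
    """
    pts = space.subset(present)
    s = len(present)
    cap = space.m if hull_dim is None else min(hull_dim, space.m)
    ndim = max(min(cap, s - 1), 1)
    if ndim < space.m:
        logger.debug("hull subspace: S=%d, m=%d -> %d axes", s, space.m, ndim)
    return pts[:, :ndim]


def hull_volume_raw(
    space: TraitSpace, present: list[str], hull_dim: int | None = DEFAULT_HULL_DIM
) -> float:
    """Unstandardised convex-hull volume of the present taxa (nan if degenerate)."""
    pts = _effective_coords(space, present, hull_dim)
    try:
        return _hull_volume(pts)
    except QhullError:
        return np.nan


def functional_richness(
    space: TraitSpace,
    present: list[str],
    pool: list[str] | None = None,
    hull_dim: int | None = DEFAULT_HULL_DIM,
) -> tuple[float, float]:
    """Convex-hull volume of present taxa, standardised by the pool hull.

    Returns ``(fric_raw, fric)`` where fric = fric_raw / pool hull volume in
    the same subspace. Degenerate point sets yield ``(nan, nan)``.
    """
    pool = list(space.taxa) if pool is None else pool
    pts = _effective_coords(space, present, hull_dim)
    ndim = pts.shape[1]
    try:
        raw = _hull_volume(pts)
    except QhullError:
        logger.warning("functional_richness: degenerate hull for S=%d", len(present))
        return np.nan, np.nan
    pool_pts = space.subset(pool)[:, :ndim]
    try:
        total = _hull_volume(pool_pts)
    except QhullError:
        return raw, np.nan
    return raw, raw / total


def functional_evenness(
    space: TraitSpace, present: list[str], weights: np.ndarray
) -> float:
    """Regularity of abundance along the minimum spanning tree.

    For each MST edge l = (i, j): EW_l = dist(i, j) / (w_i + w_j) and
    PEW_l = EW_l / sum EW; FEve rescales the sum of min(PEW_l, 1/(S-1)) to
    [0, 1], with 1 for perfectly even spacing and weighting.
    """
    s = len(present)
    if s < 3:
        raise InsufficientSpeciesError("FEve needs >= 3 taxa")
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    pts = space.subset(present)
    dmat = squareform(pdist(pts))
    mst = minimum_spanning_tree(dmat).tocoo()
    ew = np.array([dmat[i, j] / (w[i] + w[j]) for i, j in zip(mst.row, mst.col)])
    total = ew.sum()
    if total == 0:
        return np.nan
    pew = ew / total
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def functional_divergence(
    space: TraitSpace,
    present: list[str],
    weights: np.ndarray,
    hull_dim: int | None = DEFAULT_HULL_DIM,
) -> float:
    """Abundance-weighted deviance from the mean distance to the hull-vertex centroid.

    G is the unweighted centroid of the convex-hull vertex taxa; with
    dG_i = ||x_i - G|| and mean d̄G, FDiv = (Δd + d̄G) / (Δ|d| + d̄G) where
    Δd = Σ w_i (dG_i − d̄G) and Δ|d| = Σ w_i |dG_i − d̄G|.
    """
    s = len(present)
    if s < 3:
        raise InsufficientSpeciesError("FDiv needs >= 3 taxa")
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    pts = _effective_coords(space, present, hull_dim)
    if pts.shape[1] == 1:
        vertices = np.array([int(np.argmin(pts[:, 0])), int(np.argmax(pts[:, 0]))])
    else:
        try:
            vertices = ConvexHull(pts).vertices
        except QhullError:
            # degenerate (e.g. collinear in >1-D): every point is a "vertex"
            vertices = np.arange(pts.shape[0])
    g = pts[vertices].mean(axis=0)
    dg = np.linalg.norm(pts - g, axis=1)
    dbar = dg.mean()
    if dbar == 0:
        logger.warning("functional_divergence: all taxa coincident")
        return np.nan
    delta_d = float(np.sum(w * (dg - dbar)))
    delta_abs = float(np.sum(w * np.abs(dg - dbar)))
    return (delta_d + dbar) / (delta_abs + dbar)


def functional_dispersion(
    space: TraitSpace, present: list[str], weights: np.ndarray
) -> float:
    """Abundance-weighted mean distance to the abundance-weighted centroid."""
    if len(present) == 0:
        raise InsufficientSpeciesError("FDis needs >= 1 taxon")
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    pts = space.subset(present)
    c = w @ pts
    return float(np.sum(w * np.linalg.norm(pts - c, axis=1)))


def rao_q(
    d: DistanceMatrix, present: list[str], weights: np.ndarray
) -> float:
    """Rao's quadratic entropy: sum_ij p_i p_j d_ij (raw, unscaled)."""
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    sub = d.submatrix(present)
    return float(w @ sub.d @ w)


def community_weighted_mean(traits: TraitMatrix, present: list[str], weights: np.ndarray) -> pd.Series:
    """Abundance-weighted mean trait value per modality, cwm_k = sum_i p_i x_ik."""
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    x = traits.values.loc[present].to_numpy(dtype=float)
    return pd.Series(w @ x, index=traits.values.columns)


def functional_distinctiveness(
    d: DistanceMatrix, present: list[str], abundances: np.ndarray
) -> tuple[pd.Series, float]:
    """Abundance-weighted distance of each taxon to all others in its community.

    D_i = sum_{j != i} d_ij a_j / sum_{j != i} a_j; the community mean is the
    abundance-weighted average of the D_i.
    """
    if len(present) < 2:
        raise InsufficientSpeciesError("distinctiveness needs >= 2 taxa")
    a = np.asarray(abundances, dtype=float)
    sub = d.submatrix(present).d
    total = a.sum()
    denom = total - a
    if (denom <= 0).any():
        raise ValueError("each taxon needs positive abundance of others")
    di = (sub @ a) / denom  # diagonal is zero so j != i is automatic
    per_taxon = pd.Series(di, index=present)
    mean = float(np.sum(a * di) / total)
    return per_taxon, mean


def redundancy_slope(richness: np.ndarray, fd: np.ndarray):
    """OLS fit of a functional diversity series against taxonomic richness.

    Returns ``(slope, slope_se, r2, p)``. A slope indistinguishable from zero
    indicates functional redundancy: adding taxa does not add trait space.
    """
    import statsmodels.api as sm

    x = np.asarray(richness, dtype=float)
    y = np.asarray(fd, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in richness: slope undefined")
    if np.ptp(y) == 0:
        return 0.0, 0.0, 0.0, 1.0  # flat response: no relation
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return (
        float(model.params[1]),
        float(model.bse[1]),
        float(model.rsquared),
        float(model.pvalues[1]),
    )


def community_fd(
    comm: CommunityMatrix,
    space: TraitSpace,
    d: DistanceMatrix,
    traits: TraitMatrix | None = None,
    hull_dim: int | None = DEFAULT_HULL_DIM,
) -> list[CommunityFD]:
    """Compute the full per-year metric suite; RaoQ scaled by the series maximum."""
    pool = [t for t in comm.taxa if t in space.taxa]
    records: list[CommunityFD] = []
    for year in comm.years:
        present = [t for t in comm.present(year) if t in space.taxa]
        a = comm.abundance.loc[year, present].to_numpy(dtype=float)
        w = a / a.sum()
        s = len(present)
        fric_raw, fric = functional_richness(space, present, pool, hull_dim)
        feve = functional_evenness(space, present, w) if s >= 3 else np.nan
        fdiv = functional_divergence(space, present, w, hull_dim) if s >= 3 else np.nan
        fdis = functional_dispersion(space, present, w)
        rq = rao_q(d, present, w)
        cwm = (
            community_weighted_mean(traits, present, w) if traits is not None else None
        )
        if s >= 2:
            fdist, fdist_mean = functional_distinctiveness(d, present, a)
        else:
            fdist, fdist_mean = pd.Series(dtype=float), np.nan
        records.append(
            CommunityFD(
                year=year,
                richness=s,
                fric_raw=fric_raw,
                fric=fric,
                feve=feve,
                fdiv=fdiv,
                fdis=fdis,
                raoq_raw=rq,
                cwm=cwm,
                fdist_per_taxon=fdist,
                fdist_mean=fdist_mean,
            )
        )
    max_rq = max((r.raoq_raw for r in records), default=np.nan)
    for r in records:
        r.raoq = r.raoq_raw / max_rq if max_rq and max_rq > 0 else np.nan
    return records


def fd_table(records: list[CommunityFD]) -> pd.DataFrame:
    """Tidy per-year metric table (year x metric columns)."""
    return pd.DataFrame(
        {
            "year": [r.year for r in records],
            "richness": [r.richness for r in records],
            "fric_raw": [r.fric_raw for r in records],
            "fric": [r.fric for r in records],
            "feve": [r.feve for r in records],
            "fdiv": [r.fdiv for r in records],
            "fdis": [r.fdis for r in records],
            "raoq_raw": [r.raoq_raw for r in records],
            "raoq": [r.raoq for r in records],
            "fdist_mean": [r.fdist_mean for r in records],
        }
    ).set_index("year")
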