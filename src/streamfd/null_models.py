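"""Name-shuffling null model and standardized effect sizes (SES).

Hull- and tree-based functional metrics (FRic, FEve, FDiv) scale with
taxonomic richness, so their raw trends confound trait change with richness
change. The name-shuffling null breaks the link between a taxon's identity
and its position in trait space while preserving each year's richness and
abundance structure: the rows of the coordinate matrix are randomly permuted
over the full taxon pool and the metric recomputed. SES =
(observed - null mean) / null sd; the rank-based two-sided p uses the
observed value's position among the permuted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CommunityMatrix
from .fd_metrics import (
    functional_divergence,
    functional_evenness,
    hull_volume_raw,
)
from .trait_space import TraitSpace

__all__ = ["SESResult", "name_shuffle_ses", "METRIC_FUNCS"]


def _fric(space: TraitSpace, present, w) -> float:
    # SES is invariant to the pool-hull standardisation constant (the pool is
    # the full taxon set, unchanged by label shuffling), so the raw volume is
    # used and the constant division skipped.
    return hull_volume_raw(space, present)


METRIC_FUNCS = {
    "fric": _fric,
    "feve": functional_evenness,
    "fdiv": functional_divergence,
}


@dataclass(frozen=True)
class SESResult:
    """Null-model outcome for one metric in one year."""

    metric: str
    year: int
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # nan when null_sd == 0
    p_two_sided: float
    n_perm: int
    seed: int


def _shuffled_space(space: TraitSpace, rng: np.random.Generator) -> TraitSpace:
    perm = rng.permutation(len(space.taxa))
    return TraitSpace(
        taxa=space.taxa,
        coords=space.coords[perm],
        eigenvalues=space.eigenvalues,
        m=space.m,
        quality=space.quality,
        correction=space.correction,
    )


def name_shuffle_ses(
    metric: str,
    comm: CommunityMatrix,
    space: TraitSpace,
    n_perm: int = 999,
    seed: int = 0,
) -> list[SESResult]:
    """SES of a functional metric under taxon-label shuffling, per year.

    Labels are permuted over the full pool (not per year) so richness and
    abundances are fixed while the trait-identity link is broken. Identical
    seeds give identical output.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if metric not in METRIC_FUNCS:
        raise ValueError(f"metric must be one of {sorted(METRIC_FUNCS)}")
    fn = METRIC_FUNCS[metric]
    rng = np.random.default_rng(seed)

    years = comm.years
    present_by_year = {}
    weights_by_year = {}
    for y in years:
        present = [t for t in comm.present(y) if t in space.taxa]
        a = comm.abundance.loc[y, present].to_numpy(dtype=float)
        present_by_year[y] = present
        weights_by_year[y] = a / a.sum()

    observed = {y: fn(space, present_by_year[y], weights_by_year[y]) for y in years}
    null_vals = {y: np.empty(n_perm) for y in years}
    for k in range(n_perm):
        shuffled = _shuffled_space(space, rng)
        for y in years:
            null_vals[y][k] = fn(shuffled, present_by_year[y], weights_by_year[y])

    results = []
    for y in years:
        nv = null_vals[y]
        obs = observed[y]
        mu = float(np.nanmean(nv))
        sd = float(np.nanstd(nv, ddof=1))
        ses = (obs - mu) / sd if sd > 0 else np.nan
        # rank-based two-sided p with the observed value included in the pool
        n_ge = int(np.sum(nv >= obs)) + 1
        n_le = int(np.sum(nv <= obs)) + 1
        p = min(1.0, 2.0 * min(n_ge, n_le) / (n_perm + 1))
        results.append(
            SESResult(
                metric=metric,
                year=y,
                observed=float(obs),
                null_mean=mu,
                null_sd=sd,
                ses=float(ses) if np.isfinite(ses) else np.nan,
                p_two_sided=p,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def ses_table(results: list[SESResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
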