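"""Synthetic trait pools and multi-year community series.

The generator emulates the statistical structure of a multidecadal stream
macroinvertebrate monitoring series: roughly 70 taxon complexes scored on 11
fuzzy-coded trait groups (63 modalities in total), about 24 annual surveys
spread over a 32-year span, linearly increasing taxonomic richness, declining
evenness, and one clade (Diptera-like) whose share of the community rises to
dominance. Taxa belong to clades with correlated trait syndromes: each clade
owns a centroid on every trait-group simplex and its members are Dirichlet
draws around it, so within-clade Gower distances are smaller than
between-clade ones. Abundances follow a lognormal rank-abundance law whose
shape parameter widens over time (the evenness driver) and are discretised
through an ordinal abundance-class scheme, mirroring class-based field
recording.

Two recruitment modes expose the functional-redundancy mechanism:
``syndrome`` (default) recruits newly arriving taxa from existing clade
syndromes, so added richness adds little trait space; ``outlier`` recruits
hull-expanding taxa with one-hot trait profiles, so functional dispersion
grows with richness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import (
    AbundanceClassScheme,
    CommunityMatrix,
    DEFAULT_CLASS_SCHEME,
    TraitMatrix,
    discretize_community,
    fuzzy_scale,
)

__all__ = ["ScenarioConfig", "generate_trait_pool", "generate_community_series", "clade_of"]

#: Modality counts per trait group (11 groups, 63 modalities), patterned on
#: standard macroinvertebrate biological trait databases.
DEFAULT_GROUP_SIZES = (7, 8, 5, 4, 3, 8, 4, 5, 8, 7, 4)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic monitoring scenario.

    Defaults reproduce the study conditions the analysis assumes: 70 taxa in
    6 clades, 24 surveys over 1983-2014, richness rising ~5 taxa per decade
    from a baseline of 25, lognormal abundance shape widening from 1.0 to 2.0
    (declining evenness), and the dominance clade's abundance multiplier
    ramping to 6x so total abundance roughly triples.
    """

    seed: int
    n_taxa: int = 70
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    n_clades: int = 6
    clade_concentration: float = 15.0  # Dirichlet tightness around clade centroid
    sparsity_cutoff: float = 0.15  # affinities below this are zeroed (fuzzy tables are sparse)
    year_start: int = 1983
    n_years: int = 32
    n_surveys: int = 24
    richness_start: float = 25.0
    richness_trend: float = 5.0  # taxa per decade
    richness_jitter_sd: float = 1.5
    evenness_sigma_start: float = 1.0
    evenness_sigma_end: float = 2.0  # > start means declining evenness
    dominance_clade: int = 1
    dominance_final_multiplier: float = 6.0
    abundance_total_start: float = 1000.0
    abundance_growth: float = 1.73  # fractional increase over the span
    base_abundance_sigma: float = 1.0  # taxon-level commonness dispersion
    recruit_mode: str = "syndrome"  # or 'outlier'
    n_outliers: int = 30  # outlier-mode recruits with one-hot profiles
    scheme: AbundanceClassScheme = field(default=DEFAULT_CLASS_SCHEME)
    discretize: bool = True

    def __post_init__(self) -> None:
        if self.n_taxa <= 0 or self.n_clades <= 0 or self.n_surveys < 2:
            raise ValueError("counts must be positive (>= 2 surveys)")
        if self.n_surveys > self.n_years:
            raise ValueError("cannot survey more years than the span")
        if self.recruit_mode not in ("syndrome", "outlier"):
            raise ValueError("recruit_mode must be 'syndrome' or 'outlier'")

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


def _rng(cfg: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[stream])


def taxon_names(cfg: ScenarioConfig) -> list[str]:
    return [f"taxon_{i:03d}" for i in range(cfg.n_taxa)]


def clade_of(cfg: ScenarioConfig, taxon: str) -> str:
    i = int(taxon.split("_")[1])
    return f"clade_{i % cfg.n_clades}"


def generate_trait_pool(cfg: ScenarioConfig) -> TraitMatrix:
    """Fuzzy-coded trait pool with clade-correlated syndromes.

    Each clade draws a centroid on every trait-group simplex; its member taxa
    are Dirichlet draws around that centroid. In ``outlier`` mode the last
    ``n_outliers`` taxa instead receive one-hot profiles (a random single
    modality per group), placing them at simplex corners far from every
    syndrome. Deterministic given the config seed.
    """
    rng = _rng(cfg, 0)
    groups = {
        f"group_{g:02d}": [f"g{g:02d}_m{m}" for m in range(size)]
        for g, size in enumerate(cfg.group_sizes)
    }
    names = taxon_names(cfg)
    centroids = {
        (c, g): rng.dirichlet(np.full(size, 0.5))
        for c in range(cfg.n_clades)
        for g, size in enumerate(cfg.group_sizes)
    }
    outliers = set(range(cfg.n_taxa - cfg.n_outliers, cfg.n_taxa)) if cfg.recruit_mode == "outlier" else set()
    # hull-expanding invaders carry trait states the resident syndromes barely
    # use: one-hot profiles drawn from the rarer half of each group's modalities
    rare_mods = {}
    for g, size in enumerate(cfg.group_sizes):
        mass = sum(centroids[(c, g)] for c in range(cfg.n_clades))
        rare_mods[g] = np.argsort(mass)[: max(size // 2, 1)]
    rows = []
    for i in range(cfg.n_taxa):
        clade = i % cfg.n_clades
        row = []
        for g, size in enumerate(cfg.group_sizes):
            if i in outliers:
                prof = np.zeros(size)
                prof[rng.choice(rare_mods[g])] = 1.0
            else:
                alpha = centroids[(clade, g)] * cfg.clade_concentration + 1e-3
                prof = rng.dirichlet(alpha)
                prof = np.where(prof < cfg.sparsity_cutoff, 0.0, prof)
                if prof.sum() == 0:  # safeguard: keep the largest modality
                    prof[np.argmax(rng.dirichlet(alpha))] = 1.0
            row.append(prof)
        rows.append(np.concatenate(row))
    raw = pd.DataFrame(
        rows, index=names, columns=[m for mods in groups.values() for m in mods]
    )
    return fuzzy_scale(raw, groups)


def survey_years(cfg: ScenarioConfig) -> list[int]:
    """24-of-32 style discontinuous survey schedule (first and last year kept)."""
    rng = _rng(cfg, 1)
    all_years = np.arange(cfg.year_start, cfg.year_start + cfg.n_years)
    interior = all_years[1:-1]
    keep = rng.choice(interior, size=cfg.n_surveys - 2, replace=False)
    return sorted([int(all_years[0]), int(all_years[-1])] + [int(y) for y in keep])


def generate_community_series(cfg: ScenarioConfig, traits: TraitMatrix) -> CommunityMatrix:
    """Multi-year community series with the configured temporal structure.

    Richness follows the configured ramp with iid jitter; the available pool
    accretes over time with dominance-clade (and, in outlier mode, outlier)
    taxa arriving preferentially in the second half; per-taxon abundances are
    lognormal with a widening shape parameter and a rising dominance-clade
    multiplier, scaled to the growing community total and (optionally)
    discretised through the abundance-class scheme.
    """
    rng = _rng(cfg, 2)
    names = taxon_names(cfg)
    n = cfg.n_taxa
    span = cfg.n_years - 1
    years = survey_years(cfg)

    peak_richness = cfg.richness_start + abs(cfg.richness_trend) / 10.0 * span
    if peak_richness > n:
        raise ValueError("requested richness exceeds the taxon pool")

    clades = np.array([i % cfg.n_clades for i in range(n)])
    is_dom = clades == cfg.dominance_clade
    is_outlier = np.zeros(n, dtype=bool)
    if cfg.recruit_mode == "outlier":
        is_outlier[n - cfg.n_outliers :] = True

    # arrival order: outlier taxa arrive as recruits; the dominance clade is
    # recruited preferentially only when its dominance ramp is active
    dom_boost = 0.5 if cfg.dominance_final_multiplier != 1.0 else 0.0
    score = rng.uniform(size=n) + dom_boost * is_dom + 1.0 * is_outlier
    arrival = np.argsort(score)  # taxon indices in arrival order
    rank = np.empty(n, dtype=int)
    rank[arrival] = np.arange(n)

    base_weight = rng.lognormal(0.0, 1.0, size=n)  # persistent commonness
    base_abund = rng.lognormal(0.0, cfg.base_abundance_sigma, size=n)

    n0 = min(n, int(np.ceil(cfg.richness_start * 1.4)))
    rows = {}
    for year in years:
        t = (year - cfg.year_start) / span
        n_avail = int(round(n0 + (n - n0) * t))
        avail = np.where(rank < max(n_avail, 3))[0]

        target = cfg.richness_start + cfg.richness_trend / 10.0 * (year - cfg.year_start)
        s = int(np.clip(round(target + rng.normal(0, cfg.richness_jitter_sd)), 3, avail.size))

        dom_mult = 1.0 + (cfg.dominance_final_multiplier - 1.0) * t
        w = base_weight[avail] * np.where(is_dom[avail], np.sqrt(dom_mult), 1.0)
        chosen = rng.choice(avail, size=s, replace=False, p=w / w.sum())

        sigma_t = cfg.evenness_sigma_start + (cfg.evenness_sigma_end - cfg.evenness_sigma_start) * t
        a = base_abund[chosen] * rng.lognormal(0.0, sigma_t, size=s)
        a *= np.where(is_dom[chosen], dom_mult, 1.0)
        total_t = cfg.abundance_total_start * (1.0 + cfg.abundance_growth * t)
        a *= total_t / a.sum()
        row = np.zeros(n)
        row[chosen] = a
        rows[year] = row

    comm = CommunityMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=names))
    if cfg.discretize:
        comm = discretize_community(comm, cfg.scheme)
    # discretisation can zero a tiny community; invariant requires >= 1 positive
    return comm
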