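"""Ingest, validate and normalise trait tables, abundance tables and taxon maps.

Community samples from long-term kick-sampling surveys come in two flavours —
ordinal abundance classes (early surveys) and counts per square metre (later
surveys). Both are reduced to a common currency, the class-mean density, via an
:class:`AbundanceClassScheme`. Biological traits are fuzzy coded: each taxon
distributes affinity scores over the modalities of a trait group, and scores
are proportionally scaled so every (taxon, group) block sums to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitMatrix",
    "CommunityMatrix",
    "AbundanceClassScheme",
    "TaxonMapping",
    "DEFAULT_CLASS_SCHEME",
    "fuzzy_scale",
    "aggregate_taxa",
    "abundance_to_class_mean",
    "read_trait_csv",
    "read_community_csv",
    "read_mapping_csv",
]


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class MappingError(KeyError):
    """A taxon or modality cannot be resolved through the supplied mapping."""


@dataclass(frozen=True)
class TraitMatrix:
    """Fuzzy-coded taxon x trait-modality affinity table.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are taxa, columns are modality labels, entries in [0, 1].
    groups : dict[str, list[str]]
        Trait-group label -> member modality labels. Every column of
        ``values`` belongs to exactly one group.
    missing : pandas.DataFrame
        Boolean taxon x group mask; True marks an all-zero (unknown) block.
    """

    values: pd.DataFrame
    groups: dict[str, list[str]]
    missing: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError("duplicate taxon identifiers in trait matrix")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate modality labels in trait matrix")
        assigned = [m for mods in self.groups.values() for m in mods]
        if sorted(assigned) != sorted(v.columns):
            raise MappingError("trait-group membership does not cover modalities 1:1")
        arr = v.to_numpy(dtype=float)
        if np.nanmin(arr) < -1e-12 or np.nanmax(arr) > 1 + 1e-12:
            raise ValidationError("trait affinities must lie in [0, 1]")
        if self.missing is None:
            object.__setattr__(
                self,
                "missing",
                pd.DataFrame(False, index=v.index, columns=list(self.groups)),
            )
        # group sums are 1 or the block is flagged missing
        for g, mods in self.groups.items():
            s = v[mods].sum(axis=1).to_numpy()
            ok = np.isclose(s, 1.0, atol=1e-9) | self.missing[g].to_numpy()
            if not ok.all():
                bad = v.index[~ok].tolist()
                raise ValidationError(
                    f"trait group {g!r}: scores do not sum to 1 for taxa {bad[:5]}"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def modalities(self) -> list[str]:
        return list(self.values.columns)

    def complete_taxa(self) -> list[str]:
        """Taxa with no missing trait-group block."""
        return list(self.values.index[~self.missing.any(axis=1)])


@dataclass(frozen=True)
class CommunityMatrix:
    """Year x taxon abundance table (class-mean densities or counts, >= 0)."""

    abundance: pd.DataFrame  # index: years (int), columns: taxa

    def __post_init__(self) -> None:
        a = self.abundance
        if not a.index.is_monotonic_increasing:
            object.__setattr__(self, "abundance", a.sort_index())
            a = self.abundance
        arr = a.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("abundances must be non-negative")
        if (arr.sum(axis=1) <= 0).any():
            empty = a.index[arr.sum(axis=1) <= 0].tolist()
            raise ValidationError(f"years with no positive abundance: {empty}")
        if a.columns.duplicated().any():
            raise ValidationError("duplicate taxon columns")
        a.index.name = "year"
        a.columns.name = None

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.abundance.index]

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.columns)

    def present(self, year: int) -> list[str]:
        row = self.abundance.loc[year]
        return list(row.index[row > 0])

    def relative(self) -> pd.DataFrame:
        """Per-year relative abundances p_i = a_i / sum(a)."""
        a = self.abundance
        return a.div(a.sum(axis=1), axis=0)

    def align_to(self, taxa: list[str]) -> "CommunityMatrix":
        """Restrict and reorder columns to ``taxa`` (missing taxa -> 0)."""
        out = self.abundance.reindex(columns=taxa, fill_value=0.0)
        return CommunityMatrix(out)


@dataclass(frozen=True)
class AbundanceClassScheme:
    """Ordinal abundance classes over (0, inf): (lower, upper, class mean).

    Intervals are half-open ``(lower, upper]``; bounds strictly increase and
    tile the positive line (last upper bound is ``inf``). Zero maps to zero.
    """

    classes: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        prev_upper = 0.0
        for lo, hi, mean in self.classes:
            if lo != prev_upper:
                raise ValidationError("class bounds must tile (0, inf) without gaps")
            if hi <= lo:
                raise ValidationError("class bounds must strictly increase")
            if not (lo < mean <= hi):
                raise ValidationError("class mean must lie within its bounds")
            prev_upper = hi
        if not np.isinf(prev_upper):
            raise ValidationError("last class must extend to infinity")

    def class_mean(self, raw: float) -> float:
        return abundance_to_class_mean(raw, self)


def _geometric_default() -> AbundanceClassScheme:
    # Geometric scheme on bounds 1,3,10,31,100,316,1000 with geometric-mean
    # class means; documented stand-in for ordinal field recording schemes.
    # First class (0,1] takes mean 0.5; the open top class extrapolates one
    # half-decade beyond its lower bound.
    bounds = [0.0, 1.0, 3.0, 10.0, 31.0, 100.0, 316.0, 1000.0, np.inf]
    classes = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if lo == 0.0:
            mean = 0.5
        elif np.isinf(hi):
            mean = float(lo * np.sqrt(10.0))
        else:
            mean = float(np.sqrt(lo * hi))
        classes.append((lo, hi, mean))
    return AbundanceClassScheme(tuple(classes))


DEFAULT_CLASS_SCHEME = _geometric_default()


@dataclass(frozen=True)
class TaxonMapping:
    """Total map raw taxon name -> taxon-complex name."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for raw, cx in self.entries.items():
            if not cx:
                raise ValidationError(f"empty complex name for taxon {raw!r}")

    def __getitem__(self, raw: str) -> str:
        try:
            return self.entries[raw]
        except KeyError as exc:
            raise MappingError(f"taxon {raw!r} missing from mapping") from exc


def fuzzy_scale(raw_traits: pd.DataFrame, groups: dict[str, list[str]]) -> TraitMatrix:
    """Proportionally scale raw affinity scores within each trait group.

    Within each (taxon, group) block, scores are divided by the block sum so
    fuzzy affinities sum to one per group. All-zero blocks are flagged missing
    rather than silently left at zero.

    Parameters
    ----------
    raw_traits : pandas.DataFrame
        Taxa x modality non-negative scores.
    groups : dict
        Trait-group label -> member modalities; every modality of
        ``raw_traits`` must be assigned to exactly one group.
    """
    arr = raw_traits.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("raw trait scores must be non-negative")
    assigned = [m for mods in groups.values() for m in mods]
    unknown = set(raw_traits.columns) - set(assigned)
    if unknown or len(assigned) != len(set(assigned)) or set(assigned) - set(raw_traits.columns):
        raise MappingError(f"modality/group mismatch (unassigned: {sorted(unknown)[:5]})")

    scaled = raw_traits.astype(float).copy()
    missing = pd.DataFrame(False, index=raw_traits.index, columns=list(groups))
    for g, mods in groups.items():
        block = scaled[mods]
        s = block.sum(axis=1)
        zero = s <= 0
        missing[g] = zero.to_numpy()
        safe = s.where(~zero, 1.0)
        scaled[mods] = block.div(safe, axis=0)
    n_missing = int(missing.to_numpy().sum())
    if n_missing:
        logger.warning("fuzzy_scale: %d all-zero (taxon, group) blocks flagged missing", n_missing)
    return TraitMatrix(values=scaled, groups=dict(groups), missing=missing)


def aggregate_taxa(comm: CommunityMatrix, mapping: TaxonMapping) -> CommunityMatrix:
    """Sum abundances of raw taxa into taxon complexes.

    Per-year total abundance is conserved exactly (complexes partition taxa).
    """
    for t in comm.taxa:
        if t not in mapping.entries:
            raise MappingError(f"taxon {t!r} missing from mapping")
    grouped = comm.abundance.T.groupby(
        comm.abundance.columns.map(mapping.entries), sort=True
    ).sum().T
    return CommunityMatrix(grouped)


def abundance_to_class_mean(raw: float, scheme: AbundanceClassScheme) -> float:
    """Map a raw density to the class mean of its abundance class; 0 stays 0."""
    if raw < 0:
        raise ValidationError("abundance must be non-negative")
    if raw == 0:
        return 0.0
    for lo, hi, mean in scheme.classes:
        if lo < raw <= hi:
            return mean
    raise AssertionError("scheme does not cover the positive line")  # pragma: no cover


def discretize_community(comm: CommunityMatrix, scheme: AbundanceClassScheme) -> CommunityMatrix:
    """Apply :func:`abundance_to_class_mean` elementwise."""
    vals = comm.abundance.map(lambda x: abundance_to_class_mean(float(x), scheme))
    return CommunityMatrix(vals.astype(float))


# ---------------------------------------------------------------------------
# CSV interfaces. Trait table: two header rows (group, modality), taxon rows.
# Abundance table: wide, 'year' column + taxon columns. Mapping: two columns.
# ---------------------------------------------------------------------------

def read_trait_csv(path) -> TraitMatrix:
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    groups: dict[str, list[str]] = {}
    for g, m in df.columns:
        groups.setdefault(g, []).append(m)
    df.columns = [m for _, m in df.columns]
    return fuzzy_scale(df, groups)


def write_trait_csv(traits: TraitMatrix, path) -> None:
    cols = pd.MultiIndex.from_tuples(
        [(g, m) for g, mods in traits.groups.items() for m in mods]
    )
    out = traits.values[[m for _, m in cols]].copy()
    out.columns = cols
    out.to_csv(path, index_label="taxon")


def read_community_csv(path) -> CommunityMatrix:
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(int)
    return CommunityMatrix(df.astype(float))


def write_community_csv(comm: CommunityMatrix, path) -> None:
    comm.abundance.to_csv(path, index_label="year")


def read_mapping_csv(path) -> TaxonMapping:
    df = pd.read_csv(path)
    if df.iloc[:, 0].duplicated().any():
        raise ValidationError("raw taxon appears more than once in mapping")
    return TaxonMapping(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))
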