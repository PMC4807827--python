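"""Turnover-preserving null assemblages.

For each site the two observed seasonal assemblages define a species pool
(wet union dry). A null replicate shuffles that pool once and reads off both
seasons from the same shuffle:

* the first ``x`` species (``x`` = observed wet richness) are the wet null
  assemblage;
* the remaining ``y`` species (``y`` = observed dry-only count) are forced
  into the dry null assemblage — they are the replicate's "turnover" species;
* the dry null is completed to the observed dry richness with species drawn
  without replacement from that replicate's wet null (here: the leading
  entries of the shuffled wet prefix, whose internal order is itself uniform).

Null richness therefore matches observed richness exactly in both seasons,
and the turnover count is preserved, so any observed-vs-null FD/PD gap is
attributable to composition rather than richness.

Each site gets its own RNG stream derived from the master seed and a stable
hash of the site identifier, so adding or removing a site never perturbs the
draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, InternalError
from .io import OccurrenceTable
from .subtree import BranchLengthIndex

DEFAULT_REPLICATES = 1000


@dataclass(frozen=True)
class NullConfig:
    """Ensemble size and seeding."""

    replicates: int = DEFAULT_REPLICATES
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")


def site_rng(master_seed: int, site) -> np.random.Generator:
    """Per-site RNG stream: stable across platforms and site-set changes."""
    return np.random.default_rng([int(master_seed), zlib.crc32(str(site).encode())])


def build_pool(occ: OccurrenceTable, site) -> tuple:
    """Species pool for a site: union of its wet and dry assemblages."""
    if site not in occ.sites:
        raise InputError(f"unknown site {site!r}")
    wet = occ.assemblage(site, "wet")
    dry = occ.assemblage(site, "dry")
    return tuple(sp for sp in occ.species if sp in wet or sp in dry)


def draw_null_pair(
    pool: Sequence[str],
    wet_sr: int,
    dry_sr: int,
    dry_only_count: int,
    rng: np.random.Generator,
) -> tuple[frozenset, frozenset]:
    """One null replicate for one site.

    ``pool`` must have exactly ``wet_sr + dry_only_count`` members, and
    ``dry_only_count <= dry_sr <= len(pool)``.
    """
    pool = list(pool)
    x, y = int(wet_sr), int(dry_only_count)
    if len(pool) != x + y:
        raise InputError(
            f"pool size {len(pool)} != wet richness {x} + dry-only count {y}"
        )
    if not (y <= dry_sr <= len(pool)):
        raise InputError(
            f"dry richness {dry_sr} outside [{y}, {len(pool)}]"
        )
    perm = rng.permutation(len(pool))
    wet_null = [pool[i] for i in perm[:x]]
    forced = [pool[i] for i in perm[x:]]
    restock = wet_null[: dry_sr - y]  # uniform subset: prefix order is uniform
    return frozenset(wet_null), frozenset(forced) | frozenset(restock)


@dataclass
class SiteNull:
    """All replicates for one site, as 0/1 matrices over the site pool."""

    pool: tuple
    wet_sr: int
    dry_sr: int
    dry_only: int
    wet: np.ndarray  # (R, n_pool) bool
    dry: np.ndarray  # (R, n_pool) bool

    def replicate(self, r: int) -> tuple[frozenset, frozenset]:
        pool = np.array(self.pool, dtype=object)
        return frozenset(pool[self.wet[r]]), frozenset(pool[self.dry[r]])


@dataclass
class NullEnsemble:
    sites: tuple
    per_site: dict
    replicates: int
    seed: int

    def to_long(self) -> pd.DataFrame:
        """Long dump (site, replicate, season, species) — large for big R."""
        rows = []
        for site in self.sites:
            sn = self.per_site[site]
            for r in range(self.replicates):
                wet, dry = sn.replicate(r)
                rows.extend(
                    {"site": site, "replicate": r, "season": "wet", "species": sp}
                    for sp in sorted(wet)
                )
                rows.extend(
                    {"site": site, "replicate": r, "season": "dry", "species": sp}
                    for sp in sorted(dry)
                )
        return pd.DataFrame(rows, columns=["site", "replicate", "season", "species"])


def build_ensemble(occ: OccurrenceTable, config: NullConfig) -> NullEnsemble:
    """Draw the full null ensemble, vectorised over replicates."""
    R = config.replicates
    per_site: dict = {}
    for site in occ.sites:
        pool = build_pool(occ, site)
        n = len(pool)
        wet_obs = occ.assemblage(site, "wet")
        dry_obs = occ.assemblage(site, "dry")
        x = len(wet_obs)
        dry_sr = len(dry_obs)
        y = n - x  # dry-only species count
        rng = site_rng(config.seed, site)
        perm = rng.permuted(np.tile(np.arange(n), (R, 1)), axis=1)
        wet = np.zeros((R, n), dtype=bool)
        np.put_along_axis(wet, perm[:, :x], True, axis=1)
        dry = np.zeros((R, n), dtype=bool)
        if y:
            np.put_along_axis(dry, perm[:, x:], True, axis=1)
        restock = dry_sr - y
        if restock < 0:
            raise InputError(
                f"site {site!r}: dry richness {dry_sr} below dry-only count {y}"
            )
        if restock:
            np.put_along_axis(dry, perm[:, :restock], True, axis=1)
        if not (wet.sum(axis=1) == x).all() or not (dry.sum(axis=1) == dry_sr).all():
            raise InternalError("null richness does not match observed richness")
        per_site[site] = SiteNull(pool, x, dry_sr, y, wet, dry)
    return NullEnsemble(occ.sites, per_site, R, config.seed)


def _indicator_columns(
    index: BranchLengthIndex, pool: Sequence[str], mapping: Mapping[str, str] | None
) -> np.ndarray:
    """(n_pool,) positions of each pool species' tip in ``index`` labels."""
    pos = {lab: i for i, lab in enumerate(index.labels)}
    cols = []
    for sp in pool:
        tip = mapping[sp] if mapping is not None else sp
        if tip not in pos:
            raise InputError(f"species {sp!r} (tip {tip!r}) missing from context")
        cols.append(pos[tip])
    return np.asarray(cols, dtype=int)


def _eval_matrix(
    index: BranchLengthIndex,
    members: np.ndarray,  # (R, n_pool) bool
    cols: np.ndarray,
    include_root: bool,
) -> np.ndarray:
    T = len(index.labels)
    R = members.shape[0]
    V = np.zeros((T, R), dtype=np.float64)
    # np.maximum.at handles several pool species collapsing onto one tip
    np.maximum.at(V, cols, members.T.astype(np.float64))
    return index.subtree_length_many(V, include_root=include_root)


@dataclass
class NullEvaluation:
    """Per-replicate SR/FD/PD and seasonal change for every site."""

    sites: tuple
    replicates: int
    values: dict = field(default_factory=dict)  # site -> season -> stat -> (R,)
    change: dict = field(default_factory=dict)  # site -> stat -> (R,)

    def summary(self) -> pd.DataFrame:
        rows = []
        for site in self.sites:
            for season in ("wet", "dry"):
                for stat, arr in self.values[site][season].items():
                    rows.append(self._row(site, season, stat, arr))
            for stat, arr in self.change[site].items():
                rows.append(self._row(site, "change", stat, arr))
        return pd.DataFrame(rows)

    @staticmethod
    def _row(site, season, stat, arr):
        finite = arr[np.isfinite(arr)]
        q = (
            np.quantile(finite, [0.025, 0.5, 0.975])
            if finite.size
            else [np.nan] * 3
        )
        return {
            "site": site,
            "season": season,
            "statistic": stat,
            "mean": float(np.mean(finite)) if finite.size else np.nan,
            "sd": float(np.std(finite, ddof=1)) if finite.size > 1 else np.nan,
            "q025": float(q[0]),
            "median": float(q[1]),
            "q975": float(q[2]),
            "n_replicates": int(arr.size),
        }


def evaluate_ensemble(
    ens: NullEnsemble,
    fd_index: BranchLengthIndex | None = None,
    pd_index: BranchLengthIndex | None = None,
    species_to_tip: Mapping[str, str] | None = None,
    include_root: bool = False,
) -> NullEvaluation:
    """Evaluate SR (and FD/PD when contexts are given) over the ensemble.

    ``fd_index`` is the pool dendrogram's branch index (tips = species);
    ``pd_index`` the phylogeny's (tips = tree tips, reached via
    ``species_to_tip`` for proxy-placed species). Change statistics are
    ``dry/wet - 1`` per replicate; replicates with a zero wet value yield NaN
    and are dropped from summaries.
    """
    out = NullEvaluation(ens.sites, ens.replicates)
    for site in ens.sites:
        sn = ens.per_site[site]
        vals = {"wet": {}, "dry": {}}
        ch = {}
        R = ens.replicates
        vals["wet"]["SR"] = np.full(R, float(sn.wet_sr))
        vals["dry"]["SR"] = np.full(R, float(sn.dry_sr))
        ch["SR"] = np.full(R, sn.dry_sr / sn.wet_sr - 1.0)
        contexts = []
        if fd_index is not None:
            contexts.append(("FD", fd_index))
        if pd_index is not None:
            contexts.append(("PD", pd_index))
        for stat, index in contexts:
            mapping = species_to_tip if stat == "PD" else None
            cols = _indicator_columns(index, sn.pool, mapping)
            wet_vals = _eval_matrix(index, sn.wet, cols, include_root)
            if sn.dry_sr:
                dry_vals = _eval_matrix(index, sn.dry, cols, include_root)
            else:
                dry_vals = np.zeros(R)
            vals["wet"][stat] = wet_vals
            vals["dry"][stat] = dry_vals
            with np.errstate(divide="ignore", invalid="ignore"):
                ch[stat] = np.where(wet_vals > 0, dry_vals / wet_vals - 1.0, np.nan)
        out.values[site] = vals
        out.change[site] = ch
    return out


def observed_diversity(
    occ: OccurrenceTable,
    fd_index: BranchLengthIndex | None = None,
    pd_index: BranchLengthIndex | None = None,
    species_to_tip: Mapping[str, str] | None = None,
    include_root: bool = False,
) -> pd.DataFrame:
    """Observed SR/FD/PD per (site, season), on the same conventions."""
    rows = []
    for site in occ.sites:
        for season in ("wet", "dry"):
            members = occ.assemblage(site, season)
            row = {"site": site, "season": season, "SR": len(members)}
            if fd_index is not None:
                row["FD"] = (
                    fd_index.subtree_length(members, include_root=include_root)
                    if members
                    else 0.0
                )
            if pd_index is not None:
                if members:
                    tips = {
                        (species_to_tip[sp] if species_to_tip else sp)
                        for sp in members
                    }
                    row["PD"] = pd_index.subtree_length(
                        tips, include_root=include_root
                    )
                else:
                    row["PD"] = 0.0
            rows.append(row)
    return pd.DataFrame(rows)
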