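"""Input artifacts and their validation.

The analysis consumes four (plus one optional) plain-text artifacts:

* a two-season site x species presence/absence table (CSV, long or wide),
* a species x trait table with declared categorical/continuous types (CSV),
* a rooted, branch-length-bearing phylogeny (Newick),
* an optional species -> proxy-tip replacement map for taxa that could not
  be placed in the tree (CSV),
* optional site coordinates for spatial autocorrelation checks (CSV).

Everything is validated on construction so downstream code can assume the
invariants (0/1 indicators, non-empty wet assemblages, unique labels,
non-negative branch lengths, ...).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

SEASONS = ("wet", "dry")

_DEFAULT_SEASON_MAP = {"wet": "wet", "dry": "dry"}


def _normalise_season(label: str, season_map: Mapping[str, str] | None) -> str:
    key = str(label).strip().lower()
    mapping = dict(_DEFAULT_SEASON_MAP)
    if season_map:
        mapping.update({str(k).strip().lower(): v for k, v in season_map.items()})
    if key not in mapping or mapping[key] not in SEASONS:
        raise InputError(
            f"unknown season label {label!r}; expected one of {sorted(mapping)} "
            "(pass a season_map in the dialect to translate)"
        )
    return mapping[key]


class OccurrenceTable:
    """Site x species x season presence/absence.

    Stored as a 0/1 integer DataFrame with a (site, season) MultiIndex and one
    column per species. Site and species order is preserved as given and used
    for all downstream outputs.
    """

    def __init__(self, presence: pd.DataFrame):
        presence = presence.copy()
        if not isinstance(presence.index, pd.MultiIndex) or presence.index.nlevels != 2:
            raise ValidationError("presence table needs a (site, season) MultiIndex")
        presence.index = presence.index.set_names(["site", "season"])
        bad_season = set(presence.index.get_level_values("season")) - set(SEASONS)
        if bad_season:
            raise ValidationError(f"unknown season labels {sorted(bad_season)}")
        if presence.columns.duplicated().any():
            dupes = presence.columns[presence.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated species identifiers: {dupes}")
        values = presence.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("presence indicators must all be 0 or 1")
        presence = presence.astype(np.int8)

        sites = list(dict.fromkeys(presence.index.get_level_values("site")))
        # guarantee a row for both seasons at every site (missing -> all absent)
        full_index = pd.MultiIndex.from_product(
            [sites, SEASONS], names=["site", "season"]
        )
        presence = presence.reindex(full_index, fill_value=0)

        for site in sites:
            if presence.loc[(site, "wet")].sum() < 1:
                raise ValidationError(
                    f"site {site!r} has no wet-season species; the relative-change "
                    "statistic divides by wet-season values"
                )
        self.presence = presence
        self.sites: tuple = tuple(sites)
        self.species: tuple = tuple(presence.columns)

    @classmethod
    def from_assemblages(
        cls,
        assemblages: Mapping[tuple, Iterable[str]],
        species: Sequence[str] | None = None,
    ) -> "OccurrenceTable":
        """Build from a ``{(site, season): iterable-of-species}`` mapping."""
        sites = list(dict.fromkeys(site for site, _ in assemblages))
        if species is None:
            seen: dict = {}
            for members in assemblages.values():
                for sp in members:
                    seen[sp] = None
            species = list(seen)
        frame = pd.DataFrame(
            0,
            index=pd.MultiIndex.from_product([sites, SEASONS], names=["site", "season"]),
            columns=list(species),
            dtype=np.int8,
        )
        for (site, season), members in assemblages.items():
            for sp in members:
                frame.loc[(site, season), sp] = 1
        return cls(frame)

    def assemblage(self, site, season: str) -> frozenset:
        row = self.presence.loc[(site, season)]
        return frozenset(row.index[row.to_numpy().astype(bool)])

    def richness(self, site, season: str) -> int:
        return int(self.presence.loc[(site, season)].sum())

    def indicator(self, site, season: str) -> np.ndarray:
        """0/1 vector over ``self.species``."""
        return self.presence.loc[(site, season)].to_numpy().astype(bool)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"site": site, "season": season, "species": sp}
            for (site, season), row in self.presence.iterrows()
            for sp in row.index[row.to_numpy().astype(bool)]
        ]
        return pd.DataFrame(rows, columns=["site", "season", "species"])

    def to_wide(self) -> pd.DataFrame:
        return self.presence.reset_index()

    def __eq__(self, other) -> bool:
        if not isinstance(other, OccurrenceTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.presence.sort_index(axis=1), other.presence.sort_index(axis=1)
            )
        except AssertionError:
            return False
        return self.sites == other.sites

    def __repr__(self) -> str:
        return (
            f"OccurrenceTable({len(self.sites)} sites, {len(self.species)} species)"
        )


def read_occurrences(path, dialect: Mapping | None = None) -> OccurrenceTable:
    """Read an occurrence CSV in long (site,season,species) or wide format.

    ``dialect`` may rename columns (``{"site": "stream", ...}``) and translate
    season labels (``{"season_map": {"summer": "wet"}}``). Wide format is any
    CSV with ``site`` and ``season`` columns followed by one 0/1 column per
    species; long format is the canonical three-column form where each row
    records one presence.
    """
    dialect = dict(dialect or {})
    season_map = dialect.pop("season_map", None)
    frame = pd.read_csv(path, dtype=str)
    rename = {v: k for k, v in dialect.items() if isinstance(v, str)}
    frame = frame.rename(columns=rename)
    cols = set(frame.columns)
    if {"site", "season", "species"} <= cols:
        frame["season"] = [_normalise_season(s, season_map) for s in frame["season"]]
        dup = frame.duplicated(subset=["site", "season", "species"])
        if dup.any():
            first = frame[dup].iloc[0]
            raise InputError(
                "duplicate occurrence row "
                f"({first['site']}, {first['season']}, {first['species']})"
            )
        assemblages: dict = {}
        for _, row in frame.iterrows():
            assemblages.setdefault((row["site"], row["season"]), []).append(
                row["species"]
            )
        return OccurrenceTable.from_assemblages(assemblages)
    if {"site", "season"} <= cols:
        frame["season"] = [_normalise_season(s, season_map) for s in frame["season"]]
        if frame.duplicated(subset=["site", "season"]).any():
            raise InputError("duplicate (site, season) row in wide occurrence table")
        body = frame.set_index(["site", "season"])
        try:
            body = body.astype(float)
        except ValueError as exc:
            raise InputError(f"non-numeric presence cell in wide table: {exc}") from exc
        return OccurrenceTable(body)
    raise InputError(
        "occurrence file needs either long columns (site, season, species) or "
        f"wide columns (site, season, <species>...); found {sorted(cols)}"
    )


def write_occurrences(table: OccurrenceTable, path, fmt: str = "long") -> None:
    if fmt == "long":
        table.to_long().to_csv(path, index=False)
    elif fmt == "wide":
        table.to_wide().to_csv(path, index=False)
    else:
        raise InputError(f"unknown occurrence format {fmt!r}")


TRAIT_KINDS = ("categorical", "continuous")


class TraitTable:
    """Species x traits with per-trait declared type.

    Trait typing is always declared (``types``), never inferred: a numeric
    column may legitimately be a categorical code, and Gower dissimilarity
    treats the two kinds differently. Missing values are allowed (NaN).
    """

    def __init__(self, values: pd.DataFrame, types: Mapping[str, str]):
        values = values.copy()
        if values.index.duplicated().any():
            raise ValidationError("duplicated species in trait table")
        missing = set(values.columns) - set(types)
        if missing:
            raise ValidationError(f"traits without a declared type: {sorted(missing)}")
        for trait, kind in types.items():
            if kind not in TRAIT_KINDS:
                raise ValidationError(
                    f"trait {trait!r} has unknown type {kind!r}; "
                    f"expected one of {TRAIT_KINDS}"
                )
            if trait not in values.columns:
                raise ValidationError(f"declared trait {trait!r} not in table")
        for trait in values.columns:
            col = values[trait]
            if types[trait] == "continuous":
                col = pd.to_numeric(col, errors="raise")
                values[trait] = col.astype(float)
                observed = col.dropna()
                if observed.nunique() < 2 or observed.max() == observed.min():
                    raise ValidationError(
                        f"continuous trait {trait!r} has zero range; Gower "
                        "normalisation would divide by zero"
                    )
            else:
                observed = col.dropna()
                if observed.nunique() < 2:
                    raise ValidationError(
                        f"categorical trait {trait!r} has fewer than 2 observed levels"
                    )
        self.values = values
        self.types = dict(types)
        self.species: tuple = tuple(values.index)

    def subset(self, species: Sequence[str]) -> "TraitTable":
        return TraitTable(self.values.loc[list(species)], self.types)

    def __repr__(self) -> str:
        return f"TraitTable({len(self.species)} species, {len(self.types)} traits)"


def read_traits(path, types: Mapping[str, str] | None = None) -> TraitTable:
    """Read a trait CSV.

    The first column is the species identifier. Types are taken from an
    optional ``#type`` row directly under the header (first cell literally
    ``#type``), or from the ``types`` argument; the argument wins.
    """
    raw = pd.read_csv(path, dtype=str)
    sp_col = raw.columns[0]
    declared: dict[str, str] = {}
    if len(raw) and str(raw.iloc[0, 0]).strip() == "#type":
        declared = {c: str(raw.iloc[0][c]).strip() for c in raw.columns[1:]}
        raw = raw.iloc[1:]
    if types:
        declared.update(types)
    if not declared:
        raise InputError(
            "trait types undeclared: add a '#type' row under the header or pass "
            "types={trait: 'categorical'|'continuous'}"
        )
    frame = raw.set_index(sp_col)
    frame.index.name = "species"
    return TraitTable(frame, declared)


def write_traits(traits: TraitTable, path) -> None:
    buf = _io.StringIO()
    header = ["species"] + list(traits.values.columns)
    buf.write(",".join(header) + "\n")
    buf.write(",".join(["#type"] + [traits.types[t] for t in traits.values.columns]))
    buf.write("\n")
    traits.values.to_csv(buf, header=False)
    Path(path).write_text(buf.getvalue())


class PhyloTree:
    """Rooted phylogeny with branch lengths (wrapper around a dendropy tree)."""

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate tip labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError("tree has an edge without a branch length")
            if edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        self.tree = tree
        self.tip_labels: tuple = tuple(labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise InputError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    @property
    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        )

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:
        return f"PhyloTree({len(self.tip_labels)} tips)"


def read_tree(path) -> PhyloTree:
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def write_tree(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


@dataclass(frozen=True)
class ReplacementMap:
    """Unplaced species -> proxy tip label (many-to-one allowed)."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "mapping", dict(self.mapping))

    def resolve(self, species: str) -> str | None:
        return self.mapping.get(species)


def read_replacements(path) -> ReplacementMap:
    frame = pd.read_csv(path, dtype=str)
    if frame.shape[1] < 2:
        raise InputError("replacement map needs two columns: species, proxy")
    sp, proxy = frame.columns[:2]
    if frame[sp].duplicated().any():
        dup = frame[sp][frame[sp].duplicated()].tolist()
        raise InputError(f"species mapped more than once in replacement map: {dup}")
    return ReplacementMap(dict(zip(frame[sp], frame[proxy])))


def write_replacements(repl: ReplacementMap, path) -> None:
    pd.DataFrame(
        sorted(repl.mapping.items()), columns=["species", "proxy"]
    ).to_csv(path, index=False)


class SiteCoordinates:
    """Planar site coordinates (projected metres or decimal degrees)."""

    def __init__(self, frame: pd.DataFrame, unit: str = "m"):
        frame = frame.copy()
        needed = {"site", "x", "y"}
        if not needed <= set(frame.columns):
            raise ValidationError(f"coordinates need columns {sorted(needed)}")
        if frame["site"].duplicated().any():
            raise ValidationError("duplicate site in coordinates")
        frame["x"] = frame["x"].astype(float)
        frame["y"] = frame["y"].astype(float)
        if frame.duplicated(subset=["x", "y"]).any():
            raise ValidationError(
                "coincident site coordinates; inverse-distance weights degenerate"
            )
        if unit not in ("m", "deg"):
            raise ValidationError(f"unknown coordinate unit {unit!r}")
        self.frame = frame.reset_index(drop=True)
        self.unit = unit
        self.sites: tuple = tuple(frame["site"])

    def xy(self, sites: Sequence) -> np.ndarray:
        indexed = self.frame.set_index("site")
        missing = [s for s in sites if s not in indexed.index]
        if missing:
            raise InputError(f"sites without coordinates: {missing}")
        return indexed.loc[list(sites), ["x", "y"]].to_numpy()


def read_coordinates(path, unit: str = "m") -> SiteCoordinates:
    return SiteCoordinates(pd.read_csv(path), unit=unit)


def write_coordinates(coords: SiteCoordinates, path) -> None:
    coords.frame.to_csv(path, index=False)


@dataclass
class AnalysisBundle:
    """Reconciled inputs plus the species -> tree-tip mapping actually used."""

    occurrences: OccurrenceTable
    traits: TraitTable
    tree: PhyloTree
    species_to_tip: dict
    substitutions: pd.DataFrame  # columns: species, proxy
    shared_proxy_species: tuple  # species whose proxy tip is shared

    def tips_for(self, assemblage: Iterable[str]) -> frozenset:
        """Tree tips representing an assemblage; shared proxies collapse to one."""
        return frozenset(self.species_to_tip[sp] for sp in assemblage)


def reconcile(
    occ: OccurrenceTable,
    traits: TraitTable,
    tree: PhyloTree,
    repl: ReplacementMap | None = None,
) -> AnalysisBundle:
    """Check that every analysed species has a trait record and a tree tip.

    Species absent from the tree are routed through the replacement map to a
    proxy tip; all substitutions are reported, and species that end up sharing
    a proxy tip are flagged (they contribute a single tip to PD).
    """
    repl = repl or ReplacementMap()
    missing_traits = [sp for sp in occ.species if sp not in traits.species]
    if missing_traits:
        raise InputError(f"species missing from trait table: {missing_traits}")
    tips = set(tree.tip_labels)
    mapping: dict = {}
    subs = []
    unresolved = []
    for sp in occ.species:
        if sp in tips:
            mapping[sp] = sp
            continue
        proxy = repl.resolve(sp)
        if proxy is None:
            unresolved.append(sp)
        elif proxy not in tips:
            raise InputError(
                f"replacement for {sp!r} points to unknown tip {proxy!r}"
            )
        else:
            mapping[sp] = proxy
            subs.append({"species": sp, "proxy": proxy})
    if unresolved:
        raise InputError(
            f"species absent from tree and replacement map: {unresolved}"
        )
    counts: dict = {}
    for sp, tip in mapping.items():
        counts.setdefault(tip, []).append(sp)
    shared = tuple(
        sp for tip, members in counts.items() if len(members) > 1 for sp in members
    )
    return AnalysisBundle(
        occurrences=occ,
        traits=traits,
        tree=tree,
        species_to_tip=mapping,
        substitutions=pd.DataFrame(subs, columns=["species", "proxy"]),
        shared_proxy_species=shared,
    )
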