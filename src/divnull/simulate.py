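"""Synthetic study datasets with controlled assembly mechanisms.

The generator emulates the structure of a two-season stream-assemblage study:
a regional pool of ~31 species on an ultrametric phylogeny, mixed-type traits
with tunable phylogenetic signal, 12 sites whose wet-season assemblages hold
5-15 species and whose dry-season assemblages hold 2-12, partial seasonal
turnover, and (by default) no species found exclusively in the dry season.

Assembly scenarios:

``A``
    neutral — uniform draws and uniform dry-season loss; the null model's own
    generative process, used for type-I calibration.
``B``
    environmental filtering — wet assemblages weighted toward a site-specific
    optimum on the first continuous trait.
``C``
    limiting similarity — wet assemblages built by sequential furthest-trait
    selection; dry-season survival favours functionally distinct species
    (high FD against the null).
``D``
    phylogenetically clustered loss — dry-season survival concentrates in a
    focal clade (low PD against the null).
``CD``
    C and D together: the joint high-FD / low-PD dry-season signature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .functional import DistanceTable, gower_distance, upgma
from .io import OccurrenceTable, PhyloTree, SiteCoordinates, TraitTable
from .subtree import BranchLengthIndex

SCENARIOS = ("A", "B", "C", "D", "CD")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-design knobs; defaults reproduce the emulated field design."""

    n_sites: int = 12
    pool_size: int = 31
    wet_sr_range: tuple = (5, 15)
    dry_sr_range: tuple = (2, 12)
    scenario: str = "A"
    signal_weight: float = 0.5  # lambda-like trait signal in [0, 1]
    turnover: float = 0.3  # per-slot insertion probability (3 slots/site)
    allow_dry_exclusive: bool = False
    n_continuous: int = 4
    n_categorical: int = 2
    filter_strength: float = 4.0  # scenario B
    similarity_strength: float = 100.0  # scenarios C, CD (removal log-odds)
    clustering_strength: float = 100.0  # scenarios D, CD (removal log-odds)
    competition_share: float = 0.5  # CD: fraction of removal events that are C
    cd_tradeoff: float = 0.1  # CD: PD weight in the joint assemblage score
    cd_refinement_steps: int = 150  # CD: stochastic swap steps per site

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise InputError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        lo_w, hi_w = self.wet_sr_range
        lo_d, hi_d = self.dry_sr_range
        if not (1 <= lo_w <= hi_w <= self.pool_size):
            raise InputError(f"infeasible wet SR range {self.wet_sr_range}")
        if not (1 <= lo_d <= hi_d <= self.pool_size):
            raise InputError(f"infeasible dry SR range {self.dry_sr_range}")
        if lo_d > hi_w:
            raise InputError("dry SR minimum exceeds wet SR maximum")
        if not 0 <= self.signal_weight <= 1:
            raise InputError("signal_weight must lie in [0, 1]")
        if not 0 <= self.turnover <= 1:
            raise InputError("turnover must lie in [0, 1]")


def simulate_tree(n_tips: int, seed=None) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree scaled to unit height."""
    if n_tips < 2:
        raise InputError("a tree needs at least 2 tips")
    rng = _as_rng(seed)
    children: dict[int, list[int]] = {0: []}
    split_time = {0: 0.0}
    active = []
    next_id = 1
    for _ in range(2):
        children[0].append(next_id)
        children[next_id] = []
        active.append(next_id)
        next_id += 1
    t = 0.0
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(len(active))))
        split_time[node] = t
        for _ in range(2):
            children[node].append(next_id)
            children[next_id] = []
            active.append(next_id)
            next_id += 1
        k += 1
    total = t + rng.exponential(1.0 / n_tips)

    labels = iter(f"sp{i + 1:02d}" for i in range(n_tips))

    def newick(node: int) -> str:
        start = split_time.get(node)
        if not children[node]:
            return f"{next(labels)}:{(total - _parent_time(node)) / total:.12g}"
        parts = ",".join(newick(c) for c in children[node])
        if node == 0:
            return f"({parts})"
        return f"({parts}):{(start - _parent_time(node)) / total:.12g}"

    parent = {c: p for p, cs in children.items() for c in cs}

    def _parent_time(node: int) -> float:
        return split_time[parent[node]]

    return PhyloTree.from_newick(newick(0) + ";")


def _brownian(tree: PhyloTree, rng: np.random.Generator) -> pd.Series:
    """One Brownian-motion realisation along the tree, standardised at tips."""
    values = {}
    out = {}
    root = tree.tree.seed_node
    values[id(root)] = 0.0
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent_val = values[id(node.parent_node)]
        step = rng.normal(0.0, np.sqrt(node.edge.length or 0.0))
        values[id(node)] = parent_val + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    series = pd.Series(out)
    sd = series.std(ddof=0)
    return (series - series.mean()) / sd if sd > 0 else series * 0.0


def _latent(tree: PhyloTree, signal_weight: float, rng: np.random.Generator) -> pd.Series:
    """sqrt-mixed Brownian + independent noise: tip correlations scale with
    ``signal_weight`` like Pagel's lambda rescales a correlation matrix."""
    bm = _brownian(tree, rng)
    noise = pd.Series(rng.normal(size=len(bm)), index=bm.index)
    w = signal_weight
    x = np.sqrt(w) * bm + np.sqrt(1.0 - w) * noise
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x


def simulate_traits(
    tree: PhyloTree,
    n_continuous: int = 4,
    n_categorical: int = 2,
    signal_weight: float = 0.5,
    seed=None,
) -> TraitTable:
    """Mixed-type traits with tunable phylogenetic signal.

    Continuous traits are standardised latent variables; categorical traits
    threshold an analogous latent variable into 2-3 levels at its quantiles.
    """
    if not 0 <= signal_weight <= 1:
        raise InputError("signal_weight must lie in [0, 1]")
    if n_continuous + n_categorical < 1:
        raise InputError("need at least one trait")
    rng = _as_rng(seed)
    data = {}
    types = {}
    for i in range(n_continuous):
        name = f"cont{i + 1}"
        data[name] = _latent(tree, signal_weight, rng)
        types[name] = "continuous"
    for i in range(n_categorical):
        name = f"cat{i + 1}"
        latent = _latent(tree, signal_weight, rng)
        k = int(rng.integers(2, 4))
        qs = np.quantile(latent, np.linspace(0, 1, k + 1)[1:-1])
        codes = np.searchsorted(qs, latent, side="right")
        if len(np.unique(codes)) < 2:  # degenerate quantiles: force median split
            codes = (latent > np.median(latent)).astype(int)
        data[name] = pd.Series([f"l{c}" for c in codes], index=latent.index)
        types[name] = "categorical"
    frame = pd.DataFrame(data).loc[list(tree.tip_labels)]
    frame.index.name = "species"
    return TraitTable(frame, types)


def _gumbel_topk(
    rng: np.random.Generator, log_w: np.ndarray, k: int
) -> np.ndarray:
    """Weighted sampling of k items without replacement (Gumbel top-k trick)."""
    keys = log_w + rng.gumbel(size=log_w.size)
    return np.argsort(keys)[::-1][:k]


def _refine_joint(
    rng: np.random.Generator,
    fd_index: BranchLengthIndex,
    tree_index: BranchLengthIndex,
    n_pool: int,
    wet_idx: np.ndarray,
    survivors: np.ndarray,
    insertions: np.ndarray,
    candidates: np.ndarray,
    tradeoff: float,
    steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Hill-climb the dry set toward high FD and low PD by member swaps.

    Survivor slots swap against unused wet members, insertion slots against
    unused regional candidates, so richness and turnover count stay fixed.
    """
    surv = list(int(i) for i in survivors)
    ins = list(int(i) for i in insertions)

    def score(members: list[int]) -> float:
        v = np.zeros((n_pool, 1))
        v[members] = 1.0
        fd = fd_index.subtree_length_many(v)[0]
        pdv = tree_index.subtree_length_many(v)[0]
        return float(fd - tradeoff * pdv)

    current = score(surv + ins)
    wet_set = set(int(i) for i in wet_idx)
    cand_set = set(int(i) for i in candidates)
    for _ in range(steps):
        free_wet = list(wet_set - set(surv))
        free_cand = list(cand_set - set(ins))
        slots = (len(surv) if free_wet else 0) + (len(ins) if free_cand else 0)
        if slots == 0:
            break
        pick = int(rng.integers(slots))
        if free_wet and pick < len(surv):
            j = int(rng.integers(len(free_wet)))
            old, surv[pick] = surv[pick], free_wet[j]
            trial = score(surv + ins)
            if trial > current:
                current = trial
            else:
                surv[pick] = old
        else:
            pick = pick - (len(surv) if free_wet else 0)
            j = int(rng.integers(len(free_cand)))
            old, ins[pick] = ins[pick], free_cand[j]
            trial = score(surv + ins)
            if trial > current:
                current = trial
            else:
                ins[pick] = old
    return np.array(surv, dtype=int), np.array(ins, dtype=int)


def simulate_communities(
    tree: PhyloTree,
    traits: TraitTable,
    cfg: ScenarioConfig,
    seed=None,
) -> tuple[OccurrenceTable, SiteCoordinates]:
    """Draw wet and dry assemblages for every site under ``cfg.scenario``."""
    rng = _as_rng(seed)
    pool = list(tree.tip_labels)
    n_pool = len(pool)
    if n_pool != cfg.pool_size:
        raise InputError(
            f"tree has {n_pool} tips but config expects pool_size={cfg.pool_size}"
        )
    missing = [sp for sp in pool if sp not in traits.species]
    if missing:
        raise InputError(f"species missing from traits: {missing}")
    order = [list(traits.species).index(sp) for sp in pool]
    dist = gower_distance(traits)
    G = dist.matrix[np.ix_(order, order)]
    tree_index = BranchLengthIndex.from_dendropy(tree.tree)
    # BranchLengthIndex label order == leaf iteration order == tip_labels order
    P = tree_index.patristic_matrix()
    P = P / P.max()
    fd_index = (
        upgma(DistanceTable(pool, G)).index if cfg.scenario == "CD" else None
    )

    cont1 = None
    for name, kind in traits.types.items():
        if kind == "continuous":
            cont1 = traits.values[name].loc[pool].to_numpy(dtype=float)
            break
    if cfg.scenario == "B" and cont1 is None:
        raise InputError("scenario B needs at least one continuous trait")

    lo_w, hi_w = cfg.wet_sr_range
    lo_d, hi_d = cfg.dry_sr_range

    def draw_wet(size: int) -> np.ndarray:
        if cfg.scenario in ("A", "D"):
            return rng.choice(n_pool, size=size, replace=False)
        if cfg.scenario == "B":
            opt = rng.normal()
            logw = -cfg.filter_strength * (cont1 - opt) ** 2
            return _gumbel_topk(rng, logw, size)
        # C / CD: sequential furthest-trait (maximin Gower) selection
        chosen = [int(rng.integers(n_pool))]
        while len(chosen) < size:
            mind = G[:, chosen].min(axis=1)
            mind[chosen] = -np.inf
            best = np.flatnonzero(mind == mind.max())
            chosen.append(int(rng.choice(best)))
        return np.array(chosen)

    wet_sets = []
    for _ in range(cfg.n_sites):
        wet_sr = int(rng.integers(lo_w, hi_w + 1))
        wet_sets.append(np.sort(draw_wet(wet_sr)))
    regional_wet = np.unique(np.concatenate(wet_sets))

    assemblages: dict = {}
    for s, wet_idx in enumerate(wet_sets):
        site = f"site{s + 1:02d}"
        assemblages[(site, "wet")] = [pool[i] for i in wet_idx]
        wet_sr = wet_idx.size
        max_dry = min(hi_d, wet_sr)
        lo = min(lo_d, max_dry)
        target_dry = int(rng.integers(lo, max_dry + 1))
        source = regional_wet if not cfg.allow_dry_exclusive else np.arange(n_pool)
        candidates = np.setdiff1d(source, wet_idx)
        n_ins = int(rng.binomial(3, cfg.turnover))
        n_ins = min(n_ins, target_dry - 1, candidates.size)
        n_surv = target_dry - n_ins

        focal = int(rng.choice(wet_idx)) if cfg.scenario in ("D", "CD") else None
        if cfg.scenario in ("A", "B"):
            survivors = rng.choice(wet_idx, size=n_surv, replace=False)
        else:
            # sequential removal until the dry richness is reached; each event
            # is one mechanism's removal: limiting similarity (C) removes a
            # species with log-odds falling in its min trait distance to the
            # rest (the functionally redundant die), clustered loss (D)
            # removes one with log-odds rising in its phylogenetic distance
            # to the focal clade. Under CD the two alternate.
            remaining = list(wet_idx)
            step = 0
            while len(remaining) > n_surv:
                rem = np.array(remaining)
                if cfg.scenario == "CD":
                    mech = (
                        "C" if rng.random() < cfg.competition_share else "D"
                    )
                else:
                    mech = cfg.scenario
                if mech == "C":
                    sub = G[np.ix_(rem, rem)].copy()
                    np.fill_diagonal(sub, np.inf)
                    logw = -cfg.similarity_strength * sub.min(axis=1)
                else:
                    logw = cfg.clustering_strength * P[rem, focal]
                out = int(rem[_gumbel_topk(rng, logw, 1)[0]])
                remaining.remove(out)
                step += 1
            survivors = np.array(remaining)

        if n_ins:
            logc = np.zeros(candidates.size)
            if cfg.scenario in ("C", "CD"):
                logc += cfg.similarity_strength * G[
                    np.ix_(candidates, survivors)
                ].min(axis=1)
            if cfg.scenario in ("D", "CD"):
                logc += -cfg.clustering_strength * P[candidates, focal]
            insertions = candidates[_gumbel_topk(rng, logc, n_ins)]
        else:
            insertions = np.array([], dtype=int)
        if cfg.scenario == "CD":
            # joint refinement: when both mechanisms act at once, the realised
            # dry assemblage is driven toward high trait dispersion AND low
            # clade spread simultaneously — stochastic swaps accepted when
            # they raise FD - cd_tradeoff * PD of the whole assemblage
            survivors, insertions = _refine_joint(
                rng,
                fd_index,
                tree_index,
                n_pool,
                wet_idx,
                survivors,
                insertions,
                candidates,
                cfg.cd_tradeoff,
                cfg.cd_refinement_steps,
            )
        dry_idx = np.sort(np.concatenate([survivors, insertions]))
        assemblages[(site, "dry")] = [pool[i] for i in dry_idx]

    observed = sorted(
        {sp for members in assemblages.values() for sp in members},
        key=pool.index,
    )
    occ = OccurrenceTable.from_assemblages(assemblages, species=observed)
    coords = SiteCoordinates(
        pd.DataFrame(
            {
                "site": [f"site{s + 1:02d}" for s in range(cfg.n_sites)],
                "x": rng.uniform(0, 1000, cfg.n_sites),
                "y": rng.uniform(0, 1000, cfg.n_sites),
            }
        ),
        unit="m",
    )
    return occ, coords


@dataclass
class SyntheticDataset:
    tree: PhyloTree
    traits: TraitTable
    occurrences: OccurrenceTable
    coordinates: SiteCoordinates
    config: ScenarioConfig
    seed: int


def simulate_dataset(cfg: ScenarioConfig, seed: int = 0) -> SyntheticDataset:
    """Full dataset: tree, traits, two-season occurrences, coordinates.

    A pure function of (config, seed): sub-streams for the tree, the traits
    and the communities are spawned from one seed sequence.
    """
    ss = np.random.SeedSequence(int(seed))
    s_tree, s_traits, s_comm = ss.spawn(3)
    tree = simulate_tree(cfg.pool_size, np.random.default_rng(s_tree))
    traits = simulate_traits(
        tree,
        n_continuous=cfg.n_continuous,
        n_categorical=cfg.n_categorical,
        signal_weight=cfg.signal_weight,
        seed=np.random.default_rng(s_traits),
    )
    occ, coords = simulate_communities(
        tree, traits, cfg, seed=np.random.default_rng(s_comm)
    )
    return SyntheticDataset(tree, traits, occ, coords, cfg, int(seed))
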