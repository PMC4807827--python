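"""End-to-end orchestration: files (or a simulated dataset) in, report out.

``analyze`` runs the whole chain in memory:
read/reconcile -> Gower + UPGMA dendrogram -> pruned phylogeny -> null
ensemble -> seasonal report. ``run`` wraps it with disk I/O (result CSVs, a
JSON manifest, optional figures); ``power_study`` repeats it over many
synthetic datasets to measure the inferential layer's operating
characteristics under known truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError
from .functional import DistanceTable, fd_by_reclustering, gower_distance, upgma
from .io import (
    AnalysisBundle,
    OccurrenceTable,
    PhyloTree,
    ReplacementMap,
    SiteCoordinates,
    TraitTable,
    read_coordinates,
    read_occurrences,
    read_replacements,
    read_traits,
    read_tree,
    reconcile,
    write_coordinates,
    write_occurrences,
    write_traits,
    write_tree,
)
from .nullmodel import (
    NullConfig,
    NullEnsemble,
    build_ensemble,
    evaluate_ensemble,
    observed_diversity,
)
from .phylo import pd_index, prune_tree
from .simulate import SCENARIOS, ScenarioConfig, SyntheticDataset, simulate_dataset
from .stats import (
    SeasonalReport,
    paired_test,
    redundancy_regression,
    season_summary,
)

log = logging.getLogger("divnull")


@dataclass
class RunConfig:
    """One analysis run: either four input paths or a simulation scenario."""

    occurrences: str | None = None
    traits: str | None = None
    tree: str | None = None
    replacements: str | None = None
    coordinates: str | None = None
    simulate: str | None = None  # scenario label
    scenario: ScenarioConfig | None = None
    replicates: int = 1000
    seed: int = 0
    include_root: bool = False
    recluster: bool = False
    row_standardise: bool = False
    outdir: str = "divnull_out"
    plots: bool = False
    dump_ensemble: bool = False

    def __post_init__(self):
        has_paths = self.occurrences is not None
        has_sim = self.simulate is not None or self.scenario is not None
        if has_paths == has_sim:
            raise InputError(
                "exactly one of input paths (occurrences/traits/tree) or a "
                "simulation scenario must be given"
            )
        if has_paths and (self.traits is None or self.tree is None):
            raise InputError("file runs need occurrences, traits and tree paths")
        if self.simulate is not None and self.simulate not in SCENARIOS:
            raise InputError(f"unknown scenario {self.simulate!r}")


def _recluster_fd(ens: NullEnsemble, ev, dist: DistanceTable):
    """Replace kernel-based FD by per-assemblage re-clustered FD (slow path)."""
    for site in ens.sites:
        sn = ens.per_site[site]
        pool = np.array(sn.pool, dtype=object)
        for season, members in (("wet", sn.wet), ("dry", sn.dry)):
            vals = np.zeros(ens.replicates)
            for r in range(ens.replicates):
                sel = pool[members[r]]
                vals[r] = fd_by_reclustering(dist, sel) if sel.size else 0.0
            ev.values[site][season]["FD"] = vals
        wet, dry = ev.values[site]["wet"]["FD"], ev.values[site]["dry"]["FD"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ev.change[site]["FD"] = np.where(wet > 0, dry / wet - 1.0, np.nan)
    return ev


def analyze(
    occ: OccurrenceTable,
    traits: TraitTable,
    tree: PhyloTree,
    repl: ReplacementMap | None = None,
    coords: SiteCoordinates | None = None,
    replicates: int = 1000,
    seed: int = 0,
    include_root: bool = False,
    recluster: bool = False,
    row_standardise: bool = False,
) -> tuple[SeasonalReport, AnalysisBundle]:
    """Run the full seasonal diversity analysis in memory."""
    bundle = reconcile(occ, traits, tree, repl)
    log.info(
        "reconciled %d species over %d sites (%d proxy substitutions)",
        len(occ.species),
        len(occ.sites),
        len(bundle.substitutions),
    )
    dist = gower_distance(traits)
    dend = upgma(dist)
    tips_used = sorted(set(bundle.species_to_tip.values()))
    pruned = prune_tree(tree, tips_used)
    pdi = pd_index(pruned)
    ens = build_ensemble(occ, NullConfig(replicates=replicates, seed=seed))
    log.info("null ensemble: %d replicates x %d sites", replicates, len(occ.sites))
    ev = evaluate_ensemble(
        ens,
        fd_index=dend.index,
        pd_index=pdi,
        species_to_tip=bundle.species_to_tip,
        include_root=include_root,
    )
    obs = observed_diversity(
        occ,
        fd_index=dend.index,
        pd_index=pdi,
        species_to_tip=bundle.species_to_tip,
        include_root=include_root,
    )
    if recluster:
        log.info("re-clustering FD per assemblage (sensitivity mode)")
        ev = _recluster_fd(ens, ev, dist)
        obs = obs.copy()
        for i, row in obs.iterrows():
            members = occ.assemblage(row["site"], row["season"])
            obs.at[i, "FD"] = fd_by_reclustering(dist, members) if members else 0.0
    report = season_summary(
        obs, ev, coords=coords, row_standardise=row_standardise
    )
    report._ensemble = ens  # kept for optional dumping / plotting
    return report, bundle


def _load_inputs(cfg: RunConfig):
    occ = read_occurrences(cfg.occurrences)
    traits = read_traits(cfg.traits)
    tree = read_tree(cfg.tree)
    repl = read_replacements(cfg.replacements) if cfg.replacements else None
    coords = read_coordinates(cfg.coordinates) if cfg.coordinates else None
    return occ, traits, tree, repl, coords


def run(cfg: RunConfig) -> SeasonalReport:
    """Execute a configured run and write the report bundle to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None or cfg.scenario is not None:
        scen = cfg.scenario or ScenarioConfig(scenario=cfg.simulate)
        if cfg.simulate is not None and scen.scenario != cfg.simulate:
            scen = replace(scen, scenario=cfg.simulate)
        ds = simulate_dataset(scen, seed=cfg.seed)
        occ, traits, tree, repl, coords = (
            ds.occurrences,
            ds.traits,
            ds.tree,
            None,
            ds.coordinates,
        )
        inputs_dir = outdir / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        write_occurrences(occ, inputs_dir / "occurrences.csv")
        write_traits(traits, inputs_dir / "traits.csv")
        write_tree(tree, inputs_dir / "tree.nwk")
        write_coordinates(coords, inputs_dir / "coordinates.csv")
    else:
        occ, traits, tree, repl, coords = _load_inputs(cfg)
    report, bundle = analyze(
        occ,
        traits,
        tree,
        repl=repl,
        coords=coords,
        replicates=cfg.replicates,
        seed=cfg.seed,
        include_root=cfg.include_root,
        recluster=cfg.recluster,
        row_standardise=cfg.row_standardise,
    )
    paths = report.to_csvs(outdir)
    bundle.substitutions.to_csv(outdir / "substitutions.csv", index=False)
    if cfg.dump_ensemble:
        report._ensemble.to_long().to_csv(outdir / "null_ensemble.csv", index=False)
    if cfg.plots:
        _write_plots(report, outdir)
    manifest = {
        "package": "divnull",
        "version": __version__,
        "seed": cfg.seed,
        "replicates": cfg.replicates,
        "config": {
            k: (asdict(v) if isinstance(v, ScenarioConfig) else v)
            for k, v in asdict(cfg).items()
        },
        "outputs": {k: str(v) for k, v in paths.items()},
        "n_sites": len(occ.sites),
        "n_species": len(occ.species),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("wrote report bundle to %s", outdir)
    return report


def _write_plots(report: SeasonalReport, outdir: Path) -> None:
    """Deviation box plots and FD/PD-vs-SR scatters (one file per measure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per_site = report.per_site
    change = per_site[per_site["season"] == "change"]
    fig, ax = plt.subplots(figsize=(5, 4))
    data, labels = [], []
    for stat in ("FD", "PD"):
        if f"{stat}_null_mean" in change.columns:
            data.append((change[stat] - change[f"{stat}_null_mean"]).dropna())
            labels.append(stat)
    if data:
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.0, ls="--", c="grey")
        ax.set_ylabel("observed change - null change")
        ax.set_title("Seasonal change: deviation from null")
        fig.tight_layout()
        fig.savefig(outdir / "change_deviation.png", dpi=150)
    plt.close(fig)
    for stat in ("FD", "PD"):
        if stat not in per_site.columns:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
        for ax, season in zip(axes, ("wet", "dry")):
            sub = per_site[per_site["season"] == season]
            ax.scatter(sub["SR"], sub[stat], c="k", label="observed")
            if f"{stat}_null_mean" in sub.columns:
                ax.scatter(
                    sub["SR"],
                    sub[f"{stat}_null_mean"],
                    facecolors="none",
                    edgecolors="grey",
                    label="null mean",
                )
            ax.set_xlabel("SR")
            ax.set_title(season)
        axes[0].set_ylabel(stat)
        axes[0].legend(frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / f"{stat.lower()}_vs_sr.png", dpi=150)
        plt.close(fig)


# ---------------------------------------------------------------------------
# operating characteristics under known truth
# ---------------------------------------------------------------------------


@dataclass
class DatasetTests:
    """The per-dataset quantities the power study aggregates."""

    fd_change_p: float
    fd_change_diff: float  # mean(observed change - null change); >0 = smaller loss
    pd_change_p: float
    pd_change_diff: float
    fd_dry_p: float
    fd_dry_diff: float  # mean(observed dry FD - null mean); >0 = high FD
    pd_dry_p: float
    pd_dry_diff: float
    fd_ses_dry: float
    pd_ses_dry: float
    sr_change_mean: float
    dry_fd_redundancy: bool | None


def dataset_tests(
    ds: SyntheticDataset, replicates: int = 1000, seed: int = 0
) -> DatasetTests:
    """Push one synthetic dataset through the pipeline's inferential core.

    Leaner than :func:`analyze`: no pruning (PD is pruning-neutral), no
    Moran's I, and only the dry-season observed-FD redundancy regression.
    """
    from .subtree import BranchLengthIndex

    dend = upgma(gower_distance(ds.traits))
    pdi = BranchLengthIndex.from_dendropy(ds.tree.tree)
    occ = ds.occurrences
    ens = build_ensemble(occ, NullConfig(replicates=replicates, seed=seed))
    ev = evaluate_ensemble(ens, fd_index=dend.index, pd_index=pdi)
    obs = observed_diversity(occ, fd_index=dend.index, pd_index=pdi)
    obs_idx = obs.set_index(["site", "season"])

    sites = list(occ.sites)
    res: dict = {}
    ses = {}
    for stat in ("FD", "PD"):
        oc, nc, od, nd, sesv = [], [], [], [], []
        for site in sites:
            wet = float(obs_idx.loc[(site, "wet"), stat])
            dry = float(obs_idx.loc[(site, "dry"), stat])
            oc.append(dry / wet - 1.0 if wet > 0 else np.nan)
            arr = ev.change[site][stat]
            finite = arr[np.isfinite(arr)]
            nc.append(float(finite.mean()) if finite.size else np.nan)
            od.append(dry)
            null_dry = ev.values[site]["dry"][stat]
            m, sd = float(null_dry.mean()), float(null_dry.std(ddof=1))
            nd.append(m)
            sesv.append((dry - m) / sd if sd > 0 else np.nan)
        t_change = paired_test(oc, nc)
        t_dry = paired_test(od, nd)
        res[stat] = (t_change, t_dry)
        ses[stat] = float(np.nanmean(sesv))

    sr_changes = [
        obs_idx.loc[(s, "dry"), "SR"] / obs_idx.loc[(s, "wet"), "SR"] - 1.0
        for s in sites
    ]
    dry_sr = [float(obs_idx.loc[(s, "dry"), "SR"]) for s in sites]
    dry_fd = [float(obs_idx.loc[(s, "dry"), "FD"]) for s in sites]
    try:
        redundancy = redundancy_regression(dry_sr, dry_fd, "FD dry").redundancy
    except InputError:
        redundancy = None
    return DatasetTests(
        fd_change_p=res["FD"][0].p,
        fd_change_diff=res["FD"][0].mean_difference,
        pd_change_p=res["PD"][0].p,
        pd_change_diff=res["PD"][0].mean_difference,
        fd_dry_p=res["FD"][1].p,
        fd_dry_diff=res["FD"][1].mean_difference,
        pd_dry_p=res["PD"][1].p,
        pd_dry_diff=res["PD"][1].mean_difference,
        fd_ses_dry=ses["FD"],
        pd_ses_dry=ses["PD"],
        sr_change_mean=float(np.mean(sr_changes)),
        dry_fd_redundancy=redundancy,
    )


def power_study(
    scenarios=SCENARIOS,
    n_datasets: int = 200,
    replicates: int = 1000,
    seed: int = 0,
    base: ScenarioConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rejection rates and effect sizes per scenario over synthetic datasets.

    The joint signature column counts datasets where dry-season FD is
    significantly ABOVE its null mean and dry-season PD significantly BELOW,
    both at ``alpha``.
    """
    base = base or ScenarioConfig()
    rows = []
    for scenario in scenarios:
        cfg = replace(base, scenario=scenario)
        sub = np.random.SeedSequence((int(seed), SCENARIOS.index(scenario)))
        child_seeds = sub.generate_state(2 * n_datasets, dtype=np.uint32) & 0x7FFFFFFF
        agg = []
        for i in range(n_datasets):
            ds = simulate_dataset(cfg, seed=int(child_seeds[2 * i]))
            agg.append(
                dataset_tests(
                    ds, replicates=replicates, seed=int(child_seeds[2 * i + 1])
                )
            )
        rows.append(
            {
                "scenario": scenario,
                "n_datasets": n_datasets,
                "replicates": replicates,
                "fd_change_rejection": np.mean([a.fd_change_p < alpha for a in agg]),
                "pd_change_rejection": np.mean([a.pd_change_p < alpha for a in agg]),
                "fd_dry_high_rate": np.mean(
                    [(a.fd_dry_p < alpha) and (a.fd_dry_diff > 0) for a in agg]
                ),
                "pd_dry_low_rate": np.mean(
                    [(a.pd_dry_p < alpha) and (a.pd_dry_diff < 0) for a in agg]
                ),
                "joint_signature_rate": np.mean(
                    [
                        (a.fd_dry_p < alpha)
                        and (a.fd_dry_diff > 0)
                        and (a.pd_dry_p < alpha)
                        and (a.pd_dry_diff < 0)
                        for a in agg
                    ]
                ),
                "redundancy_detection_rate": np.mean(
                    [bool(a.dry_fd_redundancy) for a in agg if a.dry_fd_redundancy is not None]
                ),
                "mean_fd_ses_dry": np.mean([a.fd_ses_dry for a in agg]),
                "mean_pd_ses_dry": np.mean([a.pd_ses_dry for a in agg]),
                "mean_sr_change": np.mean([a.sr_change_mean for a in agg]),
            }
        )
    return pd.DataFrame(rows)
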