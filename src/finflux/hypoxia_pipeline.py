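"""Randomized oxygen-limited growth experiment.

For each sampled condition (random minimal-feed ratios plus lognormal flux
capacities), growth is predicted by parsimonious FBA over a log-spaced grid
of oxygen uptake rates up to that condition's minimal oxygen requirement at
maximal growth (r_max). Downstream steps summarize the sweep: bootstrap
confidence bands on mean relative growth, detection of limiting reactions
(flux pinned at a non-zero bound), Ward/Euclidean clustering of normalized
absolute fluxes, and hypergeometric pathway enrichment of cluster genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model, Reaction
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .chem import metabolite_mass
from .lp_engine import VALIDATION_TOLERANCE, FluxSolution, fba, pfba
from .model_core import ModelValidationError
from .synthetic_data import ConditionSample

__all__ = [
    "SweepGrid",
    "GrowthPoint",
    "run_sweep",
    "sweep_to_frame",
    "mu_rel_table",
    "normalized_flux_matrix",
    "aerobic_correction",
    "bootstrap_band",
    "detect_limiting",
    "limiting_report",
    "cluster_fluxes",
    "enrich_pathways",
]

_BIG = 1000.0
LIMITING_TOLERANCE = 1e-6


@dataclass
class SweepGrid:
    """Logarithmically spaced oxygen uptake rates in (0, r_max].

    The top point equals r_max (so relative growth reaches 1); zero is
    excluded. ``r_rel`` values are shared across conditions even though the
    absolute rates differ.
    """

    o2_rates: np.ndarray
    r_max: float

    @classmethod
    def from_r_max(cls, r_max: float, n_levels: int = 50,
                   span_decades: float = 2.0) -> "SweepGrid":
        if r_max <= 0:
            raise ModelValidationError(f"r_max must be positive, got {r_max}")
        rates = r_max * np.logspace(-span_decades, 0.0, n_levels)
        return cls(o2_rates=rates, r_max=float(r_max))

    def validate(self) -> None:
        r = np.asarray(self.o2_rates, dtype=float)
        if not (np.all(np.diff(r) > 0) and r[0] > 0 and r[-1] <= self.r_max * (1 + 1e-9)):
            raise ModelValidationError(
                "o2_rates must be strictly increasing within (0, r_max]"
            )


@dataclass
class GrowthPoint:
    """One pFBA solution of the sweep: condition x oxygen level."""

    condition_id: int
    r: float
    r_rel: float
    mu: float
    mu_rel: float
    status: str
    level: int = -1
    fluxes: dict[str, float] = field(default_factory=dict)
    limiting: frozenset[str] = frozenset()


def _apply_condition(model: Model, condition: ConditionSample,
                     feed_total_mass: float,
                     free_uptakes: tuple[str, ...] = ()) -> str:
    """Impose a sampled condition on the (context-managed) model.

    Adds the condition's feed reaction (1 g of nutrients per unit flux,
    capped at ``feed_total_mass``), closes all uptakes except phosphate,
    oxygen and water, closes secretion of feed nutrients, and replaces the
    capacity bound of every sampled reaction direction. Returns the feed
    reaction id.
    """
    total = sum(
        ratio * metabolite_mass(n) for n, ratio in condition.feed_ratios.items()
    )
    feed = Reaction("FEED_CONDITION")
    stoich = {}
    for nutrient, ratio in condition.feed_ratios.items():
        mass = metabolite_mass(nutrient)
        met = model.metabolites.get_by_id(f"{nutrient}_e")
        stoich[met] = 1000.0 * (ratio * mass / total) / mass
    feed.add_metabolites(stoich)
    feed.bounds = (0.0, feed_total_mass)
    model.add_reactions([feed])

    for rxn in model.boundary:
        (met,) = rxn.metabolites
        base = met.id.rsplit("_", 1)[0]
        if base == "h2o":
            rxn.bounds = (-1e6, 1e6)  # water is never the binding constraint
        elif base == "pi" or base in free_uptakes:
            rxn.lower_bound = -_BIG
        elif base == "o2":
            pass  # set per grid level
        else:
            rxn.lower_bound = 0.0
        if base in condition.feed_ratios:
            rxn.upper_bound = 0.0  # no secretion of feed nutrients

    for (rid, direction), bound in condition.bound_samples.items():
        rxn = model.reactions.get_by_id(rid)
        if direction == "forward":
            rxn.upper_bound = bound
        else:
            rxn.lower_bound = -bound
    return feed.id


def run_sweep(
    model: Model,
    conditions: list[ConditionSample],
    n_levels: int = 50,
    feed_total_mass: float = 10.0,
    o2_exchange: str = "EX_o2_e",
    keep_fluxes: bool = True,
    detect: bool = True,
    free_uptakes: tuple[str, ...] = (),
) -> list[GrowthPoint]:
    """pFBA growth predictions across conditions and oxygen levels.

    Per condition the unconstrained-oxygen optimum (mu_max) and minimal
    oxygen requirement (r_max) are computed first; the oxygen exchange is
    then capped at each grid rate and parsimonious fluxes recorded.
    Infeasible or zero-growth points are kept with their status.
    ``free_uptakes`` lists extra nutrients with unlimited import outside the
    feed bundle (e.g. choline in a fish-meal experiment).
    """
    points: list[GrowthPoint] = []
    for cid, condition in enumerate(conditions):
        with model as m:
            _apply_condition(m, condition, feed_total_mass, free_uptakes)
            ex = m.reactions.get_by_id(o2_exchange)
            ex.lower_bound = -_BIG
            free = fba(m)
            if not free.optimal or free.objective_value <= VALIDATION_TOLERANCE:
                points.append(GrowthPoint(cid, np.nan, np.nan, 0.0, 0.0,
                                          "zero_growth"))
                continue
            mu_max = free.objective_value
            growth_rxn = [r for r in m.reactions if r.objective_coefficient][0]
            growth_rxn.lower_bound = mu_max * (1 - 1e-9)
            min_o2 = fba(m, objective=o2_exchange, sense="max")
            r_max = max(-min_o2.fluxes[o2_exchange], VALIDATION_TOLERANCE)
            growth_rxn.lower_bound = 0.0
            grid = SweepGrid.from_r_max(r_max, n_levels)
            for level, r in enumerate(grid.o2_rates):
                ex.lower_bound = -r
                sol = pfba(m)
                if not sol.optimal:
                    points.append(GrowthPoint(cid, float(r), float(r / r_max),
                                              np.nan, np.nan, sol.status, level))
                    continue
                mu = sol.objective_value
                lim = detect_limiting(sol, m) if detect else frozenset()
                points.append(GrowthPoint(
                    condition_id=cid,
                    r=float(r),
                    r_rel=float(r / r_max),
                    mu=float(mu),
                    mu_rel=float(mu / mu_max),
                    status="optimal",
                    level=level,
                    fluxes=dict(sol.fluxes) if keep_fluxes else {},
                    limiting=lim,
                ))
    return points


def sweep_to_frame(points: list[GrowthPoint]) -> pd.DataFrame:
    """Long-form sweep table (condition, r, r_rel, mu, mu_rel, status)."""
    return pd.DataFrame(
        {
            "condition_id": [p.condition_id for p in points],
            "level": [p.level for p in points],
            "r": [p.r for p in points],
            "r_rel": [p.r_rel for p in points],
            "mu": [p.mu for p in points],
            "mu_rel": [p.mu_rel for p in points],
            "status": [p.status for p in points],
        }
    )


def mu_rel_table(points: list[GrowthPoint]) -> pd.DataFrame:
    """Condition x oxygen-level table of relative growth (optimal points)."""
    df = sweep_to_frame(points)
    df = df[df["status"] == "optimal"]
    return df.pivot_table(index="condition_id", columns="level", values="mu_rel")


def aerobic_correction(points: list[GrowthPoint],
                       anaerobic_mu: float) -> list[GrowthPoint]:
    """Subtract the zero-oxygen growth rate to isolate aerobic growth.

    ``anaerobic_mu`` is the FBA optimum at zero oxygen uptake for the same
    feed. Corrected rates are floored at zero and relative growth is
    renormalized against the corrected maximum.
    """
    if anaerobic_mu < 0:
        raise ModelValidationError("anaerobic_mu must be non-negative")
    by_condition: dict[int, float] = {}
    for p in points:
        if p.status == "optimal":
            mu_corr = max(0.0, p.mu - anaerobic_mu)
            by_condition[p.condition_id] = max(
                by_condition.get(p.condition_id, 0.0), mu_corr
            )
    corrected = []
    for p in points:
        if p.status != "optimal":
            corrected.append(p)
            continue
        mu_corr = max(0.0, p.mu - anaerobic_mu)
        top = by_condition.get(p.condition_id, 0.0)
        corrected.append(GrowthPoint(
            condition_id=p.condition_id, r=p.r, r_rel=p.r_rel, mu=mu_corr,
            mu_rel=mu_corr / top if top > 0 else 0.0,
            status=p.status, level=p.level, fluxes=p.fluxes,
            limiting=p.limiting,
        ))
    return corrected


def bootstrap_band(
    values: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Percentile-bootstrap confidence band of the across-condition mean.

    ``values`` is a condition x level table (rows are conditions). Returns a
    DataFrame indexed by level with columns mean/lower/upper; with a single
    condition the band degenerates to the mean and is flagged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ModelValidationError("values must be a 2-D condition x level table")
    n_cond = arr.shape[0]
    mean = np.nanmean(arr, axis=0)
    out = pd.DataFrame({"mean": mean}, index=values.columns)
    if n_cond < 2:
        out["lower"] = mean
        out["upper"] = mean
        out.attrs["degenerate"] = True
        return out
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_cond, size=(n_boot, n_cond))
    boot_means = np.nanmean(arr[idx, :], axis=1)  # (n_boot, n_levels)
    alpha = (1.0 - level) / 2.0
    out["lower"] = np.nanpercentile(boot_means, 100 * alpha, axis=0)
    out["upper"] = np.nanpercentile(boot_means, 100 * (1 - alpha), axis=0)
    out.attrs["degenerate"] = False
    return out


def detect_limiting(solution: FluxSolution, model: Model,
                    tolerance: float = LIMITING_TOLERANCE) -> frozenset[str]:
    """Reactions whose flux sits within ``tolerance`` of a non-zero bound.

    Zero bounds never flag (a closed reaction is not limiting); bounds are
    read from the model as currently constrained.
    """
    limiting = set()
    for rxn in model.reactions:
        v = solution.fluxes.get(rxn.id)
        if v is None:
            continue
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if lb != 0 and abs(v - lb) <= tolerance:
            limiting.add(rxn.id)
        elif ub != 0 and abs(v - ub) <= tolerance:
            limiting.add(rxn.id)
    return frozenset(limiting)


def limiting_report(points: list[GrowthPoint]) -> pd.Series:
    """Count, per reaction, how many sweep solutions it limited."""
    counts: dict[str, int] = {}
    for p in points:
        for rid in p.limiting:
            counts[rid] = counts.get(rid, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def normalized_flux_matrix(points: list[GrowthPoint]) -> pd.DataFrame:
    """Absolute fluxes normalized per reaction to its maximum within each
    condition (columns ordered by condition then oxygen rate; all-zero
    reaction/condition blocks map to 0)."""
    ok = [p for p in points if p.status == "optimal" and p.fluxes]
    if not ok:
        raise ModelValidationError("no optimal sweep points with stored fluxes")
    reactions = sorted({rid for p in ok for rid in p.fluxes})
    cols = []
    data = []
    for p in sorted(ok, key=lambda q: (q.condition_id, q.level)):
        cols.append((p.condition_id, p.level))
        data.append([abs(p.fluxes.get(rid, 0.0)) for rid in reactions])
    mat = pd.DataFrame(
        np.asarray(data, dtype=float).T, index=reactions,
        columns=pd.MultiIndex.from_tuples(cols, names=["condition_id", "level"]),
    )
    for cid in mat.columns.get_level_values(0).unique():
        block = mat.loc[:, cid]
        peak = block.max(axis=1)
        peak[peak == 0] = 1.0
        mat.loc[:, cid] = block.div(peak, axis=0).values
    return mat


def cluster_fluxes(points: list[GrowthPoint], n_clusters: int = 8) -> pd.Series:
    """Ward/Euclidean clustering of normalized absolute flux profiles.

    Returns reaction id -> cluster label (1..n_clusters). Requires at least
    ``n_clusters`` reactions with a non-zero flux somewhere in the sweep.
    Assignment is invariant to reaction input order (rows are sorted).
    """
    mat = normalized_flux_matrix(points)
    active = mat.index[(mat != 0).any(axis=1)]
    if len(active) < n_clusters:
        raise ModelValidationError(
            f"only {len(active)} active reactions for {n_clusters} clusters"
        )
    sub = mat.loc[active]
    Z = linkage(sub.values, method="ward", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=active, name="cluster")


def enrich_pathways(
    cluster_genes: set[str],
    pathway_genes: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric pathway enrichment with BH adjustment.

    For each pathway, tests over-representation of ``cluster_genes`` (drawn
    from ``background``) in the pathway's gene set; ``recall`` is the
    fraction of the pathway's genes found in the cluster.
    """
    if not background:
        raise ModelValidationError("background gene set is empty")
    if not set(cluster_genes) <= set(background):
        raise ModelValidationError("cluster_genes must be a subset of background")
    N = len(background)
    n = len(cluster_genes)
    rows = []
    for pathway, genes in pathway_genes.items():
        in_bg = set(genes) & set(background)
        K = len(in_bg)
        k = len(set(cluster_genes) & in_bg)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({
            "pathway": pathway, "overlap": k, "pathway_size": K,
            "p": min(1.0, p), "recall": k / K if K else 0.0,
        })
    table = pd.DataFrame(rows).set_index("pathway")
    if len(table):
        table["p_adjusted"] = multipletests(table["p"].values, method="fdr_bh")[1]
        table["enriched"] = table["p_adjusted"] <= alpha
    return table.sort_values("p")
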