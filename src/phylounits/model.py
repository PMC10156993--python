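"""Model-style front end: fit the spatial-unit evaluation to a site table.

``SpatialUnitModel`` bundles a site table (and optionally a unit partition,
phylogenetic tree and covariate table) and, on ``fit()``, runs the full
evaluation: per-unit majority clades, fixed-unit accuracy, the 25-run
Voronoi benchmark, and the one-sample t comparison. The returned
``SpatialUnitResults`` carries the estimates and diagnostics and prints a
summary table; Mantel correlations against geography, elevation and
covariates are available when a tree is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DistanceMatrix, Site, UnitPartition, frame_to_sites
from .phylo import CladeTree
from .spatial import Metric, assign_units, geodesic_matrix
from .stats import MantelResult, TTestResult, mantel
from .unit_eval import (DEFAULT_TRAIN_FRACTIONS, ExperimentTable, MajorityMap,
                        UnitAccuracy, compare_units, majority_map,
                        unit_accuracy, voronoi_experiment)

__all__ = ["SpatialUnitModel", "SpatialUnitResults"]


class SpatialUnitModel:
    """Majority-clade spatial-unit model for a phylogeographic survey.

    Parameters
    ----------
    sites
        Site records carrying coordinates and clade labels. If a
        ``partition`` is given, unit membership is (re)derived by
        point-in-polygon assignment; otherwise the sites' existing
        ``watershed_id`` labels are used.
    partition
        Optional unit polygons (watersheds, grid cells, ...).
    tree
        Optional clade tree whose tips are site ids; enables Mantel
        diagnostics of phylogenetic vs geographic/environmental distance.
    covariates
        Optional per-site environmental table indexed by site id.
    """

    def __init__(self, sites: Sequence[Site], partition: UnitPartition | None = None,
                 tree: CladeTree | None = None,
                 covariates: pd.DataFrame | None = None):
        sites = list(sites)
        if not sites:
            raise ValueError("no sites supplied")
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site ids must be unique")
        if partition is not None:
            assignments, unassigned = assign_units(sites, partition)
            sites = [s.with_unit(assignments[s.site_id])
                     for s in sites if s.site_id in assignments]
        self.sites = sites
        self.partition = partition
        self.tree = tree
        self.covariates = covariates

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, partition: UnitPartition | None = None,
                       tree: CladeTree | None = None,
                       covariates: pd.DataFrame | None = None) -> "SpatialUnitModel":
        """Build from a site table with columns site_id, lat, lon and
        (optionally) elevation, watershed_id, clade, strain_id."""
        return cls(frame_to_sites(frame), partition=partition, tree=tree,
                   covariates=covariates)

    def fit(self, train_fractions: Sequence[float] = DEFAULT_TRAIN_FRACTIONS,
            iterations: int = 5, metric: Metric = "planar",
            seed: int | None = None) -> "SpatialUnitResults":
        """Run the unit evaluation and Voronoi benchmark."""
        labelled = [s for s in self.sites if s.clade and s.watershed_id]
        if not labelled:
            raise ValueError("no sites with both a unit and a clade label")
        mm = majority_map(labelled)
        ua = unit_accuracy(labelled, mm)
        table = voronoi_experiment(labelled, fractions=train_fractions,
                                   iterations=iterations, metric=metric, seed=seed)
        ttest = compare_units(ua.accuracy, table)
        return SpatialUnitResults(model=self, majority=mm, unit_result=ua,
                                  benchmark=table, comparison=ttest,
                                  metric=metric, seed=seed)


@dataclass
class SpatialUnitResults:
    """Fitted spatial-unit evaluation.

    Attributes
    ----------
    unit_result
        Fixed-unit (e.g. watershed) majority-clade accuracy with per-unit
        breakdown.
    benchmark
        The Voronoi training/testing experiment table.
    comparison
        One-sample t-test of the benchmark accuracies against the
        fixed-unit accuracy (negative mean_diff: Voronoi is worse).
    """

    model: SpatialUnitModel
    majority: MajorityMap
    unit_result: UnitAccuracy
    benchmark: ExperimentTable
    comparison: TTestResult
    metric: str
    seed: int | None
    _mantel_cache: dict = field(default_factory=dict, repr=False)

    @property
    def unit_accuracy(self) -> float:
        return self.unit_result.accuracy

    @property
    def benchmark_mean_accuracy(self) -> float:
        return float(self.benchmark.accuracies.mean())

    def mantel_tests(self, n_perm: int = 999, seed: int | None = None,
                     ) -> pd.DataFrame:
        """Mantel correlations of patristic distance against geographic
        distance, elevation difference, and each covariate's absolute
        difference (one test per factor, no multiplicity correction)."""
        if self.model.tree is None:
            raise ValueError("a tree is required for Mantel diagnostics")
        key = (n_perm, seed)
        if key in self._mantel_cache:
            return self._mantel_cache[key]
        sites = {s.site_id: s for s in self.model.sites}
        pat = self.model.tree.patristic_matrix()
        labels = [t for t in pat.labels if t in sites]
        pat = pat.reorder(labels)
        sel = [sites[t] for t in labels]
        factors: dict[str, DistanceMatrix] = {
            "geography_km": DistanceMatrix(labels, geodesic_matrix(
                [s.lat for s in sel], [s.lon for s in sel])),
            "elevation_m": _absdiff_matrix(labels, [s.elevation for s in sel]),
        }
        cov = self.model.covariates
        if cov is not None:
            for col in cov.columns:
                vals = cov.loc[labels, col].to_numpy(dtype=float)
                factors[col] = _absdiff_matrix(labels, vals)
        rng = np.random.default_rng(seed)
        rows = []
        for name, dm in factors.items():
            res: MantelResult = mantel(pat, dm, n_perm=n_perm,
                                       seed=int(rng.integers(2 ** 31)))
            rows.append({"factor": name, "r": res.r, "p_value": res.p_value,
                         "n": res.n, "n_perm": res.n_perm})
        out = pd.DataFrame(rows)
        self._mantel_cache[key] = out
        return out

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        ua, tt = self.unit_result, self.comparison
        s = self.benchmark.summary
        kind = self.model.partition.kind if self.model.partition else "watershed"
        lines = [
            "Spatial-unit evaluation of clade distribution",
            "=" * 60,
            f"Sites: {ua.n_sites}    units: {len(self.majority.mapping)} ({kind})"
            f"    clades: {len(set(self.majority.mapping.values()))}",
            "",
            f"Fixed-unit majority-clade accuracy: {ua.accuracy:.2f}"
            f"  (error rate {ua.error_rate:.2f})",
            f"Voronoi benchmark ({len(self.benchmark.runs)} runs, metric={self.metric}):"
            f" mean {s['mean']:.2f}  median {s['median']:.2f}"
            f"  min {s['min']:.2f}  max {s['max']:.2f}",
            "",
            "Comparison (one-sample t, benchmark vs fixed units):",
            f"  t = {tt.t:.2f}  |t| = {tt.abs_t:.2f}  df = {tt.df:.0f}"
            f"  discrepancy = {tt.mean_diff:.2f}  p = {_fmt_p(tt.p_value)}",
            "",
            "Per-unit breakdown:",
        ]
        for _, row in ua.per_unit.iterrows():
            lines.append(f"  {row['unit_id']:>8}  majority={self.majority[row['unit_id']]}"
                         f"  n={int(row['n_sites']):>4}  accuracy={row['accuracy']:.2f}")
        return "\n".join(lines)

    def plot_map(self, ax=None):
        """Plot unit polygons and sites coloured by clade (plain export)."""
        from .plotting import plot_units
        return plot_units(self.model.partition, self.model.sites, ax=ax)


def _absdiff_matrix(labels, values) -> DistanceMatrix:
    v = np.asarray(values, dtype=float)
    return DistanceMatrix(labels, np.abs(v[:, None] - v[None, :]))


def _fmt_p(p: float) -> str:
    return f"{p:.4f}" if p >= 1e-4 else f"{p:.2e}"
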