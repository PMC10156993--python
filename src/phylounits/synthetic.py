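"""Watershed-structured synthetic datasets.

The generator emulates the statistical structure of a watershed
phylogeography survey: sites placed with complete spatial randomness over a
rectangular study region tiled by contiguous "watershed" polygons, one
dominant phylogenetic clade per watershed, a rooted tree with deep
between-clade and shallow within-clade divergence, and climate-like
covariates that follow smooth spatial gradients.

Defaults mirror the motivating survey of the nematode-trapping fungus
*Arthrobotrys oligospora* across Yunnan's six major river watersheds:
149 sites, 6 watersheds, 5 clades with per-watershed majority-clade
probabilities (0.674, 0.633, 0.659, 0.833, 0.667), and the last two
watersheds sharing the fifth clade (one watershed has no clade of its own).

Watershed polygons are nearest-seed (Voronoi) tessellations of random seed
points — only the partition property matters downstream, not hydrological
realism. All randomness flows from a single integer seed through one
``numpy`` SeedSequence, consumed in the fixed order: watersheds, sites,
tree, covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .core import Site, UnitPartition, sites_to_frame
from .phylo import CladeTree
from .spatial import assign_units

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "generate_watersheds",
    "generate_sites",
    "generate_tree",
    "generate_covariates",
    "generate_dataset",
]

#: Study-region bounding box (lon_min, lat_min, lon_max, lat_max), degrees.
DEFAULT_BBOX = (97.5, 21.1, 106.2, 29.3)

#: Per-watershed probability that a site carries its watershed's majority
#: clade; the first five values are the observed clade-consistency levels,
#: the sixth covers the watershed that shares the fifth clade.
DEFAULT_MAJORITY_PROB = (0.674, 0.633, 0.659, 0.833, 0.667, 0.667)


@dataclass(frozen=True)
class CovariateSpec:
    """Linear spatial gradient for one synthetic covariate.

    covariate = intercept + coef_lon·lon + coef_lat·lat + coef_elev·elev
    + Normal(0, noise_sd).
    """

    coef_lon: float = 0.0
    coef_lat: float = 0.0
    coef_elev: float = 0.0
    noise_sd: float = 0.0
    intercept: float = 0.0


#: Climate-like defaults: two temperature-type factors (latitude gradient,
#: elevation lapse rate of −6.5 °C/km) and two precipitation-type factors
#: (longitude and latitude gradients), each with moderate local noise.
DEFAULT_COVARIATES: dict[str, CovariateSpec] = {
    "bio4": CovariateSpec(coef_lat=45.0, coef_elev=0.02, noise_sd=25.0, intercept=400.0),
    "bio5": CovariateSpec(coef_lat=-0.4, coef_elev=-0.0065, noise_sd=0.8, intercept=42.0),
    "bio15": CovariateSpec(coef_lon=-2.5, coef_lat=1.5, noise_sd=3.0, intercept=330.0),
    "bio16": CovariateSpec(coef_lon=25.0, coef_lat=-30.0, coef_elev=-0.05,
                           noise_sd=40.0, intercept=1500.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic watershed-phylogeography generator."""

    n_sites: int = 149
    n_watersheds: int = 6
    n_clades: int = 5
    majority_prob: tuple[float, ...] = DEFAULT_MAJORITY_PROB
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    between_clade_depth: float = 0.05
    within_clade_depth: float = 0.005
    covariate_gradients: Mapping[str, CovariateSpec] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES))
    elevation_noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_watersheds < 1:
            raise ValueError("n_watersheds must be at least 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")
        if self.n_clades < 1:
            raise ValueError("n_clades must be at least 1")
        lon0, lat0, lon1, lat1 = self.bbox
        if not (lon1 > lon0 and lat1 > lat0):
            raise ValueError("bbox must be non-degenerate")
        p = self.majority_prob
        if np.isscalar(p):
            object.__setattr__(self, "majority_prob", (float(p),) * self.n_watersheds)
        else:
            object.__setattr__(self, "majority_prob", tuple(float(x) for x in p))
        if len(self.majority_prob) != self.n_watersheds:
            raise ValueError("majority_prob must have one entry per watershed")
        for x in self.majority_prob:
            if not (1.0 / self.n_clades <= x <= 1.0):
                raise ValueError(
                    f"majority_prob {x} must lie in [1/n_clades={1 / self.n_clades:.3f}, 1] "
                    "so the designated clade is the modal expectation")
        if self.between_clade_depth < 0 or self.within_clade_depth < 0:
            raise ValueError("tree depths must be non-negative")

    @property
    def clade_labels(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_clades)]

    @property
    def watershed_ids(self) -> list[str]:
        width = len(str(self.n_watersheds))
        return [f"W{i + 1:0{width}d}" for i in range(self.n_watersheds)]

    @property
    def designated_clades(self) -> dict[str, str]:
        """Fixed watershed→majority-clade map: a bijection for the first
        min(n_clades, n_watersheds) watersheds; extra watersheds reuse the
        last clade (a merged unit without a clade of its own)."""
        clades = self.clade_labels
        return {w: clades[min(i, self.n_clades - 1)]
                for i, w in enumerate(self.watershed_ids)}

    def _rngs(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return [np.random.default_rng(c) for c in children]


@dataclass
class SyntheticDataset:
    """A complete synthetic survey: sites, watershed partition, tree,
    covariates, plus the generating configuration."""

    config: SimulationConfig
    sites: list[Site]
    partition: UnitPartition
    tree: CladeTree
    covariates: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        """Write sites.csv, watersheds.geojson, tree.nwk, covariates.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sites": outdir / "sites.csv",
            "partition": outdir / "watersheds.geojson",
            "tree": outdir / "tree.nwk",
            "covariates": outdir / "covariates.csv",
        }
        sites_to_frame(self.sites).to_csv(paths["sites"], index=False)
        self.partition.write_geojson(paths["partition"])
        self.tree.write_newick(paths["tree"])
        self.covariates.to_csv(paths["covariates"], index_label="site_id",
                               float_format="%.10g")
        return paths


def generate_watersheds(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> UnitPartition:
    """Tile the bbox with nearest-seed (Voronoi) polygons.

    Seed points are drawn uniformly in the bbox; the resulting polygons
    partition the bbox exactly (no gaps, no overlaps).
    """
    rng = rng if rng is not None else config._rngs()[0]
    lon0, lat0, lon1, lat1 = config.bbox
    window = box(lon0, lat0, lon1, lat1)
    ids = config.watershed_ids
    if config.n_watersheds == 1:
        return UnitPartition(units={ids[0]: window}, kind="watershed")
    seeds = np.column_stack([rng.uniform(lon0, lon1, config.n_watersheds),
                             rng.uniform(lat0, lat1, config.n_watersheds)])
    cells = voronoi_diagram(MultiPoint(seeds.tolist()), envelope=window)
    units: dict[str, object] = {}
    remaining = list(cells.geoms)
    for wid, (sx, sy) in zip(ids, seeds):
        for k, cell in enumerate(remaining):
            if cell.covers(Point(sx, sy)):
                units[wid] = cell.intersection(window)
                remaining.pop(k)
                break
        else:  # pragma: no cover - degenerate coincident seeds
            raise RuntimeError("Voronoi cell matching failed; coincident seeds?")
    return UnitPartition(units=units, kind="watershed")


def generate_sites(config: SimulationConfig, partition: UnitPartition,
                   rng: np.random.Generator | None = None) -> list[Site]:
    """Place sites uniformly (CSR) in the bbox and label their clades.

    Each site gets its containing watershed and a clade drawn as: with
    probability ``majority_prob[w]`` the watershed's designated clade,
    otherwise uniform over the remaining clades. Elevation is a smooth
    function of the coordinates plus Gaussian noise.
    """
    rng = rng if rng is not None else config._rngs()[1]
    lon0, lat0, lon1, lat1 = config.bbox
    n = config.n_sites
    lons = rng.uniform(lon0, lon1, n)
    lats = rng.uniform(lat0, lat1, n)
    elevs = _smooth_elevation(lons, lats, config.bbox)
    elevs = elevs + rng.normal(0.0, config.elevation_noise_sd, n)
    bare = [Site(site_id=f"site{i + 1:03d}", lat=float(lats[i]), lon=float(lons[i]),
                 elevation=float(round(elevs[i], 1)))
            for i in range(n)]
    assignments, unassigned = assign_units(bare, partition)
    if unassigned:  # cannot happen when the partition tiles the bbox
        raise RuntimeError(f"sites outside the partition: {unassigned}")
    p_by_unit = dict(zip(config.watershed_ids, config.majority_prob))
    designated = config.designated_clades
    clades = config.clade_labels
    sites = []
    for i, s in enumerate(bare):
        wid = assignments[s.site_id]
        major = designated[wid]
        if rng.random() < p_by_unit[wid] or config.n_clades == 1:
            clade = major
        else:
            others = [c for c in clades if c != major]
            clade = others[rng.integers(len(others))]
        sites.append(Site(site_id=s.site_id, lat=s.lat, lon=s.lon,
                          elevation=s.elevation, watershed_id=wid, clade=clade,
                          strain_id=f"strain{i + 1:03d}"))
    return sites


def _smooth_elevation(lons: np.ndarray, lats: np.ndarray,
                      bbox: tuple[float, float, float, float]) -> np.ndarray:
    """Mountain-plateau surface: ~800–3500 m over the study region."""
    lon0, lat0, lon1, lat1 = bbox
    u = (lons - lon0) / (lon1 - lon0)
    v = (lats - lat0) / (lat1 - lat0)
    return 2000.0 + 1200.0 * np.sin(np.pi * u) * np.cos(np.pi * v) + 600.0 * (v - 0.5)


def generate_tree(sites: Sequence[Site], config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> CladeTree:
    """Rooted tree with one subtree per clade present among the sites.

    A star backbone joins the clade ancestors to the root with pendant
    length ``between_clade_depth``; each ancestor subtends a random
    coalescent-topology ultrametric subtree of total depth
    ``within_clade_depth`` over that clade's tips (tips named by site_id).
    Clades with no sites are simply absent. With a single clade present the
    subtree itself is returned (no degree-one root).
    """
    rng = rng if rng is not None else config._rngs()[2]
    by_clade: dict[str, list[str]] = {}
    for s in sites:
        if not s.clade:
            raise ValueError(f"site {s.site_id!r} has no clade label")
        by_clade.setdefault(s.clade, []).append(s.site_id)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    present = [c for c in sorted(by_clade)]
    subtrees = [_coalescent_subtree(by_clade[c], config.within_clade_depth, rng, taxa)
                for c in present]
    if len(subtrees) == 1:
        tree.seed_node = subtrees[0]
    else:
        for node in subtrees:
            node.edge.length = config.between_clade_depth
            tree.seed_node.add_child(node)
    ct = CladeTree(tree)
    ct.clade_map = {c: frozenset(by_clade[c]) for c in present}
    return ct


def _coalescent_subtree(tip_names: list[str], depth: float,
                        rng: np.random.Generator,
                        taxa: dendropy.TaxonNamespace) -> dendropy.Node:
    """Random-topology ultrametric subtree with all tips at ``depth``."""
    nodes: list[tuple[dendropy.Node, float]] = []
    for name in tip_names:
        leaf = dendropy.Node()
        leaf.taxon = taxa.new_taxon(label=name)
        nodes.append((leaf, 0.0))
    if len(nodes) == 1:
        node, _ = nodes[0]
        node.edge.length = depth
        return node
    # Kingman-style coalescent heights, rescaled so the subtree root is at
    # exactly `depth`.
    t = 0.0
    heights: list[float] = []
    merges: list[tuple[int, int]] = []
    k = len(nodes)
    avail = list(range(k))
    while len(avail) > 1:
        m = len(avail)
        t += rng.exponential(2.0 / (m * (m - 1)))
        i, j = sorted(rng.choice(len(avail), size=2, replace=False))
        merges.append((avail[i], avail[j]))
        heights.append(t)
        avail[i] = k + len(merges) - 1
        avail.pop(j)
    scale = depth / t if t > 0 else 0.0
    all_nodes = [n for n, _ in nodes]
    all_heights = [0.0] * k
    for (a, b), h in zip(merges, heights):
        parent = dendropy.Node()
        h_scaled = h * scale
        for child_idx in (a, b):
            child = all_nodes[child_idx]
            child.edge.length = h_scaled - all_heights[child_idx]
            parent.add_child(child)
        all_nodes.append(parent)
        all_heights.append(h_scaled)
    return all_nodes[-1]


def generate_covariates(sites: Sequence[Site], config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-site covariate table: linear gradients in (lon, lat, elevation)
    plus Gaussian noise, one column per configured covariate."""
    rng = rng if rng is not None else config._rngs()[3]
    lons = np.array([s.lon for s in sites])
    lats = np.array([s.lat for s in sites])
    elevs = np.array([s.elevation for s in sites])
    data = {}
    for name, spec in config.covariate_gradients.items():
        base = (spec.intercept + spec.coef_lon * lons + spec.coef_lat * lats
                + spec.coef_elev * elevs)
        noise = rng.normal(0.0, spec.noise_sd, len(sites)) if spec.noise_sd > 0 else 0.0
        data[name] = base + noise
    return pd.DataFrame(data, index=pd.Index([s.site_id for s in sites], name="site_id"))


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all four generation stages under the config's single seed."""
    rng_w, rng_s, rng_t, rng_c = config._rngs()
    partition = generate_watersheds(config, rng_w)
    sites = generate_sites(config, partition, rng_s)
    tree = generate_tree(sites, config, rng_t)
    covariates = generate_covariates(sites, config, rng_c)
    return SyntheticDataset(config=config, sites=sites, partition=partition,
                            tree=tree, covariates=covariates)
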