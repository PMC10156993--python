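"""Reference values from the motivating watershed survey.

These are the published summary numbers of a province-wide survey of the
nematode-trapping fungus *Arthrobotrys oligospora* across Yunnan's six major
river watersheds: 2,250 samples at 228 sites, 149 sequenced strains falling
into five phylogenetic clades. Site-level coordinates and clade assignments
were not released, so these printed summaries are the only real-data inputs
the package can consume; everything else runs on synthetic data.
"""

from __future__ import annotations

from .unit_eval import ExperimentTable, RunRecord

__all__ = [
    "N_SITES_TOTAL",
    "N_SITES_OCCUPIED",
    "N_STRAINS",
    "WATERSHED_ACCURACY",
    "CLADE_WATERSHED_CONSISTENCY",
    "GENE_FLOW_MEAN",
    "GENE_FLOW_SD",
    "VORONOI_BENCHMARK_ROWS",
    "voronoi_benchmark_table",
]

#: Sites surveyed / sites where the fungus occurred.
N_SITES_TOTAL = 228
N_SITES_OCCUPIED = 193

#: Strains sequenced (one per occupied site passing quality control).
N_STRAINS = 149

#: Majority-clade classification accuracy with watersheds as units.
WATERSHED_ACCURACY = 0.68

#: Fraction of each clade's strains found in its corresponding watershed
#: (clades 1–5 → Jinsha, Red, Pearl, Lancang, Nujiang–Irrawaddy).
CLADE_WATERSHED_CONSISTENCY = {
    "C1": 0.674, "C2": 0.633, "C3": 0.659, "C4": 0.833, "C5": 0.667,
}

#: Between-clade gene-flow (Nm) summary: all pairs below 1.
GENE_FLOW_MEAN = 0.38
GENE_FLOW_SD = 0.28

#: The 25 published Voronoi benchmark runs:
#: (run_id, n_train, n_test, n_correct, reported_accuracy).
#: Accuracy is n_correct over all 149 strains, rounded to 2 decimals.
VORONOI_BENCHMARK_ROWS: list[tuple[str, int, int, int, float]] = [
    ("V1", 11, 138, 57, 0.38),
    ("V2", 10, 139, 53, 0.36),
    ("V3", 11, 138, 61, 0.41),
    ("V4", 10, 139, 61, 0.41),
    ("V5", 11, 138, 53, 0.36),
    ("V6", 25, 124, 66, 0.44),
    ("V7", 25, 124, 69, 0.46),
    ("V8", 26, 123, 64, 0.43),
    ("V9", 24, 125, 60, 0.40),
    ("V10", 26, 123, 76, 0.51),
    ("V11", 41, 108, 72, 0.48),
    ("V12", 41, 108, 77, 0.52),
    ("V13", 39, 110, 80, 0.54),
    ("V14", 38, 111, 74, 0.50),
    ("V15", 38, 111, 72, 0.48),
    ("V16", 55, 94, 89, 0.60),
    ("V17", 53, 96, 92, 0.62),
    ("V18", 53, 96, 90, 0.60),
    ("V19", 54, 95, 83, 0.56),
    ("V20", 55, 94, 82, 0.55),
    ("V21", 70, 79, 85, 0.57),
    ("V22", 65, 84, 70, 0.47),
    ("V23", 58, 91, 95, 0.64),
    ("V24", 62, 87, 92, 0.62),
    ("V25", 62, 87, 76, 0.51),
]


def voronoi_benchmark_table() -> ExperimentTable:
    """The published 25-run Voronoi benchmark as an :class:`ExperimentTable`."""
    runs = [RunRecord(run_id=rid, n_train=tr, n_test=te, n_correct=cor)
            for rid, tr, te, cor, _acc in VORONOI_BENCHMARK_ROWS]
    return ExperimentTable(runs=runs)
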