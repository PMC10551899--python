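"""Canonical simulation scenarios.

These are the study conditions used throughout the package's validation:
a neutral (no-selection) scan for null calibration, a planted
interface/aggregation scan for parameter recovery, and a depletion-only
scan for replicate sampling-noise structure. Cell and read numbers are
chosen so that FACS throughput (millions of cells over a sorting session)
rather than sequencing is the limiting sample size, as in real sort-seq
screens; the library skew and noise defaults come from the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NaiveLibrary, PhenotypeParams, ReferenceProtein, SortSpec, VariantKey, codon_for
from .counts import counts_from_simulation
from .scores import conservation_scores, enrichment_ratios
from .simulate import DEFAULT_EFFECTS, EffectClass, SortResult, assign_phenotypes, build_ssm_library, simulate_replicates, simulate_sort

_AA_NO_M = "ACDEFGHIKLNPQRSTVWY"


def demo_reference(n_residues: int = 10, seed: int = 0, name: str = "demo") -> ReferenceProtein:
    """A deterministic pseudo-random reference ORF starting with Met."""
    rng = np.random.default_rng(seed)
    aa = "M" + "".join(rng.choice(list(_AA_NO_M), size=n_residues - 1))
    cds = "ATG" + "".join(codon_for(a) for a in aa[1:])
    return ReferenceProtein(name, aa, cds)


@dataclass
class ScanRun:
    """A simulated scan with its ground truth and scored replicates."""

    reference: ReferenceProtein
    library: NaiveLibrary
    phenotypes: PhenotypeParams
    replicates: list[SortResult]
    bifc_tables: list[pd.DataFrame]
    expression_tables: list[pd.DataFrame]

    @property
    def labels(self) -> dict[VariantKey, str]:
        return self.phenotypes.labels()

    def conservation(self, selection: str = "bifc") -> pd.DataFrame:
        tables = self.bifc_tables if selection == "bifc" else self.expression_tables
        return conservation_scores(tables)


def _score(reps: list[SortResult], pseudocount: float = 0.5) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    bifc, expr = [], []
    for i, rep in enumerate(reps, start=1):
        nav = counts_from_simulation(rep, "naive", replicate=str(i))
        bifc.append(enrichment_ratios(nav, counts_from_simulation(rep, "bifc", replicate=str(i)), pseudocount))
        expr.append(enrichment_ratios(nav, counts_from_simulation(rep, "expression", replicate=str(i)), pseudocount))
    return bifc, expr


def neutral_scan(
    seed: int = 0,
    n_residues: int = 10,
    n_cells: int = 2_000_000,
    n_reads: int = 1_000_000,
) -> ScanRun:
    """All-neutral scan: every variant behaves like wild type, so the only
    structure left is gate and sequencing sampling noise. Used to check
    that enrichment ratios are centred on zero under the null."""
    ref = demo_reference(n_residues)
    lib = build_ssm_library(ref, seed=seed)
    phen = assign_phenotypes(lib, {"neutral": EffectClass("neutral", proportion=1.0)}, seed=seed)
    sim = simulate_sort(lib, phen, SortSpec(n_cells=n_cells, n_reads_per_condition=n_reads), seed=seed + 1)
    bifc, expr = _score([sim])
    return ScanRun(ref, lib, phen, [sim], bifc, expr)


def interface_recovery_scan(
    seed: int = 0,
    n_residues: int = 10,
    interface_positions: frozenset[int] = frozenset({2, 3, 4}),
    aggregating_fraction: float = 0.08,
    n_cells: int = 4_000_000,
    n_reads: int = 2_000_000,
) -> ScanRun:
    """Planted-truth scan for recovery tests: all variants at the
    interface positions disrupt specific dimerization; a fixed fraction of
    the remaining variants aggregate nonspecifically; the rest are
    neutral. Two sorting replicates are simulated at deep cell and read
    sampling so recovery is limited by the method, not by shot noise."""
    ref = demo_reference(n_residues)
    lib = build_ssm_library(ref, seed=seed)
    rng = np.random.default_rng(seed + 100)
    assignments: dict[VariantKey, str] = {}
    rest = []
    for v in lib.variants:
        if v.position in interface_positions:
            assignments[v] = "interface"
        else:
            rest.append(v)
    n_agg = round(aggregating_fraction * len(lib.variants))
    for i in rng.choice(len(rest), size=n_agg, replace=False):
        assignments[rest[i]] = "aggregating"
    phen = assign_phenotypes(lib, dict(DEFAULT_EFFECTS), seed=seed + 1, assignments=assignments)
    reps = simulate_replicates(
        lib, phen, SortSpec(n_cells=n_cells, n_reads_per_condition=n_reads), seed=seed + 2
    )
    bifc, expr = _score(reps)
    return ScanRun(ref, lib, phen, reps, bifc, expr)


def sampling_noise_scan(
    seed: int = 0,
    n_residues: int = 30,
    skew: float = 2.0,
    n_cells: int = 1_000_000,
    n_reads: int = 500_000,
) -> ScanRun:
    """Depletion-only scan for replicate-concordance structure: interface
    residues (3-9) and microdomain-clustering tail residues (26-29) are
    planted, with no aggregating class, so between-replicate disagreement
    is dominated by how deeply each variant was sampled during sorting.
    The stronger library skew puts a usable number of mutations into the
    rare (naive frequency < 5e-5) stratum."""
    ref = demo_reference(n_residues, name="demo30")
    lib = build_ssm_library(ref, skew=skew, seed=seed)
    iface = set(range(3, 10))
    clust = set(range(26, 30))
    assignments = {}
    for v in lib.variants:
        if v.position in iface:
            assignments[v] = "interface"
        elif v.position in clust:
            assignments[v] = "clustering"
    phen = assign_phenotypes(lib, dict(DEFAULT_EFFECTS), seed=seed + 1, assignments=assignments)
    reps = simulate_replicates(
        lib, phen, SortSpec(n_cells=n_cells, n_reads_per_condition=n_reads), seed=seed + 2
    )
    bifc, expr = _score(reps)
    return ScanRun(ref, lib, phen, reps, bifc, expr)
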