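"""Ground-truthed sort-seq simulator.

Emulates a single-site saturation mutagenesis library expressed one variant
per cell, sorted by FACS through a surface-expression gate and a rank-based
top-fraction BiFC gate, then sequenced as amplicon fragments. Every stage is
seeded, so downstream modules can be tested against known ground truth
without any external data.

Signal model (per cell carrying variant v):

    E = expr_v * eps_E                          (expression channel)
    B = expr_v * (alpha*dimer_v + beta*clust_v + gamma*agg_v) * eps_B

with eps_E, eps_B independent lognormal noise of median 1 and coefficient
of variation ``cv_noise``. The expression gate keeps cells with E above an
absolute threshold (or a top quantile); the BiFC gate keeps the top
``bifc_top_fraction`` of expression-gated cells ranked by B/E (ties broken
by cell index). Reads are multinomial samples of each condition's cell
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .core import (
    Fragment,
    NaiveLibrary,
    PhenotypeParams,
    ReferenceProtein,
    SortSpec,
    ValidationError,
    VariantKey,
    VariantPhenotype,
    check_alphabet,
    check_fragments,
    codon_for,
)

AA_ALPHABET_DEFAULT = "ACDEFGHIKLMNPQRSTVWY"

CONDITIONS = ("naive", "expression", "bifc")


class EmptyGateError(RuntimeError):
    """A FACS gate collected zero cells."""


# ---------------------------------------------------------------------------
# library construction


def build_ssm_library(
    ref: ReferenceProtein,
    alphabet: str = AA_ALPHABET_DEFAULT,
    skew: float = 1.5,
    wt_fraction: float = 0.05,
    seed: int = 0,
) -> NaiveLibrary:
    """Build a naive SSM library with lognormally skewed variant frequencies.

    One variant per (position, mut_aa) pair with mut_aa != wt_aa. Raw
    abundances are i.i.d. lognormal(0, skew^2) and normalised so the
    variants sum to 1 - wt_fraction; skew = 0 gives a perfectly even
    library. The skewed default mirrors the large variation in mutation
    frequency typical of real naive plasmid libraries.
    """
    check_alphabet(alphabet)
    if skew < 0:
        raise ValidationError("skew must be >= 0")
    if not 0 < wt_fraction < 1:
        raise ValidationError("wt_fraction must lie in (0, 1)")
    variants = ref.all_variants(alphabet)
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, skew, size=len(variants)))
    freqs = raw / raw.sum() * (1.0 - wt_fraction)
    return NaiveLibrary(ref, dict(zip(variants, freqs.tolist())), wt_fraction)


# ---------------------------------------------------------------------------
# phenotype assignment


@dataclass(frozen=True)
class EffectClass:
    """One phenotype class in an effect specification.

    Each parameter is either a scalar applied to every member or a
    (low, high) pair sampled uniformly per variant. ``proportion`` is the
    fraction of variants assigned to the class when no explicit assignment
    map is given.
    """

    name: str
    proportion: float = 0.0
    expr: float | tuple[float, float] = 1.0
    dimer: float | tuple[float, float] = 1.0
    agg: float | tuple[float, float] = 0.0
    clust: float | tuple[float, float] = 1.0


#: canonical effect classes: structurally neutral variants; destabilised
#: variants that aggregate nonspecifically in the membrane; variants that
#: break the specific oligomer interface; tail variants that lose lipid
#: microdomain clustering.
DEFAULT_EFFECTS: dict[str, EffectClass] = {
    "neutral": EffectClass("neutral"),
    "aggregating": EffectClass("aggregating", expr=0.7, agg=5.0),
    "interface": EffectClass("interface", dimer=0.2),
    "clustering": EffectClass("clustering", clust=0.1),
}


def _draw(value: float | tuple[float, float], rng: np.random.Generator) -> float:
    if isinstance(value, tuple):
        lo, hi = value
        return float(rng.uniform(lo, hi))
    return float(value)


def assign_phenotypes(
    lib: NaiveLibrary,
    effect_spec: dict[str, EffectClass],
    seed: int = 0,
    assignments: dict[VariantKey, str] | None = None,
    alpha: float = 1.0,
    beta: float = 0.5,
    gamma: float = 1.0,
    cv_noise: float = 0.5,
) -> PhenotypeParams:
    """Assign each library variant to one effect class and return ground truth.

    Without an explicit ``assignments`` map, classes are allotted by their
    proportions with largest-remainder rounding and distributed over a
    seeded permutation of the variants. Class labels are retained on each
    variant's phenotype so recovery tests can compare calls to truth.
    """
    rng = np.random.default_rng(seed)
    variants = lib.variants
    if assignments is None:
        names = list(effect_spec)
        props = np.array([effect_spec[n].proportion for n in names], dtype=float)
        if props.sum() <= 0:
            raise ValidationError("effect_spec proportions must sum to a positive value")
        props = props / props.sum()
        n = len(variants)
        quota = props * n
        counts = np.floor(quota).astype(int)
        remainder = n - counts.sum()
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:remainder]] += 1
        labels = np.repeat(names, counts)
        perm = rng.permutation(n)
        assignments = {variants[i]: labels[j] for j, i in enumerate(perm)}
    phen: dict[VariantKey, VariantPhenotype] = {}
    for v in variants:
        cls_name = assignments.get(v, "neutral")
        if cls_name not in effect_spec:
            raise ValidationError(f"unknown effect class {cls_name!r} for variant {v}")
        cls = effect_spec[cls_name]
        phen[v] = VariantPhenotype(
            expr=_draw(cls.expr, rng),
            dimer=_draw(cls.dimer, rng),
            agg=_draw(cls.agg, rng),
            clust=_draw(cls.clust, rng),
            label=cls.name,
        )
    return PhenotypeParams(phen, alpha=alpha, beta=beta, gamma=gamma, cv_noise=cv_noise)


# ---------------------------------------------------------------------------
# FACS sort


@dataclass
class ConditionCounts:
    cells: dict[VariantKey | None, int]
    reads: dict[VariantKey | None, int]


@dataclass
class SortResult:
    """Cell and read counts per condition (None key = wild type)."""

    reference: ReferenceProtein
    conditions: dict[str, ConditionCounts]
    n_expression_gate: int
    n_bifc_gate: int
    expr_threshold_used: float


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def simulate_sort(
    lib: NaiveLibrary,
    phen: PhenotypeParams,
    sort: SortSpec,
    seed: int = 0,
) -> SortResult:
    """Simulate one sorting experiment: naive, expression-gated, BiFC-gated.

    Cells are assigned genotypes by a single multinomial draw (one variant
    per cell). The BiFC gate is exact rank selection: it collects
    round(bifc_top_fraction x expression-gate size) cells.
    """
    variants = lib.variants
    missing = [v for v in variants if v not in phen.variants]
    if missing:
        raise ValidationError(f"phenotypes missing for {len(missing)} library variants")
    genotypes: list[VariantKey | None] = [None] + variants
    p = np.array([lib.wt_fraction] + [lib.frequencies[v] for v in variants])
    expr = np.array([1.0] + [phen.variants[v].expr for v in variants])
    factor = np.array(
        [phen.bifc_factor(VariantPhenotype())]
        + [phen.bifc_factor(phen.variants[v]) for v in variants]
    )

    rng = np.random.default_rng(seed)
    cell_counts = rng.multinomial(sort.n_cells, p / p.sum())
    g = np.repeat(np.arange(len(genotypes)), cell_counts)
    sigma = _lognormal_sigma(phen.cv_noise)
    eps_e = np.exp(sigma * rng.standard_normal(sort.n_cells)) if sigma > 0 else np.ones(sort.n_cells)
    eps_b = np.exp(sigma * rng.standard_normal(sort.n_cells)) if sigma > 0 else np.ones(sort.n_cells)
    e_sig = expr[g] * eps_e
    b_sig = expr[g] * factor[g] * eps_b

    if sort.expr_gate_quantile is None:
        threshold = sort.expr_threshold
        gated = np.flatnonzero(e_sig > threshold)
    else:
        k = int(math.floor(sort.expr_gate_quantile * sort.n_cells + 0.5))
        order = np.argsort(-e_sig, kind="stable")
        gated = np.sort(order[:k])
        threshold = float(e_sig[order[k - 1]]) if k else float("inf")
    if gated.size == 0:
        raise EmptyGateError("expression gate collected zero cells")

    score = b_sig[gated] / e_sig[gated] if sort.bifc_rank_on == "ratio" else b_sig[gated]
    k_bifc = int(math.floor(sort.bifc_top_fraction * gated.size + 0.5))
    if k_bifc == 0:
        raise EmptyGateError("BiFC gate collected zero cells")
    top = gated[np.argsort(-score, kind="stable")[:k_bifc]]

    n_geno = len(genotypes)
    cond_cells = {
        "naive": cell_counts,
        "expression": np.bincount(g[gated], minlength=n_geno),
        "bifc": np.bincount(g[top], minlength=n_geno),
    }
    conditions: dict[str, ConditionCounts] = {}
    for name in CONDITIONS:
        cells = cond_cells[name]
        total = int(cells.sum())
        reads = rng.multinomial(sort.n_reads_per_condition, cells / total)
        conditions[name] = ConditionCounts(
            cells={gt: int(c) for gt, c in zip(genotypes, cells)},
            reads={gt: int(c) for gt, c in zip(genotypes, reads)},
        )
    return SortResult(
        reference=lib.reference,
        conditions=conditions,
        n_expression_gate=int(gated.size),
        n_bifc_gate=int(k_bifc),
        expr_threshold_used=float(threshold),
    )


def simulate_replicates(
    lib: NaiveLibrary,
    phen: PhenotypeParams,
    sort: SortSpec,
    seed: int = 0,
    n_replicates: int = 2,
    share_naive: bool = True,
) -> list[SortResult]:
    """Independent sorting replicates of the same transfected library.

    With ``share_naive`` (default) all replicates are compared against a
    single naive sequencing run, as when one plasmid library preparation
    is sequenced once.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    reps = [simulate_sort(lib, phen, sort, seed=int(s)) for s in child_seeds]
    if share_naive:
        for rep in reps[1:]:
            rep.conditions["naive"] = reps[0].conditions["naive"]
    return reps


# ---------------------------------------------------------------------------
# read emission


def _variant_read(ref: ReferenceProtein, fr: Fragment, v: VariantKey | None) -> str:
    seq = ref.cds[fr.start - 1 : fr.end]
    if v is None:
        return seq
    off = 3 * (v.position - 1) - (fr.start - 1)
    return seq[:off] + codon_for(v.mut_aa) + seq[off + 3 :]


def emit_reads(
    read_counts: dict[VariantKey | None, int],
    ref: ReferenceProtein,
    fragments: list[Fragment],
    error_rate: float = 0.0,
    seed: int = 0,
    out_path: str = "reads.fastq",
    condition: str = "condition",
) -> dict[str, int]:
    """Write one condition's reads as FASTQ, one fragment per read.

    Each variant's reads are split multinomially across the fragments whose
    codon-aligned interval contains its codon (wild-type reads across all
    fragments); the read carries the variant's deterministic codon
    substitution plus i.i.d. base substitution errors at ``error_rate``.
    Base quality is Phred 40 ('I') except at introduced errors (Phred 2).
    Returns emission statistics, including the number of error bases
    introduced.
    """
    check_fragments(ref, fragments)
    if error_rate < 0 or error_rate >= 1:
        raise ValidationError("error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    records = []
    n_errors = 0
    serial = 0
    for gt, n in read_counts.items():
        if n <= 0:
            continue
        if gt is None:
            covering = fragments
        else:
            covering = [fr for fr in fragments if fr.covers(gt.position)]
            if not covering:
                raise ValidationError(f"variant {gt} lies outside all fragments")
        split = rng.multinomial(n, np.full(len(covering), 1.0 / len(covering)))
        for fr, m in zip(covering, split):
            if m == 0:
                continue
            template = _variant_read(ref, fr, gt)
            length = len(template)
            err_counts = rng.binomial(length, error_rate, size=m) if error_rate else np.zeros(m, dtype=int)
            for i in range(m):
                seq = template
                qual = [40] * length
                k = int(err_counts[i])
                if k:
                    pos = rng.choice(length, size=k, replace=False)
                    chars = list(seq)
                    for pj in pos:
                        alternatives = [b for b in bases if b != chars[pj]]
                        chars[pj] = alternatives[rng.integers(0, 3)]
                        qual[pj] = 2
                    seq = "".join(chars)
                    n_errors += k
                rec = SeqRecord(
                    Seq(seq),
                    id=f"{condition}:{fr.name}:{fr.start}-{fr.end}:{serial}",
                    description="",
                )
                rec.letter_annotations["phred_quality"] = qual
                records.append(rec)
                serial += 1
    with open(out_path, "w") as fh:
        seqio_write(records, fh, "fastq")
    return {"n_reads": serial, "n_errors": n_errors}


def emit_condition_fastqs(
    sim: SortResult,
    fragments: list[Fragment],
    error_rate: float = 0.0,
    seed: int = 0,
    outdir: str = ".",
) -> dict[str, str]:
    """Write a FASTQ per condition of a simulated sort; returns paths."""
    import os

    rng = np.random.default_rng(seed)
    paths = {}
    for name in CONDITIONS:
        path = os.path.join(outdir, f"{name}.fastq")
        emit_reads(
            sim.conditions[name].reads,
            sim.reference,
            fragments,
            error_rate=error_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            out_path=path,
            condition=name,
        )
        paths[name] = path
    return paths
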