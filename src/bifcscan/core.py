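"""Domain types shared across the pipeline.

The package analyses sort-seq deep mutational scans of membrane receptors:
a single-site saturation mutagenesis (SSM) library is expressed one variant
per cell, cells are sorted by FACS through an expression gate and a
high-BiFC gate, and each sorted population is sequenced. The types here
describe the reference protein, single amino-acid substitutions, the naive
(unselected) library composition, the simulator's ground-truth phenotypes,
and the sort configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

#: sentinel written to the temperature-factor field of unmatched residues
UNMAPPED_BFACTOR = 99.0


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class VariantKey(NamedTuple):
    """A single amino-acid substitution in a named reference protein.

    position is a 1-based residue index counted from the initiator Met;
    wt_aa and mut_aa are one-letter codes with mut_aa != wt_aa.
    """

    position: int
    wt_aa: str
    mut_aa: str

    def __str__(self) -> str:  # e.g. "I204W"
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class ReferenceProtein:
    """A reference open reading frame: protein sequence plus its CDS.

    The CDS must translate exactly to ``aa_sequence`` (standard code,
    no stop included) and the protein must be at least 10 residues.
    """

    name: str
    aa_sequence: str
    cds: str

    def __post_init__(self) -> None:
        if len(self.aa_sequence) < 10:
            raise ValidationError(f"reference protein must be >=10 residues, got {len(self.aa_sequence)}")
        if len(self.cds) != 3 * len(self.aa_sequence):
            raise ValidationError("CDS length must be 3 x protein length")
        translated = str(Seq(self.cds).translate())
        if translated != self.aa_sequence:
            raise ValidationError(f"CDS does not translate to the stated protein sequence ({translated!r})")

    def __len__(self) -> int:
        return len(self.aa_sequence)

    def wt_aa(self, position: int) -> str:
        if not 1 <= position <= len(self):
            raise ValidationError(f"position {position} outside 1..{len(self)}")
        return self.aa_sequence[position - 1]

    def wt_codon(self, position: int) -> str:
        return self.cds[3 * (position - 1) : 3 * position]

    def validate_variant(self, v: VariantKey) -> VariantKey:
        wt = self.wt_aa(v.position)
        if v.wt_aa != wt:
            raise ValidationError(f"variant {v}: reference residue at {v.position} is {wt}, not {v.wt_aa}")
        if v.mut_aa == v.wt_aa:
            raise ValidationError(f"variant {v}: mutant equals wild type")
        return v

    def all_variants(self, alphabet: str = AA_ALPHABET) -> list[VariantKey]:
        """Every (position, mut_aa) substitution with mut_aa != wt_aa."""
        return [
            VariantKey(pos, wt, aa)
            for pos, wt in enumerate(self.aa_sequence, start=1)
            for aa in alphabet
            if aa != wt
        ]


def check_alphabet(alphabet: str) -> str:
    allowed = set(AA_ALPHABET + STOP)
    if not alphabet:
        raise ValidationError("alphabet must be nonempty")
    bad = set(alphabet) - allowed
    if bad:
        raise ValidationError(f"alphabet contains characters outside the amino-acid code: {sorted(bad)}")
    if len(set(alphabet)) != len(alphabet):
        raise ValidationError("alphabet contains duplicates")
    return alphabet


def codon_for(mut_aa: str) -> str:
    """Deterministic codon for an amino acid: the alphabetically lowest
    standard-table codon (TAA for a stop)."""
    if mut_aa == STOP:
        return "TAA"
    codons = sorted(c for c, aa in standard_dna_table.forward_table.items() if aa == mut_aa)
    if not codons:
        raise ValidationError(f"no codon encodes {mut_aa!r}")
    return codons[0]


@dataclass(frozen=True)
class NaiveLibrary:
    """Unselected SSM library composition: per-variant fractions plus the
    wild-type carryover fraction. Fractions sum to 1."""

    reference: ReferenceProtein
    frequencies: dict[VariantKey, float]
    wt_fraction: float

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.frequencies.values()):
            raise ValidationError("variant frequencies must be nonnegative")
        total = self.wt_fraction + sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"frequencies + wt_fraction must sum to 1, got {total}")

    @property
    def variants(self) -> list[VariantKey]:
        return list(self.frequencies)


@dataclass(frozen=True)
class VariantPhenotype:
    """Ground-truth multipliers for one variant.

    expr scales surface expression (WT = 1); dimer scales specific oligomer
    assembly (WT = 1); clust scales lipid-microdomain clustering (WT = 1);
    agg is an aggregation propensity added on top (WT = 0).
    """

    expr: float = 1.0
    dimer: float = 1.0
    agg: float = 0.0
    clust: float = 1.0
    label: str = "neutral"

    def __post_init__(self) -> None:
        for name in ("expr", "dimer", "agg", "clust"):
            x = getattr(self, name)
            if not (x >= 0 and x < float("inf")):
                raise ValidationError(f"phenotype parameter {name} must be finite and nonnegative")


WT_PHENOTYPE = VariantPhenotype()


@dataclass(frozen=True)
class PhenotypeParams:
    """Ground truth for a simulated scan.

    Per-cell signals are built as
        expression  E = expr * noise,
        BiFC        B = expr * (alpha*dimer + beta*clust + gamma*agg) * noise,
    with independent lognormal noise of coefficient of variation cv_noise
    on each channel. alpha, beta and gamma weight the three association
    mechanisms (specific dimerization, microdomain clustering, nonspecific
    aggregation) in the BiFC signal.
    """

    variants: dict[VariantKey, VariantPhenotype]
    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 1.0
    cv_noise: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "cv_noise"):
            x = getattr(self, name)
            if not (x >= 0 and x < float("inf")):
                raise ValidationError(f"{name} must be finite and nonnegative")

    def bifc_factor(self, p: VariantPhenotype) -> float:
        return self.alpha * p.dimer + self.beta * p.clust + self.gamma * p.agg

    def labels(self) -> dict[VariantKey, str]:
        return {v: p.label for v, p in self.variants.items()}


@dataclass(frozen=True)
class SortSpec:
    """FACS sort and sequencing configuration.

    By default the expression gate is an absolute threshold on the
    expression signal chosen so that wild-type cells pass (expr_threshold
    on the WT-median-1 scale); setting expr_gate_quantile instead keeps the
    top fraction of cells by expression signal. The BiFC gate is rank
    based: within the expression gate, the top bifc_top_fraction of cells
    by BiFC/expression signal ratio (or raw BiFC signal when
    bifc_rank_on="signal") are collected.
    """

    n_cells: int = 100_000
    n_reads_per_condition: int = 1_000_000
    bifc_top_fraction: float = 0.05
    expr_gate_quantile: float | None = None
    expr_threshold: float = 0.25
    bifc_rank_on: str = "ratio"
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be positive")
        if self.n_reads_per_condition < 1:
            raise ValidationError("n_reads_per_condition must be >= 1")
        if not 0 < self.bifc_top_fraction < 1:
            raise ValidationError("bifc_top_fraction must lie in (0, 1)")
        if self.bifc_rank_on not in ("ratio", "signal"):
            raise ValidationError("bifc_rank_on must be 'ratio' or 'signal'")
        if self.read_error_rate < 0:
            raise ValidationError("read_error_rate must be >= 0")


@dataclass(frozen=True)
class Fragment:
    """A codon-aligned amplicon interval on the CDS, 1-based inclusive
    nucleotide coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"fragment {self.name}: bad interval {self.start}-{self.end}")
        if (self.start - 1) % 3 or self.end % 3:
            raise ValidationError(f"fragment {self.name}: interval must be codon aligned")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def residue_positions(self) -> range:
        """1-based residue positions whose codons lie fully inside."""
        return range((self.start - 1) // 3 + 1, self.end // 3 + 1)

    def covers(self, position: int) -> bool:
        return position in self.residue_positions


def whole_cds_fragment(ref: ReferenceProtein) -> Fragment:
    return Fragment("full", 1, len(ref.cds))


def check_fragments(ref: ReferenceProtein, fragments: list[Fragment]) -> list[Fragment]:
    """Fragments must tile the CDS: every codon covered by at least one."""
    covered: set[int] = set()
    for fr in fragments:
        if fr.end > len(ref.cds):
            raise ValidationError(f"fragment {fr.name} extends past the CDS end")
        covered.update(fr.residue_positions)
    missing = set(range(1, len(ref) + 1)) - covered
    if missing:
        raise ValidationError(f"fragments do not tile the CDS; uncovered residues {sorted(missing)[:5]}...")
    return fragments
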