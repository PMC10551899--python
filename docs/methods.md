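# Methods

## The measurement being modeled

A single-site saturation mutagenesis (SSM) library of a receptor carrying
one half of split Venus is transfected under limiting-DNA conditions so
that cells express at most one variant, tightly linking genotype to
phenotype. Host cells stably express the wild-type receptor fused to the
complementary Venus half; receptor self-association reconstitutes Venus
fluorescence (BiFC). Two FACS selections are sequenced against the naive
library: an expression gate (surface-stained receptor above threshold)
and, within it, a high-BiFC gate that collects the top 5% of cells by
Venus fluorescence *relative to* surface expression. Scores are
WT-normalized log2 enrichment ratios; per-residue conservation scores are
means over a position's substitutions.

## Signal model in the simulator

Each variant carries four ground-truth multipliers: `expr` (surface
expression; WT = 1), `dimer` (specific oligomer assembly; WT = 1), `clust`
(lipid-microdomain clustering; WT = 1) and `agg` (nonspecific aggregation
propensity; WT = 0) — the three association mechanisms the assay
conflates, plus expression. Per cell,

    E = expr · ε_E
    B = expr · (α·dimer + β·clust + γ·agg) · ε_B

with ε independent lognormal noise of median 1 and coefficient of
variation `cv_noise`. Defaults α = 1, β = 0.5, γ = 1 make specific
dimerization the dominant WT signal with a smaller clustering
contribution; any positive `agg` adds to BiFC irrespective of the other
terms, reproducing the empirical hazard that destabilizing mutations
*gain* BiFC. `cv_noise = 0.5` is a typical cell-to-cell CV for
flow-cytometry reporter intensities; the assay gives no measured noise
model, so noise is independent between channels.

Gates: the expression gate is an absolute threshold (default 0.25 on the
WT-median-1 scale, so essentially all WT-like cells pass and strongly
expression-impaired variants fail); a top-quantile variant is available
for sensitivity analysis. The BiFC gate is **rank-based**: exactly
`round(bifc_top_fraction × n_gated)` cells, ranked by B/E (ties broken by
cell index), default fraction 0.05. Ranking on B/E rather than B reflects
sorting on BiFC relative to surface expression; plain-B ranking is a
config option. Reads are multinomial samples of each condition's cell
counts — amplification bias is deliberately not modeled, since sampling
during sorting is the dominant noise source being studied.

Library: variant frequencies are i.i.d. lognormal(0, skew²), normalized to
1 − wt_fraction; defaults skew = 1.5 (naive SSM libraries show order-of-
magnitude frequency variation) and wt_fraction = 0.05 (WT carryover from
library construction). Default sort sizes are 10⁵ cells and 10⁶ reads per
condition; these are plausible placeholders, not inferred from any
particular experiment.

Reads: each amplicon fragment is a codon-aligned CDS interval (intervals
are validated at construction; codon alignment keeps single-codon calling
exact at fragment edges). Each amino-acid substitution is written as one
deterministic codon — the alphabetically lowest codon encoding the mutant
residue — since modeling NNK codon degeneracy adds nothing to the analysis
path. Sequencing errors are i.i.d. base substitutions; error bases are
written with Phred 2 ('#') against a background of Phred 40 ('I'), which
also makes emitted errors independently countable.

## Scoring conventions

- Frequencies for enrichment are **fragment-local per position**:
  f_v = (c_v + pc) / (depth_pos + A·pc), where depth_pos is the variant
  counts at the position plus the effective WT depth there (sum of fully
  wild-type reads over covering fragments), pc = 0.5 by default, and A is
  the alphabet size. This corrects for unequal amplicon depth. The WT
  normalization term uses the same position's WT frequency, so the WT
  score is identically zero.
- Confidence flags use the **pseudocount-free naive frequency on the
  whole-library scale** (count / total naive reads): < 5×10⁻⁶ absent
  (no score), ≥ 5×10⁻⁵ confident, otherwise rare.
- Conservation scores average the scored (non-absent) substitutions at a
  position; stop codons are excluded by default (nonsense conflates
  translation truncation with missense structure effects) but kept in the
  raw enrichment table. Replicates are combined as the arithmetic mean of
  per-replicate conservation profiles; whether to average before or after
  residue averaging is not dictated by the assay, and the choice is
  recorded in output metadata.
- Replicate concordance is squared Pearson correlation on the log2 scale,
  per stratum (confident-in-both vs the rest; absent pairs excluded);
  strata with fewer than 3 pairs are reported as undefined (NaN), never 0.
- Aggregation-promoting mutations: log2 ratio **strictly greater than 1 in
  both replicates**; a variant absent in either replicate is never called.
  Because the denominator convention for "percent of missense mutations"
  is ambiguous, fractions are reported against both the scored-missense
  and the all-possible-missense denominators.
- Variant cross-referencing reports overlap plus a hypergeometric
  depletion p-value P(X ≤ overlap) over the scored-variant universe.
- The interface test statistic is mean conservation over interface
  residues minus mean over the other membrane-exposed residues (negative =
  interface more conserved). The null permutes interface labels among the
  membrane-exposed set; when the number of label choices is ≤ n_perm the
  null is enumerated exhaustively (p = b/total), otherwise sampled with
  the add-one correction (b+1)/(n_perm+1).
- Structure mapping writes clamped scores ([−3, +3], the conventional
  heat-map display range) into the B-factor column (two decimals, PDB
  fixed columns); unmatched residues get the sentinel 99.0; the attribute
  file keeps unclamped full-precision values. Residue numbering is related
  to profile positions by a single integer offset per chain; alignment-
  based mapping is out of scope. Contact-based residue sets use a 4.5 Å
  heavy-atom cutoff by default.

## Canonical study conditions (`bifcscan.scenarios`)

Validation runs on a 10-residue (190-variant) or 30-residue (570-variant)
demo receptor so that every scan completes in seconds:

- `neutral_scan` — all variants neutral; 2×10⁶ cells, 10⁶ reads. Checks
  that confident-variant enrichment is centred on zero; the residual
  spread is dominated by WT-count sampling in the 5% gate.
- `interface_recovery_scan` — residues 2–4 planted as interface
  (dimer = 0.2), 8% of remaining variants aggregating (agg = 5,
  expr = 0.7), rest neutral; two replicates at 4×10⁶ cells and 2×10⁶
  reads. Deep cell sampling matters because aggregating variants saturate
  the competitive top-5% gate, leaving few gate cells per neutral variant;
  at these depths the >1-in-both rule recovers planted truth at ≥0.9
  precision and recall.
- `sampling_noise_scan` — 30 residues, skew 2.0 (to populate the rare
  stratum), interface and clustering classes planted, **no aggregating
  class**, 10⁶ cells, 5×10⁵ reads. Without gate saturation,
  between-replicate disagreement tracks how deeply each variant was
  sampled, giving the expected orderings: confident R² > rare R², and
  residue-level R² > mutation-level R² (averaging 19 substitutions per
  residue cancels independent per-mutation noise).

One naive sequencing run is shared across replicates (`share_naive=True`),
as when a single plasmid library preparation is sequenced once.

## What the simulator does not capture

Antibody staining chemistry, FACS compensation and instrument drift,
RNA→cDNA→PCR amplification bias, codon degeneracy and junction artifacts
of the amplicon design, paired-end overlaps/UMIs, and cell-to-cell
transfection multiplicity (exactly one variant per cell is assumed).
Passing recovery tests therefore demonstrates that the scoring and
decision rules are correct and well calibrated under sampling noise — not
that real screens meet these precision figures, since real data add the
above systematic effects (and real replicate R² is far below the
simulator's at matched depth).

## Numerical and degenerate-input choices

Seeded `numpy` generators everywhere; identical seeds give byte-identical
FASTQ. Zero-depth positions yield frequency 0 and absent flags rather than
division errors; an empty FACS gate raises an explicit error rather than
returning silent zeros; a missing wild type in either condition is a hard
error because normalization is undefined. With pseudocount 0, a variant
unobserved in the selected pool scores −inf; the default pseudocount 0.5
keeps scores finite. Permutation ties are counted conservatively
(≤ observed + 1e−12).
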