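"""Decision rules on scored scans.

Predicts aggregation-promoting mutations (log2 enrichment > threshold in
both independent BiFC-sorted replicates), cross-references predictions
against observed human missense variant lists (gnomAD-style), and tests
whether a candidate dimer-interface surface is more conserved than the
rest of the membrane-exposed surface by label permutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ReferenceProtein, ValidationError, STOP, VariantKey
from .scores import FLAG_ABSENT, VARIANT_COLS


@dataclass(frozen=True)
class SurfaceDefinition:
    """Residue sets for the interface-conservation comparison: the
    candidate interface must be a proper, nonempty subset of the
    membrane-exposed residues."""

    interface_residues: frozenset[int]
    membrane_exposed_residues: frozenset[int]

    def __post_init__(self) -> None:
        if not self.interface_residues or not self.membrane_exposed_residues:
            raise ValidationError("interface and membrane-exposed residue sets must be nonempty")
        if not self.interface_residues <= self.membrane_exposed_residues:
            raise ValidationError("interface residues must be a subset of membrane-exposed residues")
        if self.interface_residues == self.membrane_exposed_residues:
            raise ValidationError("interface equals the membrane-exposed set; no null support")


def predict_aggregating(
    rep_a: pd.DataFrame,
    rep_b: pd.DataFrame,
    threshold: float = 1.0,
) -> tuple[set[VariantKey], dict]:
    """Variants with log2 enrichment strictly above ``threshold`` in BOTH
    replicates of the BiFC selection.

    A variant absent or unscored in either replicate is never predicted.
    The summary reports the predicted count as a fraction of missense
    variants scored in both replicates and of all possible missense
    variants, since either denominator convention may be wanted.
    """
    if not math.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    j = rep_a.merge(rep_b, on=VARIANT_COLS, suffixes=("_a", "_b"))
    missense = j["mut_aa"] != STOP
    scored = (
        j["log2_ratio_a"].notna()
        & j["log2_ratio_b"].notna()
        & (j["flag_a"] != FLAG_ABSENT)
        & (j["flag_b"] != FLAG_ABSENT)
    )
    hit = scored & missense & (j["log2_ratio_a"] > threshold) & (j["log2_ratio_b"] > threshold)
    predicted = {
        VariantKey(int(r.position), r.wt_aa, r.mut_aa) for r in j[hit].itertuples()
    }
    n_scored = int((scored & missense).sum())
    n_possible = int(missense.sum())
    summary = {
        "threshold": threshold,
        "n_predicted": len(predicted),
        "n_scored_missense": n_scored,
        "n_possible_missense": n_possible,
        "frac_of_scored": len(predicted) / n_scored if n_scored else float("nan"),
        "frac_of_possible": len(predicted) / n_possible if n_possible else float("nan"),
    }
    return predicted, summary


def scored_missense_set(rep_a: pd.DataFrame, rep_b: pd.DataFrame) -> set[VariantKey]:
    """Missense variants scored (non-absent) in both replicates — the
    universe for enrichment/depletion statistics."""
    j = rep_a.merge(rep_b, on=VARIANT_COLS, suffixes=("_a", "_b"))
    ok = (
        j["log2_ratio_a"].notna()
        & j["log2_ratio_b"].notna()
        & (j["flag_a"] != FLAG_ABSENT)
        & (j["flag_b"] != FLAG_ABSENT)
        & (j["mut_aa"] != STOP)
    )
    return {VariantKey(int(r.position), r.wt_aa, r.mut_aa) for r in j[ok].itertuples()}


def read_variant_list(path) -> pd.DataFrame:
    """Read an observed-variant CSV (columns protein, position, wt_aa,
    mut_aa, allele_count, allele_frequency)."""
    df = pd.read_csv(path)
    required = {"position", "wt_aa", "mut_aa"}
    if not required <= set(df.columns):
        raise ValidationError(f"variant list must have columns {sorted(required)}")
    return df


def validate_variant_list(observed: pd.DataFrame, ref: ReferenceProtein) -> list[VariantKey]:
    """Check numbering against the reference; duplicates and wt_aa
    mismatches are hard errors naming the offending records."""
    keys = []
    bad = []
    for r in observed.itertuples():
        v = VariantKey(int(r.position), r.wt_aa, r.mut_aa)
        try:
            ref.validate_variant(v)
        except ValidationError:
            bad.append(str(v))
            continue
        keys.append(v)
    if bad:
        raise ValidationError(f"observed variants disagree with reference numbering: {bad}")
    if len(set(keys)) != len(keys):
        dupes = sorted({str(k) for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate observed variants: {dupes}")
    return keys


def cross_reference_variants(
    predicted: set[VariantKey],
    observed: pd.DataFrame,
    ref: ReferenceProtein,
    scored_universe: set[VariantKey] | None = None,
) -> dict:
    """Overlap of an observed missense-variant list with the predicted set.

    Reports the observed variants that are predicted, the counts, and a
    hypergeometric depletion p-value, P(X <= overlap), for drawing
    ``overlap`` predicted variants when |observed| variants are sampled
    from the scored universe. An empty observed list gives overlap 0 and
    an undefined p-value.
    """
    keys = validate_variant_list(observed, ref)
    universe = scored_universe if scored_universe is not None else set(predicted) | set(keys)
    obs_in_universe = [k for k in keys if k in universe]
    overlap = sorted(set(obs_in_universe) & predicted, key=lambda v: (v.position, v.mut_aa))
    report = {
        "n_observed": len(keys),
        "n_observed_in_universe": len(obs_in_universe),
        "n_predicted": len(predicted),
        "n_universe": len(universe),
        "overlap": [str(v) for v in overlap],
        "n_overlap": len(overlap),
    }
    if not keys or not universe:
        report["p_depletion"] = None
        return report
    k_pred = len(predicted & universe)
    report["p_depletion"] = float(
        stats.hypergeom.cdf(len(overlap), len(universe), k_pred, len(obs_in_universe))
    )
    return report


def interface_conservation_test(
    profile: pd.DataFrame,
    surfaces: SurfaceDefinition,
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "auto",
) -> dict:
    """Is the candidate interface more conserved than the rest of the
    membrane-exposed surface?

    The statistic is mean conservation score over interface residues
    minus the mean over the other membrane-exposed residues; depleted
    (intolerant) residues have negative scores, so a more conserved
    interface gives a negative statistic. The null permutes interface
    labels among the membrane-exposed residues; the one-sided p-value is
    for the interface being more conserved. When the number of distinct
    label choices is at most ``n_perm`` (or method="exhaustive"), the
    null is enumerated exactly; otherwise ``n_perm`` random permutations
    are drawn with the add-one correction (b+1)/(n+1).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if method not in ("auto", "exhaustive", "sampled"):
        raise ValidationError("method must be auto, exhaustive or sampled")
    scores = profile["score"]
    exposed = sorted(p for p in surfaces.membrane_exposed_residues if p in scores.index)
    iface = {p for p in surfaces.interface_residues if p in scores.index}
    others = [p for p in exposed if p not in iface]
    if not iface or not others:
        raise ValidationError("both interface and non-interface sets need scored positions")
    vals = scores.loc[exposed].to_numpy(dtype=float)
    is_iface = np.array([p in iface for p in exposed])
    k = int(is_iface.sum())

    def stat(mask: np.ndarray) -> float:
        return float(vals[mask].mean() - vals[~mask].mean())

    observed = stat(is_iface)
    n_choices = math.comb(len(exposed), k)
    exhaustive = method == "exhaustive" or (method == "auto" and n_choices <= n_perm)
    eps = 1e-12
    if exhaustive:
        b = 0
        for combo in combinations(range(len(exposed)), k):
            mask = np.zeros(len(exposed), dtype=bool)
            mask[list(combo)] = True
            if stat(mask) <= observed + eps:
                b += 1
        p = b / n_choices
        used = n_choices
    else:
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(n_perm):
            mask = np.zeros(len(exposed), dtype=bool)
            mask[rng.choice(len(exposed), size=k, replace=False)] = True
            if stat(mask) <= observed + eps:
                b += 1
        p = (b + 1) / (n_perm + 1)
        used = n_perm
    return {
        "statistic": observed,
        "p_value": float(p),
        "n_interface": int(len(iface)),
        "n_other": int(len(others)),
        "method": "exhaustive" if exhaustive else "sampled",
        "n_permutations": int(used),
    }
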