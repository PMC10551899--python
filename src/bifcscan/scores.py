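"""Core sort-seq statistics.

Computes wild-type-normalized log2 enrichment ratios for every single
amino-acid substitution, frequency-based confidence flags, per-residue
conservation scores, and replicate concordance (R^2) per frequency
stratum.

The enrichment ratio of variant v between a selected population and the
naive library is

    E_v = log2(f_sel,v / f_naive,v) - log2(f_sel,WT / f_naive,WT),

so the wild type is 0 by construction. Frequencies are computed per
fragment-covered position, f_v = (c_v + pc) / (depth_pos + A*pc), where
depth_pos is the variant counts at that position plus the effective WT
depth there, pc is a pseudocount and A the alphabet size; this corrects
for unequal amplicon-fragment depth. Confidence flags use the
pseudocount-free naive frequency on the whole-library scale
(count / total reads): below 5e-6 a mutation is considered absent from
the library; at or above 5e-5 it is confident; in between it is rare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AA_ALPHABET, ValidationError, STOP, VariantKey
from .counts import CountTable

ABSENT_THRESHOLD = 5e-6
CONFIDENT_THRESHOLD = 5e-5

FLAG_ABSENT = "absent"
FLAG_RARE = "rare"
FLAG_CONFIDENT = "confident"

VARIANT_COLS = ["position", "wt_aa", "mut_aa"]


class WTAbsentError(ValidationError):
    """Wild type missing from a condition; normalization is undefined."""


def flag_for(naive_raw_freq: float) -> str:
    if naive_raw_freq < ABSENT_THRESHOLD:
        return FLAG_ABSENT
    if naive_raw_freq >= CONFIDENT_THRESHOLD:
        return FLAG_CONFIDENT
    return FLAG_RARE


def compute_frequencies(
    table: CountTable,
    pseudocount: float = 0.5,
    alphabet: str = AA_ALPHABET,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant and per-position WT frequencies for one count table.

    Returns (variants, wt) where ``variants`` has one row per possible
    substitution at the table's covered positions with columns count,
    freq (pseudocounted, position-local), raw_global_freq
    (pseudocount-free count / total reads); ``wt`` is indexed by position
    with columns wt_depth, depth and wt_freq. Positions with zero depth
    get freq 0 rather than a division error; their variants are flagged
    absent downstream.
    """
    if table.total_reads == 0:
        raise ValidationError("empty count table")
    ref = table.reference
    a = len(alphabet)
    rows = []
    wt_rows = []
    for pos in sorted(table.positions):
        wt_aa = ref.wt_aa(pos)
        at_pos = {v: c for v, c in table.counts.items() if v.position == pos}
        depth = table.wt_depth.get(pos, 0) + sum(at_pos.values())
        denom = depth + a * pseudocount
        wt_rows.append(
            {
                "position": pos,
                "wt_depth": table.wt_depth.get(pos, 0),
                "depth": depth,
                "wt_freq": (table.wt_depth.get(pos, 0) + pseudocount) / denom if denom > 0 else 0.0,
            }
        )
        for aa in alphabet:
            if aa == wt_aa:
                continue
            v = VariantKey(pos, wt_aa, aa)
            c = at_pos.get(v, 0)
            rows.append(
                {
                    "position": pos,
                    "wt_aa": wt_aa,
                    "mut_aa": aa,
                    "count": c,
                    "freq": (c + pseudocount) / denom if denom > 0 else 0.0,
                    "raw_global_freq": c / table.total_reads,
                }
            )
    variants = pd.DataFrame(rows)
    wt = pd.DataFrame(wt_rows).set_index("position")
    return variants, wt


def enrichment_ratios(
    naive: CountTable,
    selected: CountTable,
    pseudocount: float = 0.5,
    alphabet: str = AA_ALPHABET,
    replicate: str = "",
) -> pd.DataFrame:
    """WT-normalized log2 enrichment ratios of selected vs naive.

    Returns an enrichment table: one row per possible substitution with
    columns position, wt_aa, mut_aa, naive_count, sel_count, naive_freq
    (raw, whole-library), flag, log2_ratio. Mutations flagged absent get
    no score (NaN). Attributes record the selection, replicate and
    pseudocount. A missing wild type in either condition is a hard error.
    """
    if naive.wt_count == 0 or selected.wt_count == 0:
        raise WTAbsentError("wild-type reads missing from naive or selected condition")
    nav_v, nav_wt = compute_frequencies(naive, pseudocount, alphabet)
    sel_v, sel_wt = compute_frequencies(selected, pseudocount, alphabet)
    df = nav_v.merge(sel_v, on=VARIANT_COLS, suffixes=("_naive", "_sel"))
    wt_term = np.log2(sel_wt["wt_freq"] / nav_wt["wt_freq"])
    df["naive_freq"] = df["raw_global_freq_naive"]
    df["flag"] = df["naive_freq"].map(flag_for)
    with np.errstate(divide="ignore"):
        ratio = np.log2(df["freq_sel"] / df["freq_naive"]) - df["position"].map(wt_term)
    df["log2_ratio"] = ratio.where(df["flag"] != FLAG_ABSENT, np.nan)
    out = df[VARIANT_COLS + ["naive_freq", "flag", "log2_ratio"]].copy()
    out["naive_count"] = df["count_naive"]
    out["sel_count"] = df["count_sel"]
    out.attrs.update(
        selection=selected.condition, replicate=replicate or selected.replicate, pseudocount=pseudocount
    )
    return out


def wt_normalized_wt_score(
    naive: CountTable,
    selected: CountTable,
    pseudocount: float = 0.5,
    alphabet: str = AA_ALPHABET,
) -> pd.Series:
    """The wild type's own WT-normalized enrichment per position.

    Computed through the same frequency machinery as variant scores; it is
    zero by construction and exposed so the normalization identity can be
    checked executably.
    """
    _, nav_wt = compute_frequencies(naive, pseudocount, alphabet)
    _, sel_wt = compute_frequencies(selected, pseudocount, alphabet)
    term = np.log2(sel_wt["wt_freq"] / nav_wt["wt_freq"])
    return term - term


def conservation_scores(
    tables: pd.DataFrame | list[pd.DataFrame],
    exclude_stop: bool = True,
) -> pd.DataFrame:
    """Per-residue mean of substitution enrichment ratios.

    For a list of replicate enrichment tables, per-replicate profiles are
    averaged position-wise (arithmetic mean of the replicate conservation
    scores). Stop substitutions are excluded by default so nonsense
    effects do not contaminate missense conservation. Positions with no
    scored substitution are absent from the result.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    profiles = []
    for t in tables:
        d = t.dropna(subset=["log2_ratio"])
        if exclude_stop:
            d = d[d["mut_aa"] != STOP]
        prof = d.groupby("position")["log2_ratio"].agg(score="mean", n_substitutions="count")
        profiles.append(prof)
    scores = pd.concat([p["score"] for p in profiles], axis=1).mean(axis=1)
    nsub = pd.concat([p["n_substitutions"] for p in profiles], axis=1).max(axis=1).astype(int)
    out = pd.DataFrame({"score": scores, "n_substitutions": nsub})
    out.index.name = "position"
    return out.dropna(subset=["score"])


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        return float("nan")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def replicate_concordance(
    rep_a: pd.DataFrame,
    rep_b: pd.DataFrame,
    level: str = "mutation",
    exclude_stop: bool = True,
) -> pd.DataFrame:
    """Squared Pearson correlation between replicates per frequency stratum.

    At mutation level, pairs scored in both replicates are split into a
    confident stratum (naive frequency >= 5e-5 in both) and a rare
    stratum (the rest); pairs absent in either replicate are excluded.
    At residue level the correlation is over per-replicate conservation
    scores. Strata with fewer than 3 pairs are reported as undefined
    (NaN), never 0.
    """
    if level == "residue":
        pa = conservation_scores(rep_a, exclude_stop=exclude_stop)
        pb = conservation_scores(rep_b, exclude_stop=exclude_stop)
        j = pa.join(pb, lsuffix="_a", rsuffix="_b", how="inner").dropna()
        return pd.DataFrame(
            [{"stratum": "residue", "r_squared": _r_squared(j["score_a"].to_numpy(), j["score_b"].to_numpy()), "n": len(j)}]
        )
    if level != "mutation":
        raise ValidationError("level must be 'mutation' or 'residue'")
    j = rep_a.merge(rep_b, on=VARIANT_COLS, suffixes=("_a", "_b"))
    j = j.dropna(subset=["log2_ratio_a", "log2_ratio_b"])
    j = j[(j["flag_a"] != FLAG_ABSENT) & (j["flag_b"] != FLAG_ABSENT)]
    confident = (j["flag_a"] == FLAG_CONFIDENT) & (j["flag_b"] == FLAG_CONFIDENT)
    rows = []
    for stratum, sel in (("confident", confident), ("rare", ~confident)):
        s = j[sel]
        rows.append(
            {
                "stratum": stratum,
                "r_squared": _r_squared(s["log2_ratio_a"].to_numpy(), s["log2_ratio_b"].to_numpy()),
                "n": len(s),
            }
        )
    return pd.DataFrame(rows)


def enrichment_matrix(
    table: pd.DataFrame,
    clamp: tuple[float, float] | None = (-3.0, 3.0),
    alphabet: str = AA_ALPHABET,
) -> pd.DataFrame:
    """Substitution-by-position matrix of log2 ratios for heat maps.

    Rows are mutant amino acids (alphabet order), columns residue
    positions; values are clamped to [-3, +3] by default, matching the
    conventional display range from strongly depleted to strongly
    enriched; absent mutations stay NaN.
    """
    mat = table.pivot(index="mut_aa", columns="position", values="log2_ratio")
    mat = mat.reindex([aa for aa in alphabet if aa in mat.index])
    if clamp is not None:
        mat = mat.clip(clamp[0], clamp[1])
    return mat


def export_heatmap(
    table: pd.DataFrame,
    tsv_path: str,
    png_path: str | None = None,
    clamp: tuple[float, float] = (-3.0, 3.0),
    alphabet: str = AA_ALPHABET,
) -> pd.DataFrame:
    """Write the clamped heat-map matrix as TSV and optionally render it."""
    mat = enrichment_matrix(table, clamp=clamp, alphabet=alphabet)
    mat.to_csv(tsv_path, sep="\t")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(4, mat.shape[1] * 0.25), 5))
        cmap = matplotlib.colormaps["coolwarm_r"].copy()
        cmap.set_bad("black")
        im = ax.imshow(mat.to_numpy(dtype=float), cmap=cmap, vmin=clamp[0], vmax=clamp[1], aspect="auto")
        ax.set_yticks(range(len(mat.index)), mat.index)
        ax.set_xlabel("residue position")
        ax.set_ylabel("substitution")
        fig.colorbar(im, ax=ax, label="log2 enrichment ratio")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return mat
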