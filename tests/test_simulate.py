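"""Simulator: library construction, phenotype planting, FACS gating,
read emission."""

import math

import numpy as np
import pytest

from bifcscan.core import SortSpec, ValidationError, VariantPhenotype, whole_cds_fragment
from bifcscan.simulate import (
    DEFAULT_EFFECTS,
    EffectClass,
    EmptyGateError,
    assign_phenotypes,
    build_ssm_library,
    emit_condition_fastqs,
    simulate_sort,
)


class TestBuildLibrary:
    def test_variant_count_is_positions_times_alternatives(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, seed=0)
        assert len(lib.frequencies) == 10 * 19

    def test_zero_skew_gives_uniform_frequencies(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, skew=0.0, wt_fraction=0.05, seed=0)
        expected = 0.95 / 190
        assert all(math.isclose(f, expected) for f in lib.frequencies.values())

    def test_frequencies_sum_to_one_with_wt(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, skew=1.5, wt_fraction=0.1, seed=3)
        assert math.isclose(lib.wt_fraction + sum(lib.frequencies.values()), 1.0, abs_tol=1e-9)

    def test_same_seed_reproduces_rare_variant_set_exactly(self, tiny_ref):
        a = build_ssm_library(tiny_ref, skew=1.5, seed=11)
        b = build_ssm_library(tiny_ref, skew=1.5, seed=11)
        rare_a = {v for v, f in a.frequencies.items() if f < 5e-6}
        rare_b = {v for v, f in b.frequencies.items() if f < 5e-6}
        assert rare_a == rare_b
        assert a.frequencies == b.frequencies

    @pytest.mark.parametrize(
        "kwargs", [{"skew": -0.1}, {"alphabet": "ACDB"}, {"alphabet": ""}, {"wt_fraction": 0.0}]
    )
    def test_invalid_inputs_rejected(self, tiny_ref, kwargs):
        with pytest.raises(ValidationError):
            build_ssm_library(tiny_ref, seed=0, **kwargs)


class TestAssignPhenotypes:
    def test_all_neutral_equals_wild_type(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, seed=0)
        phen = assign_phenotypes(lib, {"neutral": EffectClass("neutral", proportion=1.0)}, seed=0)
        wt = VariantPhenotype()
        assert all(
            (p.expr, p.dimer, p.agg, p.clust) == (wt.expr, wt.dimer, wt.agg, wt.clust)
            for p in phen.variants.values()
        )

    def test_aggregation_raises_bifc_signal_above_wt(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, seed=0)
        phen = assign_phenotypes(
            lib, {"aggregating": EffectClass("aggregating", proportion=1.0, agg=5.0)}, seed=0
        )
        wt_factor = phen.bifc_factor(VariantPhenotype())
        assert all(phen.bifc_factor(p) > wt_factor for p in phen.variants.values())

    def test_class_counts_match_proportions_with_deterministic_rounding(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, seed=0)
        spec = {
            "neutral": EffectClass("neutral", proportion=0.85),
            "aggregating": EffectClass("aggregating", proportion=0.10, agg=5.0),
            "interface": EffectClass("interface", proportion=0.05, dimer=0.2),
        }
        phen = assign_phenotypes(lib, spec, seed=4)
        labels = list(phen.labels().values())
        # 190 variants: quotas 161.5 / 19 / 9.5 -> largest remainder
        assert labels.count("aggregating") == 19
        assert labels.count("neutral") + labels.count("interface") == 171
        assert abs(labels.count("neutral") - 161.5) <= 0.5
        assert assign_phenotypes(lib, spec, seed=4).labels() == phen.labels()

    def test_unknown_class_name_rejected(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, seed=0)
        first = lib.variants[0]
        with pytest.raises(ValidationError, match="unknown effect class"):
            assign_phenotypes(lib, DEFAULT_EFFECTS, seed=0, assignments={first: "bogus"})


@pytest.fixture(scope="module")
def scan(tiny_ref):
    lib = build_ssm_library(tiny_ref, seed=1)
    phen = assign_phenotypes(lib, {"neutral": EffectClass("neutral", proportion=1.0)}, seed=1)
    sort = SortSpec(n_cells=50_000, n_reads_per_condition=100_000)
    return lib, phen, simulate_sort(lib, phen, sort, seed=2)


class TestSimulateSort:
    def test_cells_are_conserved_through_the_expression_gate(self, scan):
        lib, phen, sim = scan
        naive_cells = sum(sim.conditions["naive"].cells.values())
        rejected = naive_cells - sim.n_expression_gate
        assert naive_cells == 50_000 and rejected >= 0
        assert sum(sim.conditions["expression"].cells.values()) == sim.n_expression_gate

    def test_bifc_gate_is_exactly_the_top_fraction(self, scan):
        _, _, sim = scan
        assert sim.n_bifc_gate == int(math.floor(0.05 * sim.n_expression_gate + 0.5))
        assert sum(sim.conditions["bifc"].cells.values()) == sim.n_bifc_gate

    def test_neutral_phenotypes_leave_condition_frequencies_unselected(self, scan):
        lib, phen, sim = scan
        n = sum(sim.conditions["bifc"].cells.values())
        for v, f in lib.frequencies.items():
            if f < 1e-3:
                continue
            observed = sim.conditions["bifc"].cells.get(v, 0)
            se = math.sqrt(n * f * (1 - f))
            assert abs(observed - n * f) <= 4 * se + 1

    def test_identical_seed_identical_result(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, seed=5)
        phen = assign_phenotypes(lib, {"neutral": EffectClass("neutral", proportion=1.0)}, seed=5)
        sort = SortSpec(n_cells=10_000, n_reads_per_condition=10_000)
        a = simulate_sort(lib, phen, sort, seed=9)
        b = simulate_sort(lib, phen, sort, seed=9)
        assert a.conditions["bifc"].reads == b.conditions["bifc"].reads

    def test_raising_agg_never_shrinks_bifc_gate_count(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, seed=1)
        target = lib.variants[7]
        counts = []
        for agg in (0.0, 2.0, 5.0, 10.0):
            phen = assign_phenotypes(
                lib,
                {"neutral": EffectClass("neutral"), "hot": EffectClass("hot", agg=agg)},
                seed=1,
                assignments={target: "hot"},
            )
            sim = simulate_sort(lib, phen, SortSpec(n_cells=20_000, n_reads_per_condition=1000), seed=3)
            counts.append(sim.conditions["bifc"].cells.get(target, 0))
        assert counts == sorted(counts)

    def test_empty_expression_gate_is_an_explicit_error(self, tiny_ref):
        lib = build_ssm_library(tiny_ref, seed=1)
        phen = assign_phenotypes(lib, {"neutral": EffectClass("neutral", proportion=1.0)}, seed=1)
        with pytest.raises(EmptyGateError):
            simulate_sort(lib, phen, SortSpec(n_cells=1000, n_reads_per_condition=100, expr_threshold=1e9), seed=0)

    def test_zero_cells_rejected_at_sortspec_construction(self):
        with pytest.raises(ValidationError):
            SortSpec(n_cells=0)


class TestGateOracle:
    def test_gate_membership_matches_exhaustive_enumeration(self, tiny_ref):
        """Zero-noise sort of <=100 cells vs a hand enumeration of every
        cell sorted by BiFC/expression ratio."""
        lib = build_ssm_library(tiny_ref, skew=0.0, seed=0)
        v1, v2, v3 = lib.variants[0], lib.variants[50], lib.variants[120]
        phen = assign_phenotypes(
            lib,
            {
                "neutral": EffectClass("neutral"),
                "hi": EffectClass("hi", agg=4.0),
                "lo": EffectClass("lo", dimer=0.1),
                "dim": EffectClass("dim", expr=0.1),
            },
            seed=0,
            assignments={v1: "hi", v2: "lo", v3: "dim"},
            cv_noise=0.0,
        )
        sort = SortSpec(n_cells=50, n_reads_per_condition=100, bifc_top_fraction=0.10)
        sim = simulate_sort(lib, phen, sort, seed=6)

        # oracle: enumerate cells in genotype order from the naive cell
        # counts, apply both gates by explicit sorting
        genotypes = [None] + lib.variants
        cells = []
        for gt in genotypes:
            n = sim.conditions["naive"].cells.get(gt, 0)
            p = phen.variants[gt] if gt is not None else VariantPhenotype()
            e = p.expr
            b = p.expr * phen.bifc_factor(p)
            cells.extend([(gt, e, b)] * n)
        gated = [(i, gt, e, b) for i, (gt, e, b) in enumerate(cells) if e > sort.expr_threshold]
        assert len(gated) == sim.n_expression_gate
        ranked = sorted(gated, key=lambda t: (-(t[3] / t[2]), t[0]))
        k = int(math.floor(sort.bifc_top_fraction * len(gated) + 0.5))
        top = ranked[:k]
        oracle_counts = {}
        for _, gt, _, _ in top:
            oracle_counts[gt] = oracle_counts.get(gt, 0) + 1
        sim_counts = {gt: c for gt, c in sim.conditions["bifc"].cells.items() if c}
        assert sim_counts == oracle_counts


class TestEmitReads:
    def test_identical_seed_byte_identical_fastq(self, tiny_ref, tmp_path):
        lib = build_ssm_library(tiny_ref, seed=2)
        phen = assign_phenotypes(lib, {"neutral": EffectClass("neutral", proportion=1.0)}, seed=2)
        sim = simulate_sort(lib, phen, SortSpec(n_cells=2000, n_reads_per_condition=3000), seed=4)
        for d in ("a", "b"):
            (tmp_path / d).mkdir()
            emit_condition_fastqs(sim, [whole_cds_fragment(tiny_ref)], error_rate=0.002, seed=7, outdir=str(tmp_path / d))
        for name in ("naive", "expression", "bifc"):
            assert (tmp_path / "a" / f"{name}.fastq").read_bytes() == (tmp_path / "b" / f"{name}.fastq").read_bytes()

    def test_single_variant_reads_all_carry_the_expected_codon(self, tiny_ref, tmp_path):
        from bifcscan.core import VariantKey, codon_for
        from bifcscan.simulate import emit_reads

        v = tiny_ref.validate_variant(VariantKey(4, "L", "W"))
        path = tmp_path / "one.fastq"
        stats = emit_reads({v: 100}, tiny_ref, [whole_cds_fragment(tiny_ref)], seed=0, out_path=str(path))
        assert stats == {"n_reads": 100, "n_errors": 0}
        lines = path.read_text().splitlines()
        seqs = lines[1::4]
        assert len(seqs) == 100
        expected = tiny_ref.cds[:9] + codon_for("W") + tiny_ref.cds[12:]
        assert all(s == expected for s in seqs)

    def test_introduced_errors_match_independent_quality_recount(self, tiny_ref, tmp_path):
        """Error bases are flagged at Phred 2; a plain-text reparse of the
        quality strings recounts them independently."""
        lib = build_ssm_library(tiny_ref, seed=2)
        phen = assign_phenotypes(lib, {"neutral": EffectClass("neutral", proportion=1.0)}, seed=2)
        sim = simulate_sort(lib, phen, SortSpec(n_cells=2000, n_reads_per_condition=4000), seed=4)
        from bifcscan.simulate import emit_reads

        path = tmp_path / "err.fastq"
        stats = emit_reads(
            sim.conditions["naive"].reads, tiny_ref, [whole_cds_fragment(tiny_ref)],
            error_rate=0.003, seed=5, out_path=str(path),
        )
        quals = path.read_text().splitlines()[3::4]
        low_q = "".join(quals).count("#")
        assert stats["n_errors"] == low_q > 0

    def test_variant_outside_all_fragments_rejected(self, tiny_ref):
        from bifcscan.core import Fragment, VariantKey
        from bifcscan.simulate import emit_reads

        v = tiny_ref.validate_variant(VariantKey(10, "L", "A"))
        with pytest.raises(ValidationError):
            emit_reads({v: 5}, tiny_ref, [Fragment("f1", 1, 27)], seed=0)
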