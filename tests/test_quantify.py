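"""Quantification chain: counting, frequencies, ratios, aggregation, matrices."""

import math

import numpy as np
import pandas as pd
import pytest

from misfit.dictionary import cross_context_fit
from misfit.mre import enumerate_variants, make_variant
from misfit.quantify import (
    CountTable,
    aggregate_pcr_error,
    aggregate_replicates,
    ddct,
    frequencies,
    mean_fold_derepression,
    normalize_to_control,
    position_effect_matrix,
    quantify_screen,
    transcript_abundance,
    translational_efficiency,
    trim_and_count,
)
from misfit.simulate import CONTROL_NONTARGETED_ID, GroundTruthModel, ScreenSimConfig, simulate_screen


class TestTrimAndCount:
    FLANK5 = "GATTACAGAT"

    def test_exact_match_semantics(self):
        seqs = {"v1": "AAAA", "v2": "AATA"}
        reads = [
            self.FLANK5 + "AAAA" + "GG",   # v1
            "CC" + self.FLANK5 + "AATA",   # v2, flank not at read start
            self.FLANK5 + "AATA" + "GG",   # 1-nt change that IS another variant
            self.FLANK5 + "ACCA" + "GG",   # unenumerated variable region
            "TTTTTTTTTTTTTTTTTT",          # no flank
            self.FLANK5 + "AAA",           # truncated variable region
        ]
        t = trim_and_count(reads, seqs, self.FLANK5)
        assert t.counts == {"v1": 1, "v2": 2}
        assert t.other_count == 3
        assert t.total == 6

    def test_conservation_of_reads(self):
        seqs = {"v1": "ACGT"}
        reads = [self.FLANK5 + "ACGT"] * 5 + ["GGGGGGGGGGGGGG"] * 2
        t = trim_and_count(reads, seqs, self.FLANK5)
        assert sum(t.counts.values()) + t.other_count == t.total == len(reads)

    def test_empty_variant_set_rejected(self):
        with pytest.raises(ValueError):
            trim_and_count([], {}, self.FLANK5)


class TestFrequencies:
    def test_hand_arithmetic(self):
        t = CountTable("pDNA", 1, {"A": 10, "B": 90})
        assert frequencies(t) == {"A": pytest.approx(0.1), "B": pytest.approx(0.9)}

    def test_all_mass_on_one_variant(self):
        t = CountTable("pDNA", 1, {"A": 7, "B": 0})
        assert frequencies(t)["A"] == pytest.approx(1.0)

    def test_sum_with_other_is_one(self):
        t = CountTable("pDNA", 1, {"A": 10, "B": 20}, other_count=70)
        f = frequencies(t)
        assert sum(f.values()) + t.other_count / t.total == pytest.approx(1.0)

    def test_pseudocount_keeps_normalisation(self):
        t = CountTable("pDNA", 1, {"A": 10, "B": 0}, other_count=5)
        f = frequencies(t, pseudocount=1.0)
        other = (t.other_count + 1.0) / (t.total + 3.0)
        assert sum(f.values()) + other == pytest.approx(1.0)
        assert f["B"] > 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            frequencies(CountTable("pDNA", 1, {"A": 0}))


class TestRatios:
    def test_abundance_hand_arithmetic(self):
        ab = transcript_abundance({"A": 0.1, "B": 0.9}, {"A": 0.5, "B": 0.5})
        assert ab["A"] == pytest.approx(0.2)
        assert ab["B"] == pytest.approx(1.8)

    def test_identical_maps_give_unit_ratios(self):
        f = {"A": 0.3, "B": 0.7}
        assert all(v == pytest.approx(1.0) for v in transcript_abundance(f, f).values())

    def test_missing_pdna_flagged_not_ratioed(self):
        ab = transcript_abundance({"A": 0.5, "B": 0.5}, {"A": 1.0, "B": 0.0})
        assert math.isnan(ab["B"])

    def test_scale_invariance(self):
        c1 = CountTable("cDNA", 1, {"A": 10, "B": 30})
        p1 = CountTable("pDNA", 1, {"A": 20, "B": 20})
        c2 = CountTable("cDNA", 1, {"A": 50, "B": 150})
        p2 = CountTable("pDNA", 1, {"A": 60, "B": 60})
        ab1 = transcript_abundance(frequencies(c1), frequencies(p1))
        ab2 = transcript_abundance(frequencies(c2), frequencies(p2))
        for vid in ab1:
            assert ab1[vid] == pytest.approx(ab2[vid])

    def test_normalize_to_control(self):
        norm = normalize_to_control({"A": 1.0, "ctrl": 2.0}, "ctrl")
        assert norm == {"A": pytest.approx(0.5), "ctrl": pytest.approx(1.0)}
        with pytest.raises(ValueError):
            normalize_to_control({"A": 1.0}, "ctrl")

    def test_normalization_preserves_ranking(self):
        ab = {"A": 0.2, "B": 1.4, "C": 0.9, "ctrl": 0.7}
        norm = normalize_to_control(ab, "ctrl")
        assert sorted(ab, key=ab.get) == sorted(norm, key=norm.get)

    def test_translational_efficiency(self):
        te = translational_efficiency({"A": 0.5, "B": 0.5}, {"A": 0.5, "B": 0.5})
        assert all(v == pytest.approx(1.0) for v in te.values())
        assert math.isnan(translational_efficiency({"A": 1.0}, {"A": 0.0})["A"])


class TestAggregation:
    def test_constant_replicates(self):
        out = aggregate_replicates([{"A": 1.0}, {"A": 1.0}, {"A": 1.0}])
        assert out.loc["A", "mean"] == pytest.approx(1.0)
        assert out.loc["A", "sd"] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        out = aggregate_replicates([{"A": 0.1}, {"A": 0.2}, {"A": 0.3}])
        assert out.loc["A", "mean"] == pytest.approx(0.2)
        assert out.loc["A", "sd"] == pytest.approx(0.1)

    def test_single_replicate_sd_undefined(self):
        out = aggregate_replicates([{"A": 0.5}])
        assert math.isnan(out.loc["A", "sd"])
        assert out.loc["A", "n"] == 1

    def test_missing_replicates_excluded_with_count(self):
        out = aggregate_replicates([{"A": 0.2}, {"A": float("nan")}, {"A": 0.4}])
        assert out.loc["A", "mean"] == pytest.approx(0.3)
        assert out.loc["A", "n"] == 2


class TestFoldDerepression:
    def test_all_equal_to_perfect(self):
        fold, ci = mean_fold_derepression({"a": 0.1, "b": 0.1}, 0.1)
        assert fold == pytest.approx(1.0)
        assert ci == pytest.approx(0.0)

    def test_toy_set(self):
        fold, _ = mean_fold_derepression({"a": 2, "b": 2, "c": 3, "d": 3}, 1.0)
        assert fold == pytest.approx(2.5)

    def test_simulated_recovery_within_ci(self, mir17, model, small_screen):
        expr = quantify_screen(small_screen.tables, CONTROL_NONTARGETED_ID)
        singles = {v.variant_id: expr.loc[v.variant_id, "mean"] for v in enumerate_variants(mir17, 1)}
        fold, ci = mean_fold_derepression(singles, expr.loc["perfect", "mean"])
        true_folds = np.array(
            [small_screen.truth[v.variant_id] for v in enumerate_variants(mir17, 1)]
        ) / model.perfect_level
        assert abs(fold - true_folds.mean()) <= max(ci, 0.1)


class TestPositionEffectMatrix:
    def test_uniform_expression_fills_cells(self, mir17):
        expr = {v.variant_id: 0.5 for v in enumerate_variants(mir17, 1)}
        expr.update({v.variant_id: 0.5 for v in enumerate_variants(mir17, 2)})
        expr[CONTROL_NONTARGETED_ID] = 1.0  # ignored: not a canonical id
        single, double = position_effect_matrix(expr, mir17)
        assert single.notna().sum().sum() == 69
        vals = single.values[~np.isnan(single.values)]
        assert np.allclose(vals, 0.5)
        off_diag = double.values[~np.isnan(double.values)]
        assert len(off_diag) == 253 * 2 and np.allclose(off_diag, 0.5)

    def test_double_matrix_symmetry_and_nan_diagonal(self, mir17):
        expr = {v.variant_id: 0.1 + 0.3 * (v.positions()[0] % 3) for v in enumerate_variants(mir17, 2)}
        _, double = position_effect_matrix(expr, mir17)
        m = double.values
        assert np.isnan(np.diag(m)).all()
        mask = ~np.isnan(m)
        assert (mask == mask.T).all()
        assert np.allclose(m[mask], m.T[mask])

    def test_seed_boost_elevates_seed_columns(self, mir17, model, small_screen):
        expr = quantify_screen(small_screen.tables, CONTROL_NONTARGETED_ID)
        single, _ = position_effect_matrix(expr["mean"].to_dict(), mir17)
        seed_cols = [p for p in single.columns if mir17.region(p) == "seed"]
        other_cols = [p for p in single.columns if mir17.region(p) == "other"]
        assert single[seed_cols].mean().mean() > single[other_cols].mean().mean()


class TestDdct:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20.0, 20.0, 20.0, 20.0), 1.0),   # ddCt = 0
            ((21.0, 20.0, 20.0, 20.0), 0.5),   # ddCt = 1
            ((18.0, 20.0, 20.0, 20.0), 4.0),   # ddCt = -2
        ],
    )
    def test_worked_examples(self, cts, expected):
        assert ddct(*cts) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            ddct(float("nan"), 20.0, 20.0, 20.0)


class TestOracleEquivalence:
    def test_full_chain_matches_direct_computation(self, mir17, model):
        """Error-free reads -> trim/count/quantify equals direct frequency math."""
        cfg = ScreenSimConfig(
            mirna=mir17, model=model, seed=31, replicates=2,
            depths={"pDNA": 30_000, "cDNA": 30_000},
        )
        screen = simulate_screen(cfg)
        from misfit.simulate import reads_from_counts

        recounted = {}
        for lib in ("pDNA", "cDNA"):
            recounted[lib] = [
                trim_and_count(
                    reads_from_counts(
                        t, screen.sequences(), cfg.flank5, cfg.flank3, err_rate=0.0, seed=i
                    ),
                    screen.sequences(),
                    cfg.flank5,
                    library_id=lib,
                    replicate=t.replicate,
                )
                for i, t in enumerate(screen.tables[lib])
            ]
        via_reads = quantify_screen(recounted, CONTROL_NONTARGETED_ID)
        direct = quantify_screen(
            {lib: screen.tables[lib] for lib in ("pDNA", "cDNA")}, CONTROL_NONTARGETED_ID
        )
        diff = (via_reads["mean"] - direct["mean"]).abs()
        assert float(diff.max()) <= 1e-12

    def test_control_normalises_to_exactly_one(self, small_screen):
        expr = quantify_screen(small_screen.tables, CONTROL_NONTARGETED_ID)
        for col in ("expr_rep1", "expr_rep2", "expr_rep3", "mean"):
            assert expr.loc[CONTROL_NONTARGETED_ID, col] == 1.0

    def test_perfect_is_most_repressed_single(self, mir17, small_screen):
        expr = quantify_screen(small_screen.tables, CONTROL_NONTARGETED_ID)
        perfect = expr.loc["perfect", "mean"]
        singles = [expr.loc[v.variant_id, "mean"] for v in enumerate_variants(mir17, 1)]
        assert perfect < min(singles)

    def test_te_slope_tracks_te_gamma(self, mir17):
        """log TE regressed on log abundance recovers the simulator's coupling."""
        for gamma, expected in [(1.0, 1.0), (0.0, 0.0)]:
            m = GroundTruthModel.default(mir17, te_gamma=gamma)
            cfg = ScreenSimConfig(
                mirna=mir17, model=m, seed=41, replicates=1,
                depths={"pDNA": 400_000, "cDNA": 400_000, "monosome": 400_000, "heavy": 400_000},
            )
            screen = simulate_screen(cfg)
            expr = quantify_screen(screen.tables, CONTROL_NONTARGETED_ID)
            singles = [v.variant_id for v in enumerate_variants(mir17, 1)]
            x = np.log(expr.loc[singles, "mean"].values.astype(float))
            y = np.log(expr.loc[singles, "te_mean"].values.astype(float))
            fit = cross_context_fit(x, y)
            assert fit.slope == pytest.approx(expected, abs=0.1)


def test_pcr_error_accumulation():
    assert aggregate_pcr_error(36, 9.5e-7) == pytest.approx(3.42e-5)
    assert aggregate_pcr_error(0, 1e-6) == 0.0
    with pytest.raises(ValueError):
        aggregate_pcr_error(-1, 1e-6)
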