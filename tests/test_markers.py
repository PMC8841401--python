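import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptermark import (
    CountMatrix,
    MarkerConfig,
    SampleSheet,
    SimulationConfig,
    deg_gate,
    diagnosis_correlation,
    evaluate_recovery,
    joint_normalize,
    percentile,
    rank_top_markers,
    run_marker_pipeline,
    simulate_dataset,
    training_specificity,
    validation_specificity,
)
from ptermark.normalization import ExpressionMatrix
from conftest import nb_counts


def percentile_oracle(values, q):
    """Direct (n-1)q interpolation between order statistics."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestPercentile:
    @pytest.mark.parametrize("values,q,expected", [
        ([1, 2, 3, 4], 0.75, 3.25),
        (list(range(1, 11)), 0.10, 1.9),
        ([5.0], 0.3, 5.0),
    ])
    def test_worked_examples(self, values, q, expected):
        assert percentile(values, q) == pytest.approx(expected)

    def test_matches_interpolation_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = rng.integers(1, 30)
            v = rng.normal(size=n)
            q = rng.uniform()
            assert percentile(v, q) == pytest.approx(
                percentile_oracle(v, q), abs=1e-12)

    def test_empty_and_bad_q_rejected(self):
        with pytest.raises(ValueError):
            percentile([], 0.5)
        with pytest.raises(ValueError):
            percentile([1.0], 1.5)


def _expr(values, sample_ids, gene_ids=None):
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(gene_ids, sample_ids, values, "normalized_counts")


def _sheet(classes, cohorts, target="T"):
    ids = [f"s{i}" for i in range(len(classes))]
    frame = pd.DataFrame({"sample_id": ids, "tissue_class": classes,
                          "cohort": cohorts}).set_index("sample_id")
    return SampleSheet(frame, target)


class TestSpecificityFlags:
    def setup_method(self):
        # 12 training samples: 4 target, 4+4 controls; 3 validation targets
        self.classes = ["T"] * 4 + ["C1"] * 4 + ["C2"] * 4 + ["T"] * 3
        self.cohorts = ["training"] * 12 + ["validation"] * 3
        self.sheet = _sheet(self.classes, self.cohorts)
        self.ids = [f"s{i}" for i in range(15)]

    def test_strictly_above_all_other_classes(self):
        vals = np.array([[10.0] * 4 + [4.0] * 4 + [3.0] * 4 + [9.0] * 3])
        df = training_specificity(_expr(vals, self.ids), self.sheet)
        assert bool(df["train_specific"][0])
        assert df["q75_other_max"][0] == 4.0

    def test_boundary_tie_fails(self):
        vals = np.array([[4.0] * 4 + [4.0] * 4 + [1.0] * 4 + [4.0] * 3])
        df = training_specificity(_expr(vals, self.ids), self.sheet)
        assert not bool(df["train_specific"][0])

    def test_validation_gap_sign(self):
        vals = np.array([[10.0] * 4 + [4.0] * 4 + [3.0] * 4 + [10.0, 10.0, 10.0]])
        v = validation_specificity(_expr(vals, self.ids), self.sheet)
        assert v["val_gap"][0] == pytest.approx(6.0)
        assert bool(v["val_specific"][0])
        vals2 = np.array([[10.0] * 4 + [4.0] * 4 + [3.0] * 4 + [4.0, 4.0, 4.0]])
        v2 = validation_specificity(_expr(vals2, self.ids), self.sheet)
        assert v2["val_gap"][0] == pytest.approx(0.0)
        assert not bool(v2["val_specific"][0])

    def test_flags_match_bruteforce_recomputation_on_random_genes(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(2, 1, (500, 15))
        expr = _expr(vals, self.ids)
        t = training_specificity(expr, self.sheet)
        v = validation_specificity(expr, self.sheet)
        for i in range(500):
            q10_t = percentile_oracle(vals[i, :4], 0.10)
            q75s = [percentile_oracle(vals[i, 4:8], 0.75),
                    percentile_oracle(vals[i, 8:12], 0.75)]
            assert t["q10_target_train"][i] == pytest.approx(q10_t, abs=1e-12)
            assert t["q75_other_max"][i] == pytest.approx(max(q75s), abs=1e-12)
            assert bool(t["train_specific"][i]) == (q10_t > max(q75s))
            q10_v = percentile_oracle(vals[i, 12:], 0.10)
            assert v["val_gap"][i] == pytest.approx(q10_v - max(q75s), abs=1e-12)
            assert bool(v["val_specific"][i]) == (q10_v - max(q75s) > 0)


class TestDiagnosisCorrelation:
    def test_indicator_itself_gives_r_one(self):
        sheet = _sheet(["T"] * 3 + ["C"] * 3, ["training"] * 6)
        vals = np.array([[1.0, 1, 1, 0, 0, 0]])
        df = diagnosis_correlation(
            ExpressionMatrix(["g0"], [f"s{i}" for i in range(6)], vals, "log2"),
            sheet)
        assert df["pearson_r"][0] == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(3)
        sheet = _sheet(["T"] * 3 + ["C"] * 3, ["training"] * 6)
        vals = rng.normal(size=(20, 6))
        df = diagnosis_correlation(
            ExpressionMatrix([f"g{i}" for i in range(20)],
                             [f"s{i}" for i in range(6)], vals, "log2"), sheet)
        ind = np.array([1.0, 1, 1, 0, 0, 0])
        for i in range(20):
            r, p = stats.pearsonr(vals[i], ind)
            assert df["pearson_r"][i] == pytest.approx(r, abs=1e-12)
            assert df["pearson_p"][i] == pytest.approx(p, rel=1e-9)

    def test_null_false_positive_rate_at_strict_alpha(self):
        rng = np.random.default_rng(4)
        sheet = _sheet(["T"] * 8 + ["C"] * 8, ["training"] * 16)
        vals = rng.normal(size=(2000, 16))
        df = diagnosis_correlation(
            ExpressionMatrix([f"g{i}" for i in range(2000)],
                             [f"s{i}" for i in range(16)], vals, "log2"), sheet)
        assert (df["pearson_p"] < 0.001).mean() <= 0.005

    def test_zero_variance_gene_gets_na(self):
        sheet = _sheet(["T"] * 2 + ["C"] * 2, ["training"] * 4)
        vals = np.array([[3.0, 3, 3, 3]])
        df = diagnosis_correlation(
            ExpressionMatrix(["g"], [f"s{i}" for i in range(4)], vals, "log2"),
            sheet)
        assert np.isnan(df["pearson_r"][0])

    def test_single_class_rejected(self):
        sheet = _sheet(["T"] * 4, ["training"] * 4)
        vals = np.zeros((1, 4))
        with pytest.raises(ValueError):
            diagnosis_correlation(
                ExpressionMatrix(["g"], [f"s{i}" for i in range(4)], vals, "log2"),
                sheet)


class TestDegGate:
    def test_conjunction_over_all_control_classes(self, small_simulation):
        train, val, sheet, truth = small_simulation
        gate = deg_gate(train, sheet)
        flags = [c for c in gate.columns if c.startswith("pass_")]
        assert len(flags) == 2  # two control classes
        conj = gate[flags[0]] & gate[flags[1]]
        assert (gate["de_pass"] == conj).all()
        # markers should overwhelmingly pass, confounders should not
        gmap = gate.set_index("gene_id")["de_pass"]
        assert gmap.loc[truth.marker_gene_ids].mean() > 0.8
        assert gmap.loc[truth.background_de_ids].mean() < 0.2


class TestJointNormalize:
    def test_validation_copy_of_training_normalizes_identically(self):
        rng = np.random.default_rng(5)
        y = nb_counts(rng, rng.lognormal(3, 1, 100), 0.1, 4)
        train = CountMatrix([f"g{i}" for i in range(100)],
                            [f"t{j}" for j in range(4)], y)
        val = CountMatrix([f"g{i}" for i in range(100)],
                          [f"v{j}" for j in range(4)], y.copy())
        joint = joint_normalize(train, val)
        assert np.allclose(joint.values[:, :4], joint.values[:, 4:])

    def test_validation_scaling_invariance(self):
        """Tripling every validation library leaves normalized values unchanged."""
        rng = np.random.default_rng(6)
        mu = rng.lognormal(4, 1, 2000)
        y_t = nb_counts(rng, mu, 0.05, 6)
        y_v = nb_counts(rng, mu, 0.05, 4)
        genes = [f"g{i}" for i in range(2000)]
        train = CountMatrix(genes, [f"t{j}" for j in range(6)], y_t)
        val = CountMatrix(genes, [f"v{j}" for j in range(4)], y_v)
        val3 = CountMatrix(genes, [f"v{j}" for j in range(4)], y_v * 3)
        base = joint_normalize(train, val)
        scaled = joint_normalize(train, val3)
        assert np.allclose(base.values, scaled.values, rtol=1e-6)

    def test_disjoint_gene_sets_error(self):
        a = CountMatrix(["g1"], ["s1", "s2"], np.array([[1, 2]]))
        b = CountMatrix(["g2"], ["v1", "v2"], np.array([[1, 2]]))
        with pytest.raises(ValueError, match="intersection"):
            joint_normalize(a, b)


class TestRankTopMarkers:
    def _records(self, scores, genes=None):
        genes = genes or [f"g{i}" for i in range(len(scores))]
        return pd.DataFrame({
            "gene_id": genes, "top_score": scores,
            "train_specific": True, "val_specific": True,
        })

    def test_descending_rank(self):
        out = rank_top_markers(self._records([2.0, 6.0]))
        assert out["gene_id"].tolist() == ["g1", "g0"]
        assert out["rank"].tolist() == [1, 2]

    def test_tie_broken_lexicographically(self):
        out = rank_top_markers(self._records([3.0, 3.0], ["gB", "gA"]))
        assert out["gene_id"].tolist() == ["gA", "gB"]

    def test_nonspecific_rows_dropped_and_empty_ok(self):
        rec = self._records([1.0, 2.0])
        rec.loc[0, "val_specific"] = False
        out = rank_top_markers(rec)
        assert out["gene_id"].tolist() == ["g1"]
        assert rank_top_markers(rec.iloc[0:0]).empty


class TestMarkerPipeline:
    def test_planted_marker_recovery_single_seed(self, default_simulation):
        train, val, sheet, truth = default_simulation
        res = run_marker_pipeline(train, val, sheet)
        ev = evaluate_recovery(truth, res.specific["gene_id"])
        assert ev["sensitivity"] >= 0.9
        assert ev["fdr"] <= 0.1
        assert ev["confounders_called"] == 0

    def test_open_gates_admit_all_expressed_genes(self, small_simulation):
        train, val, sheet, _ = small_simulation
        cfg = MarkerConfig(lfc=-np.inf, deg_alpha=1.1, corr_alpha=1.1)
        res = run_marker_pipeline(train, val, sheet, cfg)
        expressed = ((train.counts.sum(axis=1) + val.counts.sum(axis=1)) > 0).sum()
        assert len(res.candidates) == expressed

    def test_empty_validation_cohort_errors(self, small_simulation):
        train, val, sheet, _ = small_simulation
        train_only = sheet.frame[sheet.frame["cohort"] == "training"]
        sheet_t = SampleSheet(train_only, sheet.target_class)
        empty_val = CountMatrix(val.gene_ids, [],
                                np.zeros((val.n_genes, 0), dtype=int),
                                val.feature_lengths)
        with pytest.raises(ValueError, match="validation"):
            run_marker_pipeline(train, empty_val, sheet_t)

    def test_threshold_monotonicity(self, small_simulation):
        """Tightening any threshold never enlarges candidate or marker sets."""
        train, val, sheet, _ = small_simulation
        prev_c, prev_s = None, None
        for lfc, alpha in [(1.0, 0.05), (2.0, 0.001), (3.0, 0.0001)]:
            cfg = MarkerConfig(lfc=lfc, deg_alpha=alpha, corr_alpha=alpha)
            res = run_marker_pipeline(train, val, sheet, cfg)
            cand = set(res.candidates["gene_id"])
            spec = set(res.specific["gene_id"])
            if prev_c is not None:
                assert cand <= prev_c
                assert spec <= prev_s
            prev_c, prev_s = cand, spec

    def test_determinism_byte_identical_outputs(self, tmp_path):
        from ptermark import write_table

        paths = []
        for run in (1, 2):
            train, val, sheet, _ = simulate_dataset(SimulationConfig(
                n_genes=300, classes=(("T", 4), ("C", 4)), target_class="T",
                n_validation=3, n_markers=10, n_background_de=5, seed=7))
            res = run_marker_pipeline(train, val, sheet)
            p = tmp_path / f"run{run}.tsv"
            write_table(res.dossier, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_dossier_flags_consistent_with_tables(self, small_simulation):
        train, val, sheet, _ = small_simulation
        res = run_marker_pipeline(train, val, sheet)
        d = res.dossier
        assert set(res.candidates["gene_id"]) == set(d.loc[d["candidate"], "gene_id"])
        assert set(res.specific["gene_id"]) == set(d.loc[d["marker"], "gene_id"])
        # pooling check: top_score from pooled target samples
        assert (d["train_specific"] == (d["q10_target_train"] > d["q75_other_max"])).all()
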