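"""Methylation statistics: QC, transforms, differential calls, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degronscreen.methylation import (
    FEATURE_PRIORITY,
    annotate_probes,
    beta_to_m,
    differential_test,
    enrichment_table,
    feature_enrichment,
    load_bed,
    m_to_beta,
    overlap_analysis,
    qc_filter,
)
from degronscreen.synthetic import gen_beta


def linear_scan_oracle(probes, features, rt):
    """Per-probe linear scan over every interval, applying the priority rule."""
    def rank(name):
        return FEATURE_PRIORITY.index(name) if name in FEATURE_PRIORITY else len(FEATURE_PRIORITY)

    out = []
    for _, row in probes.iterrows():
        point = int(row["pos"]) - 1
        best = None
        for order, (chrom, start, end, name) in enumerate(features or []):
            if chrom == row["chrom"] and start <= point < end:
                key = (rank(name), order)
                if best is None or key < best[0]:
                    best = (key, name)
        feature = best[1] if best else "intergenic"
        rt_class = "unassigned"
        for chrom, start, end, value in rt or []:
            if chrom == row["chrom"] and start <= point < end:
                v = float(value)
                rt_class = "early" if v > 0 else "late" if v < 0 else "unassigned"
                break
        out.append((row["probe_id"], feature, rt_class))
    return out


class TestQcFilter:
    def test_one_failing_sample_removes_probe(self):
        beta = pd.DataFrame(0.5, index=["p1", "p2"], columns=list("abcdef"))
        det = pd.DataFrame(0.001, index=["p1", "p2"], columns=list("abcdef"))
        det.loc["p1", "c"] = 0.06
        out = qc_filter(beta, det, 0.05)
        assert list(out.index) == ["p2"]

    def test_all_passing_identity(self):
        beta = pd.DataFrame(0.3, index=["p1", "p2"], columns=["a", "b"])
        det = pd.DataFrame(0.001, index=beta.index, columns=beta.columns)
        pd.testing.assert_frame_equal(qc_filter(beta, det), beta)

    def test_planted_failures_match_manifest(self):
        data = gen_beta(n_probes=200, n_affected=10, n_qc_fail=15, seed=6)
        out = qc_filter(data["beta"], data["detection_p"])
        removed = set(data["beta"].index) - set(out.index)
        assert removed == set(data["manifest"]["qc_fail_probes"])

    def test_missing_detection_p_error(self):
        beta = pd.DataFrame(0.5, index=["p1"], columns=["a"])
        with pytest.raises(ValueError):
            qc_filter(beta, None)


class TestBetaMTransforms:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_analytic_points(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            beta_to_m(1.5)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_round_trip(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-9)

    def test_frame_shape_preserved(self):
        df = pd.DataFrame([[0.1, 0.9], [0.5, 0.5]], index=["p1", "p2"], columns=["a", "b"])
        out = beta_to_m(df)
        assert isinstance(out, pd.DataFrame)
        assert list(out.index) == ["p1", "p2"]
        pd.testing.assert_frame_equal(m_to_beta(out), df)


class TestDifferentialTest:
    def _labels(self, n_test=3, n_ref=3):
        names = [f"t{i}" for i in range(n_test)] + [f"r{i}" for i in range(n_ref)]
        return pd.Series(
            ["test"] * n_test + ["ref"] * n_ref, index=names
        )

    def test_identical_groups_null(self):
        labels = self._labels()
        m = pd.DataFrame(
            np.tile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], (5, 1)),
            index=[f"p{i}" for i in range(5)],
            columns=labels.index,
        )
        calls = differential_test(m, labels, "test", "ref")
        assert (calls["logFC"] == 0).all()
        assert not calls["significant"].any()
        assert (calls["direction"] == "none").all()

    def test_constant_probe_gets_p_one(self):
        labels = self._labels()
        m = pd.DataFrame(
            [[2.0] * 6, [0, 1, 2, 3, 4, 5]], index=["const", "var"], columns=labels.index
        )
        calls = differential_test(m, labels, "test", "ref")
        assert calls.loc["const", "p_value"] == 1.0

    def test_direction_follows_logfc_sign(self):
        data = gen_beta(n_probes=300, n_affected=30, delta_m=3.0, noise=0.3, seed=2)
        labels = pd.Series(data["groups"])
        calls = differential_test(beta_to_m(data["beta"]), labels, "test", "ref")
        sig = calls[calls["significant"]]
        assert ((sig["logFC"] > 0) == (sig["direction"] == "hyper")).all()

    def test_planted_shift_recovery(self):
        """>=45/50 planted hyper probes found, few null calls, per seed."""
        for seed in range(5):
            data = gen_beta(n_probes=550, n_affected=50, delta_m=2.0, noise=0.5, seed=seed)
            labels = pd.Series(data["groups"])
            calls = differential_test(beta_to_m(data["beta"]), labels, "test", "ref")
            planted = set(data["manifest"]["affected_probes"])
            hyper = set(calls.index[calls["direction"] == "hyper"])
            assert len(planted & hyper) >= 45
            null_sig = (calls["significant"] & ~calls.index.isin(planted)).sum()
            assert null_sig <= 0.05 * 1.5 * 500

    def test_pure_null_type_i_error(self):
        """Unadjusted false-positive rate stays near alpha on null data."""
        rates = []
        for seed in range(20):
            data = gen_beta(n_probes=500, n_affected=0, delta_m=0.0, noise=0.5, seed=seed)
            labels = pd.Series(data["groups"])
            calls = differential_test(beta_to_m(data["beta"]), labels, "test", "ref")
            rates.append((calls["p_value"] <= 0.05).mean())
            assert calls["significant"].sum() <= 0.05 * 1.5 * 500
        assert np.mean(rates) <= 0.05 * 1.5

    def test_bh_step_up_hand_case(self):
        # p = (.01,.02,.03,.04): max p_(i) with p_(i) <= 0.05 i/4 is .04 -> all pass
        labels = self._labels()
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(4, 6)), columns=labels.index)
        calls = differential_test(
            m, labels, "test", "ref",
            engine=lambda t, r: np.array([0.01, 0.02, 0.03, 0.04]),
        )
        assert calls["significant"].all()
        assert calls["adj_p"].max() == pytest.approx(0.04)

    def test_small_group_error(self):
        labels = pd.Series(["test", "ref", "ref"], index=["a", "b", "c"])
        m = pd.DataFrame(np.ones((2, 3)), columns=labels.index)
        with pytest.raises(ValueError):
            differential_test(m, labels, "test", "ref")


class TestOverlap:
    def _calls(self, ids, direction="hyper"):
        return pd.DataFrame(
            {"direction": [direction] * len(ids)}, index=pd.Index(ids, name="probe_id")
        )

    def test_identical_sets_full_overlap(self):
        a = self._calls(["p1", "p2"])
        assert overlap_analysis(a, a, "hyper")["overlap_percent"] == 100.0

    def test_disjoint_zero(self):
        res = overlap_analysis(self._calls(["p1"]), self._calls(["p2"]), "hyper")
        assert res["overlap_percent"] == 0.0
        assert res["unique_to_a"] == ["p1"] and res["unique_to_b"] == ["p2"]

    def test_union_denominator_arithmetic(self):
        a = self._calls([f"p{i}" for i in range(30)])
        b = self._calls([f"p{i}" for i in range(20, 50)])
        res = overlap_analysis(a, b, "hyper")
        assert res["overlap_percent"] == pytest.approx(100 * 10 / 50)
        res_a = overlap_analysis(a, b, "hyper", denominator="a")
        assert res_a["overlap_percent"] == pytest.approx(100 * 10 / 30)


class TestAnnotateProbes:
    def test_containment_and_boundaries(self):
        probes = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "chrom": ["c1", "c1"], "pos": [151, 250]}
        )
        features = [("c1", 100, 200, "exon")]
        rt = [("c1", 100, 200, 0.0)]
        out = annotate_probes(probes, features, rt)
        assert out.loc["p1", "genomic_feature"] == "exon"
        assert out.loc["p1", "rt_class"] == "unassigned"  # RT value exactly 0
        assert out.loc["p2", "genomic_feature"] == "intergenic"

    def test_priority_on_overlap(self):
        probes = pd.DataFrame({"probe_id": ["p1"], "chrom": ["c1"], "pos": [150]})
        features = [("c1", 0, 300, "intron"), ("c1", 100, 200, "promoter-TSS")]
        out = annotate_probes(probes, features, None)
        assert out.loc["p1", "genomic_feature"] == "promoter-TSS"

    def test_rt_sign_rule(self):
        probes = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "chrom": ["c1", "c1"], "pos": [50, 150]}
        )
        rt = [("c1", 0, 100, 1.5), ("c1", 100, 200, -0.7)]
        out = annotate_probes(probes, None, rt)
        assert list(out["rt_class"]) == ["early", "late"]

    def test_matches_linear_scan_oracle(self, rng):
        chroms = ["c1", "c2"]
        features = []
        rt = []
        for _ in range(60):
            c = chroms[int(rng.integers(2))]
            s = int(rng.integers(0, 10_000))
            e = s + int(rng.integers(1, 500))
            features.append((c, s, e, str(rng.choice(FEATURE_PRIORITY + ["enhancer"]))))
        for c in chroms:
            edges = np.sort(rng.choice(10_000, size=8, replace=False))
            for s, e in zip(edges[:-1], edges[1:]):
                rt.append((c, int(s), int(e), float(rng.normal())))
        probes = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(10_000)],
                "chrom": rng.choice(chroms, size=10_000),
                "pos": rng.integers(1, 10_001, size=10_000),
            }
        )
        out = annotate_probes(probes, features, rt)
        oracle = linear_scan_oracle(probes, features, rt)
        got = list(zip(out.index, out["genomic_feature"], out["rt_class"]))
        assert got == oracle

    def test_malformed_bed_fatal_with_line(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("c1\t100\t200\texon\nc1\t300\t300\tintron\n")
        with pytest.raises(ValueError, match=":2"):
            load_bed(bad)


class TestFeatureEnrichment:
    def _setup(self, q, m, total, k, feature="exon"):
        n = total - m
        probes = [f"p{i}" for i in range(total)]
        ann = pd.DataFrame(
            {"genomic_feature": [feature] * m + ["intron"] * n},
            index=pd.Index(probes, name="probe_id"),
        )
        direction = (
            ["hyper"] * q + ["none"] * (m - q) + ["hyper"] * (k - q) + ["none"] * (n - (k - q))
        )
        calls = pd.DataFrame({"direction": direction}, index=ann.index)
        return calls, ann

    def test_proportional_null_bias_zero(self):
        # significant probes spread proportionally to feature size
        calls, ann = self._setup(q=10, m=100, total=200, k=20)
        r = feature_enrichment(calls, ann, "exon")
        assert r.bias_percent == pytest.approx(0.0)

    def test_half_array_feature_all_hits_inside(self):
        calls, ann = self._setup(q=20, m=100, total=200, k=20)
        r = feature_enrichment(calls, ann, "exon")
        assert r.bias_percent == pytest.approx(50.0)

    def test_conservation_over_partition(self):
        data = gen_beta(n_probes=400, n_affected=40, seed=3)
        labels = pd.Series(data["groups"])
        calls = differential_test(beta_to_m(data["beta"]), labels, "test", "ref")
        ann = annotate_probes(data["probes"], data["features"], data["rt"])
        table = enrichment_table(calls, ann, "hyper", columns=["genomic_feature"])
        assert table["q"].sum() == table["k"].iloc[0]

    def test_absent_feature_error(self):
        calls, ann = self._setup(q=1, m=10, total=20, k=2)
        with pytest.raises(ValueError, match="absent"):
            feature_enrichment(calls, ann, "TTS")

    def test_mismatched_universe_error(self):
        calls, ann = self._setup(q=1, m=10, total=20, k=2)
        with pytest.raises(ValueError, match="universe"):
            feature_enrichment(calls.iloc[:10], ann, "exon")

    def test_planted_enrichment_recovered(self):
        hits = 0
        for seed in range(20):
            data = gen_beta(
                n_probes=2000, n_affected=150, enrichment_ratio=3.0,
                affected_feature="exon", delta_m=2.0, noise=0.5, seed=seed,
            )
            labels = pd.Series(data["groups"])
            calls = differential_test(beta_to_m(data["beta"]), labels, "test", "ref")
            ann = annotate_probes(data["probes"], data["features"], data["rt"])
            r = feature_enrichment(calls, ann, "exon", "hyper")
            if r.bias_percent > 0 and r.p_hyper < 0.01:
                hits += 1
        assert hits >= 19
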