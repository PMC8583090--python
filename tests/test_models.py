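"""Cell-line matching, dose-response metrics, biomarker correlation, CN calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sigrev.models import (
    CellLineProfile,
    DoseResponseCurve,
    biomarker_correlation,
    cellline_similarity,
    dependency_efficacy_selectivity,
    dose_response_metrics,
    filter_cn_segments,
    gene_level_cn_summary,
    gistic_categorize,
    select_model_lines,
    sensitivity_table,
)
from sigrev.signatures import DiseaseSignature
from sigrev.simulate import (
    TOP2A_COORDS,
    SimulationConfig,
    generate_viability_screen,
    make_ground_truth,
)

from oracles import fisher_z_interval, pearson_direct


def _signature(n=60):
    genes = [f"g{i}" for i in range(n)]
    lfc = np.linspace(2.5, 1.1, n // 2).tolist() + np.linspace(-1.1, -2.5, n - n // 2).tolist()
    table = pd.DataFrame({"log2FC": lfc}, index=genes)
    up = frozenset(g for g, v in zip(genes, lfc) if v > 0)
    down = frozenset(g for g, v in zip(genes, lfc) if v < 0)
    return DiseaseSignature("sig", up, down, table)


def _line(name, expression, cn=None):
    cn = cn if cn is not None else pd.Series(1.0, index=expression.index)
    return CellLineProfile(cell_line=name, expression=expression, cn=cn)


class TestCelllineSimilarity:
    def _panel(self, sig, rng, n_other=10, scale=1.0):
        genes = list(sig.table.index)
        base = pd.Series(rng.uniform(3, 8, len(genes)), index=genes)
        lines = [
            _line("match", (base + scale * sig.table["log2FC"]).clip(lower=0)),
            _line("anti", (base - scale * sig.table["log2FC"]).clip(lower=0)),
        ]
        for i in range(n_other):
            lines.append(_line(f"bg{i}", base + rng.normal(0, 0.2, len(genes))))
        return lines

    def test_matched_construction_scores_near_one(self, rng):
        sig = _signature()
        sims = cellline_similarity(sig, self._panel(sig, rng))
        assert sims["match"] > 0.9
        assert sims["anti"] < -0.9

    def test_planted_tumorlike_lines_occupy_top_ranks(self):
        cfg = SimulationConfig(n_tumorlike_lines=5, seed=31)
        truth = make_ground_truth(cfg)[1]
        scr = generate_viability_screen(cfg, truth)
        genes = sorted(truth.de_genes)
        table = pd.DataFrame({"log2FC": [truth.de_genes[g] for g in genes]}, index=genes)
        sig = DiseaseSignature(
            "planted",
            frozenset(g for g in genes if truth.de_genes[g] > 0),
            frozenset(g for g in genes if truth.de_genes[g] < 0),
            table,
        )
        sims = cellline_similarity(sig, scr.profiles)
        assert set(sims.index[:5]) == set(scr.tumorlike_lines)

    def test_sparse_overlap_skipped_with_warning(self, rng):
        sig = _signature()
        tiny = _line("tiny", pd.Series([1.0, 2.0], index=["g0", "g1"]))
        with pytest.warns(UserWarning, match="tiny"):
            sims = cellline_similarity(sig, self._panel(sig, rng) + [tiny])
        assert "tiny" not in sims.index


class TestSelectModelLines:
    def test_consensus_covering_all_lines_gives_top_k(self):
        sims = pd.Series({"a": 0.9, "b": 0.8, "c": 0.7, "d": 0.1})
        assert select_model_lines(sims, ["a", "b", "c", "d"], k=3) == ["a", "b", "c"]

    def test_disjoint_consensus_falls_back_with_warning(self):
        sims = pd.Series({"a": 0.9, "b": 0.8, "c": 0.7})
        with pytest.warns(UserWarning, match="falling back"):
            chosen = select_model_lines(sims, ["zzz"], k=2)
        assert chosen == ["a", "b"]


class TestDoseResponseMetrics:
    def _curve(self, doses, values, drug="d", cl="c"):
        return DoseResponseCurve(
            drug, cl, pd.DataFrame({"dose_uM": doses, "viability_log2fc": values})
        )

    def test_flat_curve_auc_equals_its_level(self):
        doses = SimulationConfig().dose_ladder
        flat0 = dose_response_metrics(self._curve(doses, [0.0] * 8))
        flat2 = dose_response_metrics(self._curve(doses, [-2.0] * 8))
        assert flat0["auc"] == pytest.approx(0.0)
        assert flat0["low_dose_score"] == 0.0
        assert flat2["auc"] == pytest.approx(-2.0)

    def test_hill_curve_matches_fine_grid_quadrature(self):
        ic50, emax = 0.05, -3.0
        doses = np.logspace(-4, 1, 2000)
        hill = emax * doses / (doses + ic50)
        metric = dose_response_metrics(self._curve(doses, hill))
        fine = np.logspace(-4, 1, 10000)
        oracle = np.trapezoid(emax * fine / (fine + ic50), np.log10(fine)) / 5.0
        assert metric["auc"] == pytest.approx(oracle, abs=1e-3)
        # monotone non-increasing viability: the low-dose mean is the least
        # negative summary, so auc <= low_dose_score < 0
        assert metric["auc"] < metric["low_dose_score"] < 0

    def test_dose_axis_scaling_leaves_auc_unchanged(self):
        doses = np.array(SimulationConfig().dose_ladder)
        values = -2.0 * doses / (doses + 1)
        a1 = dose_response_metrics(self._curve(doses, values))["auc"]
        a2 = dose_response_metrics(self._curve(doses * 7.3, values))["auc"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_duplicate_doses_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            self._curve([1.0, 1.0, 2.0], [0, -1, -2])


class TestBiomarkerCorrelation:
    def _metrics(self, values, drug="d"):
        return pd.DataFrame(
            {
                "drug": drug,
                "cell_line": [f"L{i}" for i in range(len(values))],
                "auc": values,
            }
        )

    def test_perfect_feature_copy_gives_r_one(self, rng):
        sens = rng.normal(-1, 0.5, 10)
        lines = [
            _line(f"L{i}", pd.Series({"TOP2A": abs(sens[i])}), pd.Series({"TOP2A": sens[i]}))
            for i in range(10)
        ]
        out = biomarker_correlation(self._metrics(sens), lines, genes=["TOP2A"])
        cn_row = out[out["modality"] == "cn"].iloc[0]
        assert cn_row["r"] == pytest.approx(1.0)
        assert cn_row["p"] < 1e-9

    def test_matches_direct_pearson_formula(self, rng):
        sens = rng.normal(-1, 0.5, 20)
        feat = rng.normal(1, 0.2, 20)
        lines = [
            _line(f"L{i}", pd.Series({"g": 1.0}), pd.Series({"g": feat[i]})) for i in range(20)
        ]
        out = biomarker_correlation(self._metrics(sens), lines, genes=["g"])
        r = out[out["modality"] == "cn"]["r"].iloc[0]
        assert r == pytest.approx(pearson_direct(feat, sens), abs=1e-12)

    def test_null_feature_rarely_exceeds_sampling_band(self, rng):
        hits = 0
        for _ in range(200):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            hits += abs(pearson_direct(x, y)) >= 0.36
        assert hits <= 0.05 * 200 * 2  # |r|>=0.36 is the two-sided 5% band at n=30

    def test_planted_negative_link_recovered_within_fisher_interval(self):
        cfg = SimulationConfig(seed=77)
        truth = make_ground_truth(cfg)[1]
        scr = generate_viability_screen(cfg, truth)
        mets = sensitivity_table(scr.curves)
        out = biomarker_correlation(mets, scr.profiles, genes=[truth.biomarker_gene])
        linked = out[(out["modality"] == "cn") & out["drug"].isin(scr.linked_drugs)]
        lo, hi = fisher_z_interval(-0.8, n=cfg.n_screen_lines)
        assert lo <= linked["r"].median() <= hi

    def test_zero_variance_feature_flagged(self):
        lines = [_line(f"L{i}", pd.Series({"g": 1.0}), pd.Series({"g": 1.0})) for i in range(5)]
        out = biomarker_correlation(self._metrics([-1, -2, -3, -4, -5]), lines, genes=["g"])
        assert out["zero_variance"].all()
        assert out["r"].isna().all()


class TestSegmentFilter:
    def _segments(self, rows):
        return pd.DataFrame(
            rows, columns=["chromosome", "start", "end", "probe_count", "type", "sample"]
        )

    def test_boundary_thresholds_exact(self):
        seg = self._segments(
            [
                ("chr1", 0, 10_000, 24, "loss", "s"),
                ("chr1", 0, 10_000, 25, "loss", "s"),
                ("chr1", 0, 10_000, 49, "gain", "s"),
                ("chr1", 0, 10_000, 50, "gain", "s"),
                ("chr1", 0, 4_999_999, 10, "cnLOH", "s"),
                ("chr1", 0, 5_000_000, 10, "cnLOH", "s"),
            ]
        )
        out = filter_cn_segments(seg)
        assert len(out) == 3
        assert set(out["probe_count"][out["type"] == "loss"]) == {25}
        assert set(out["probe_count"][out["type"] == "gain"]) == {50}
        assert set(out["end"][out["type"] == "cnLOH"]) == {5_000_000}

    def test_idempotent_and_subset(self):
        seg = self._segments(
            [("chr1", 0, 10_000_000, k, t, "s") for k in (10, 30, 60) for t in ("loss", "gain", "cnLOH")]
        )
        once = filter_cn_segments(seg)
        twice = filter_cn_segments(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) <= len(seg)

    def test_unknown_type_dropped_and_logged(self):
        seg = self._segments([("chr1", 0, 10_000, 100, "mystery", "s")])
        out = filter_cn_segments(seg)
        assert out.empty
        assert out.attrs["n_rejected_type"] == 1


class TestGeneLevelCalls:
    def test_gene_inside_retained_gain_called_gain(self):
        seg = pd.DataFrame(
            [{"chromosome": "chr1", "start": 0, "end": 1000, "probe_count": 60, "type": "gain", "sample": "s1"}]
        )
        calls, _ = gene_level_cn_summary(seg, {"g": ("chr1", 100, 200)}, ["s1", "s2"])
        by = calls.set_index("sample")["state"]
        assert by["s1"] == "gain" and by["s2"] == "neutral"

    def test_equal_overlap_contradiction_is_ambiguous_neutral(self):
        seg = pd.DataFrame(
            [
                {"chromosome": "chr1", "start": 0, "end": 150, "probe_count": 60, "type": "gain", "sample": "s"},
                {"chromosome": "chr1", "start": 150, "end": 300, "probe_count": 60, "type": "loss", "sample": "s"},
            ]
        )
        calls, _ = gene_level_cn_summary(seg, {"g": ("chr1", 100, 200)}, ["s"])
        assert calls["state"].iloc[0] == "neutral"
        assert bool(calls["ambiguous"].iloc[0])

    def test_planted_biomarker_gain_frequency(self, default_config):
        """8 planted gains among 32 samples -> 25% gain frequency."""
        from sigrev.simulate import generate_cn_segments

        seg = generate_cn_segments(default_config, n_samples=32, n_gene_gains=8)
        retained = filter_cn_segments(seg)
        samples = [f"S{i:02d}" for i in range(1, 33)]
        _, freq = gene_level_cn_summary(retained, {"TOP2A": TOP2A_COORDS}, samples)
        gain = freq[(freq["gene"] == "TOP2A") & (freq["type"] == "gain")]
        assert gain["frequency"].iloc[0] == pytest.approx(0.25)


class TestGisticCategorize:
    def test_neutral_and_total_loss_anchors(self):
        assert gistic_categorize(1.0) == 0  # at ploidy
        assert gistic_categorize(0.0) == -2  # zero copies

    def test_monotone_nondecreasing_over_sorted_draws(self, rng):
        x = np.sort(rng.uniform(0, 2.5, 1000))
        cats = gistic_categorize(x)
        assert (np.diff(cats) >= 0).all()
        assert set(cats) == {-2, -1, 0, 1, 2}

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            gistic_categorize(float("nan"))


class TestDependencySummary:
    def _matrix(self, rows, n_lines=20):
        return pd.DataFrame(
            rows, index=[f"gene{i}" for i in range(len(rows))],
            columns=[f"L{i}" for i in range(n_lines)],
        )

    def test_pan_essential_gene_has_zero_selectivity(self):
        dep = self._matrix([[-1.0] * 20])
        out = dependency_efficacy_selectivity(dep)
        assert out["efficacy"].iloc[0] == pytest.approx(-1.0)
        assert out["selectivity"].iloc[0] == 0.0
        assert bool(out["constant_row"].iloc[0])

    def test_selective_gene_outranks_pan_essential(self):
        pan = [-1.0] * 20
        selective = [-1.0] * 2 + [0.0] * 18
        out = dependency_efficacy_selectivity(self._matrix([pan, selective]))
        assert out["selectivity"].iloc[1] > out["selectivity"].iloc[0]

    def test_planted_selective_gene_attains_max_selectivity(self, rng):
        mat = rng.normal(0, 0.05, size=(100, 30))
        mat[42, :5] = -1.0  # lethal in a small minority of lines only
        out = dependency_efficacy_selectivity(
            pd.DataFrame(mat, index=[f"gene{i}" for i in range(100)])
        )
        assert out["selectivity"].idxmax() == "gene42"

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError, match="10"):
            dependency_efficacy_selectivity(self._matrix([[-1.0] * 5], n_lines=5))
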