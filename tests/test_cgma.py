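"""Relative-expression profiles and arm-level sign-test bias calls."""

import numpy as np
import pandas as pd
import pytest

from renalclass import (
    ExpressionMatrix,
    ProbeAnnotation,
    SimulationConfig,
    cohort_bias_summary,
    regional_bias,
    relative_expression,
    simulate_expression,
)
from renalclass.cgma import RelativeExpressionMatrix


def _em(values, sample_prefix="s", labels=None):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(values.shape[0])],
        columns=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
    )
    lab = pd.Series(labels, index=df.columns) if labels is not None else None
    return ExpressionMatrix(df, lab)


def _annotation(n_probes, arm="1p", genes_per_probe=1):
    chrom, arm_letter = arm[:-1], arm[-1]
    rows = []
    for i in range(n_probes):
        rows.append(
            {
                "probe_id": f"p{i}",
                "gene_symbol": f"G{i // genes_per_probe}",
                "chromosome": chrom,
                "arm": arm_letter,
                "cytoband": f"{arm}11",
                "position": 1000 * (i + 1),
            }
        )
    return ProbeAnnotation(pd.DataFrame(rows))


class TestRelativeExpression:
    def test_matches_definition(self):
        tumors = _em([[5.0, 7.0], [3.0, 3.0]])
        normals = _em([[4.0, 6.0], [1.0, 5.0]], sample_prefix="n")
        R = relative_expression(tumors, normals)
        np.testing.assert_allclose(R.values.to_numpy(), [[0.0, 2.0], [0.0, 0.0]])

    def test_brute_force_on_random_data(self):
        rng = np.random.default_rng(0)
        tumors = _em(rng.normal(8, 1, (50, 6)))
        normals = _em(rng.normal(8, 1, (50, 4)), sample_prefix="n")
        R = relative_expression(tumors, normals)
        for i in range(50):
            for j in range(6):
                expected = tumors.values.iloc[i, j] - normals.values.iloc[i].mean()
                assert R.values.iloc[i, j] == pytest.approx(expected, rel=1e-12)

    def test_probe_mismatch_names_offender(self):
        tumors = _em(np.ones((3, 2)))
        normals = ExpressionMatrix(
            pd.DataFrame(np.ones((3, 2)), index=["p0", "p1", "pX"], columns=["n0", "n1"])
        )
        with pytest.raises(ValueError, match="pX"):
            relative_expression(tumors, normals)

    def test_labels_carried_over(self):
        tumors = _em(np.ones((2, 2)), labels=["A", "B"])
        normals = _em(np.zeros((2, 3)), sample_prefix="n")
        assert relative_expression(tumors, normals).labels.tolist() == ["A", "B"]


class TestRegionalBias:
    def test_sixteen_positive_genes_give_z_four_gain(self):
        R = RelativeExpressionMatrix(
            pd.DataFrame(np.full((16, 1), 0.5), index=[f"p{i}" for i in range(16)], columns=["s0"])
        )
        out = regional_bias(R, _annotation(16))
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["n_genes"], row["n_positive"]) == (16, 16)
        assert row["z"] == pytest.approx(4.0)
        assert row["call"] == "gain"
        assert row["region"] == "1p"

    def test_half_and_half_is_neutral(self):
        vals = np.array([0.5] * 8 + [-0.5] * 8)[:, None]
        R = RelativeExpressionMatrix(
            pd.DataFrame(vals, index=[f"p{i}" for i in range(16)], columns=["s0"])
        )
        row = regional_bias(R, _annotation(16)).iloc[0]
        assert row["z"] == pytest.approx(0.0)
        assert row["call"] == "neutral"

    def test_exact_zeros_excluded_from_count(self):
        vals = np.array([0.5] * 12 + [0.0] * 4)[:, None]
        R = RelativeExpressionMatrix(
            pd.DataFrame(vals, index=[f"p{i}" for i in range(16)], columns=["s0"])
        )
        row = regional_bias(R, _annotation(16)).iloc[0]
        assert row["n_genes"] == 12
        assert row["z"] == pytest.approx(np.sqrt(12))

    def test_negating_r_flips_call_and_z(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0.4, 1.0, size=(30, 3))
        idx = [f"p{i}" for i in range(30)]
        R = RelativeExpressionMatrix(pd.DataFrame(vals, index=idx, columns=["s0", "s1", "s2"]))
        Rneg = RelativeExpressionMatrix(pd.DataFrame(-vals, index=idx, columns=["s0", "s1", "s2"]))
        ann = _annotation(30)
        a = regional_bias(R, ann).set_index("sample")
        b = regional_bias(Rneg, ann).set_index("sample")
        np.testing.assert_allclose(a["z"].to_numpy(), -b["z"].to_numpy())
        flip = {"gain": "loss", "loss": "gain", "neutral": "neutral"}
        assert [flip[c] for c in a["call"]] == list(b["call"])

    def test_probes_collapse_to_genes_by_mean(self):
        # two probes per gene with opposite signs averaging positive
        vals = np.tile([[1.0], [-0.4]], (10, 1))
        R = RelativeExpressionMatrix(
            pd.DataFrame(vals, index=[f"p{i}" for i in range(20)], columns=["s0"])
        )
        row = regional_bias(R, _annotation(20, genes_per_probe=2)).iloc[0]
        assert row["n_genes"] == 10
        assert row["n_positive"] == 10

    def test_small_arm_skipped(self):
        R = RelativeExpressionMatrix(
            pd.DataFrame(np.ones((5, 1)), index=[f"p{i}" for i in range(5)], columns=["s0"])
        )
        out = regional_bias(R, _annotation(5), min_genes=10)
        assert out.empty

    def test_no_overlap_rejected(self):
        R = RelativeExpressionMatrix(pd.DataFrame(np.ones((2, 1)), index=["qa", "qb"], columns=["s0"]))
        with pytest.raises(ValueError, match="overlap"):
            regional_bias(R, _annotation(4))

    def test_null_data_call_rate_is_low(self):
        cfg = SimulationConfig(n_discriminative=0, arm_biases=[])
        tumors, normals, annotation, _ = simulate_expression(cfg, seed=21)
        out = regional_bias(relative_expression(tumors, normals), annotation)
        rate = float((out["call"] != "neutral").mean())
        # two-sided normal test at 1.96 on null arms: ~5% calls
        assert rate < 0.12

    def test_biased_arms_recovered_in_default_study(self, default_sim):
        R = relative_expression(default_sim["tumors"], default_sim["normals"])
        out = regional_bias(R, default_sim["annotation"])
        labels = default_sim["tumors"].labels
        biased_arms = {b.arm for b in default_sim["config"].arm_biases if b.class_name == "chRCC"}
        sub = out[out["sample"].map(labels).eq("chRCC") & out["region"].isin(biased_arms)]
        assert not sub.empty
        assert (sub["call"] == "loss").mean() >= 0.9


class TestCohortSummary:
    def test_fractions_by_region_and_cohort(self):
        calls = pd.DataFrame(
            {
                "sample": ["s0", "s1", "s2", "s0", "s1", "s2"],
                "region": ["1p"] * 3 + ["2q"] * 3,
                "call": ["loss", "loss", "neutral", "gain", "neutral", "neutral"],
            }
        )
        labels = pd.Series({"s0": "A", "s1": "A", "s2": "B"})
        out = cohort_bias_summary(calls, labels).set_index(["region", "cohort"])
        assert out.loc[("1p", "A"), "loss_fraction"] == pytest.approx(1.0)
        assert out.loc[("1p", "B"), "loss_fraction"] == pytest.approx(0.0)
        assert out.loc[("2q", "A"), "gain_fraction"] == pytest.approx(0.5)
        assert (out["n_samples"].to_numpy() == [2, 1, 2, 1]).all()

    def test_empty_calls_give_empty_summary(self):
        out = cohort_bias_summary(pd.DataFrame(), pd.Series(dtype=object))
        assert out.empty
        assert list(out.columns) == ["region", "cohort", "n_samples", "gain_fraction", "loss_fraction"]

    def test_default_study_cohort_separation(self, default_sim):
        R = relative_expression(default_sim["tumors"], default_sim["normals"])
        calls = regional_bias(R, default_sim["annotation"])
        summary = cohort_bias_summary(calls, default_sim["tumors"].labels)
        sub = summary.set_index(["region", "cohort"])
        # chRCC loses both arms of chromosome 1; oncocytoma does not lose 1q
        assert sub.loc[("1q", "chRCC"), "loss_fraction"] >= 0.9
        assert sub.loc[("1q", "oncocytoma"), "loss_fraction"] <= 0.2
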