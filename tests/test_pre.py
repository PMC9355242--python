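import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spinsight import (
    IntensityTable,
    classify_against_structure,
    compare_attenuation,
    compute_ratios,
    make_pre_dataset,
    normalize_to_max,
)
from spinsight.pre import PRERatioTable, simulate_null_rejection_rate
from spinsight.errors import CoverageError, PairingError, SelfComparisonError


def table(condition, rows):
    return IntensityTable(
        data=pd.DataFrame(rows, columns=["residue_id", "intensity", "noise_rms"]),
        condition=condition,
    )


class TestComputeRatios:
    def test_equal_intensities_propagate_noise(self):
        para = table("para", [("I1", 100.0, 5.0)])
        dia = table("dia", [("I1", 100.0, 5.0)])
        out = compute_ratios(para, dia).data
        assert out.loc[0, "ratio"] == pytest.approx(1.0)
        assert out.loc[0, "sigma"] == pytest.approx(np.sqrt(2) * 0.05, abs=1e-6)

    def test_attenuated_residue(self):
        para = table("para", [("I1", 20.0, 2.0)])
        dia = table("dia", [("I1", 100.0, 5.0)])
        out = compute_ratios(para, dia).data
        assert out.loc[0, "ratio"] == pytest.approx(0.2)
        assert out.loc[0, "sigma"] == pytest.approx(0.2 * np.sqrt(0.01 + 0.0025), abs=1e-6)

    def test_sigma_linear_in_noise(self):
        para1 = table("para", [("I1", 50.0, 3.0)])
        dia1 = table("dia", [("I1", 80.0, 4.0)])
        para2 = table("para", [("I1", 50.0, 6.0)])
        dia2 = table("dia", [("I1", 80.0, 8.0)])
        s1 = compute_ratios(para1, dia1).data.loc[0, "sigma"]
        s2 = compute_ratios(para2, dia2).data.loc[0, "sigma"]
        assert s2 == pytest.approx(2 * s1)

    def test_disjoint_tables_rejected(self):
        para = table("para", [("I1", 10.0, 1.0)])
        dia = table("dia", [("I2", 10.0, 1.0)])
        with pytest.raises(PairingError):
            compute_ratios(para, dia)

    def test_scale_invariance_of_normalized_table(self):
        rows = [("I1", 40.0, 2.0), ("I2", 90.0, 3.0), ("I3", 70.0, 2.5)]
        para = table("para", rows)
        dia = table("dia", [("I1", 100.0, 5.0), ("I2", 100.0, 5.0), ("I3", 100.0, 5.0)])
        scaled = table("para", [(r, 3.7 * i, 3.7 * n) for r, i, n in rows])
        t1 = normalize_to_max(compute_ratios(para, dia)).data
        t2 = normalize_to_max(compute_ratios(scaled, dia)).data
        assert np.allclose(t1["norm_ratio"], t2["norm_ratio"])
        assert np.allclose(t1["norm_sigma"], t2["norm_sigma"])


class TestNormalizeToMax:
    def test_reference_is_argmax(self):
        t = PRERatioTable(
            data=pd.DataFrame(
                {"residue_id": ["A", "B", "C"], "ratio": [0.5, 1.25, 1.0], "sigma": [0.1] * 3}
            )
        )
        out = normalize_to_max(t)
        assert out.reference_residue == "B"
        assert np.allclose(out.data["norm_ratio"], [0.4, 1.0, 0.8])

    def test_single_row_normalizes_to_one(self):
        t = PRERatioTable(data=pd.DataFrame({"residue_id": ["A"], "ratio": [0.7], "sigma": [0.1]}))
        assert normalize_to_max(t).data.loc[0, "norm_ratio"] == pytest.approx(1.0)

    def test_idempotent(self):
        t = PRERatioTable(
            data=pd.DataFrame(
                {"residue_id": ["A", "B"], "ratio": [0.5, 1.0], "sigma": [0.1, 0.1]}
            )
        )
        once = normalize_to_max(t)
        twice = normalize_to_max(PRERatioTable(data=once.data.rename(columns={})))
        assert np.allclose(once.data["norm_ratio"], twice.data["norm_ratio"])


def three_ref_table(target_ratio, target_sigma=0.03, ref_sigma=0.02):
    df = pd.DataFrame(
        {
            "residue_id": ["R1", "R2", "R3", "T"],
            "ratio": [1.0, 1.0, 1.0, target_ratio],
            "sigma": [ref_sigma] * 3 + [target_sigma],
        }
    )
    return PRERatioTable(data=df)


class TestCompareAttenuation:
    def test_null_case_is_not_significant(self):
        out = compare_attenuation(three_ref_table(1.0), "T", ["R1", "R2", "R3"])
        assert out["z"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(0.5)
        assert not out["significant_05"]

    def test_single_reference_z_arithmetic(self):
        # ref 1.00 (sigma 0.02), target 0.90 (sigma 0.03):
        # z = 0.10/sqrt(0.0013) = 2.7735, one-sided p = 0.00277
        df = pd.DataFrame(
            {"residue_id": ["R", "T"], "ratio": [1.0, 0.9], "sigma": [0.02, 0.03]}
        )
        out = compare_attenuation(PRERatioTable(data=df), "T", ["R"])
        assert out["z"] == pytest.approx(0.10 / np.sqrt(0.0013), abs=1e-6)
        assert out["p"] == pytest.approx(float(stats.norm.sf(2.7735)), abs=1e-4)
        assert out["significant_05"] and out["significant_01"]

    def test_self_comparison_rejected(self):
        with pytest.raises(SelfComparisonError):
            compare_attenuation(three_ref_table(0.9), "T", ["T", "R1"])

    def test_missing_residue_reported(self):
        with pytest.raises(CoverageError):
            compare_attenuation(three_ref_table(0.9), "T", ["R1", "R9"])

    def test_type_i_error_near_nominal(self):
        rate = simulate_null_rejection_rate(10_000, seed=11)
        assert rate == pytest.approx(0.05, abs=0.01)


class TestClassifyAgainstStructure:
    def setup_method(self):
        self.table = PRERatioTable(
            data=pd.DataFrame(
                {
                    "residue_id": ["near", "far", "candidate", "I252/I420"],
                    "ratio": [0.2, 0.95, 0.40, 0.5],
                    "sigma": [0.02] * 4,
                }
            )
        )
        self.distances = {"near": 12.0, "far": 40.0, "candidate": 40.0, "I252": 12.0, "I420": 32.0}

    def test_concordant_and_discordant_rows(self):
        out = classify_against_structure(self.table, self.distances).set_index("residue_id")
        assert out.loc["near", "expected"] == "attenuated"
        assert out.loc["near", "observed"] == "attenuated"
        assert bool(out.loc["near", "concordant"])
        assert out.loc["far", "expected"] == "unaffected"
        assert bool(out.loc["far", "concordant"])
        # strong attenuation at 40 A: minor-conformer candidate
        assert out.loc["candidate", "observed"] == "attenuated"
        assert not bool(out.loc["candidate", "concordant"])

    def test_merged_id_uses_minimum_distance(self):
        out = classify_against_structure(self.table, self.distances).set_index("residue_id")
        assert out.loc["I252/I420", "distance_A"] == pytest.approx(12.0)

    def test_missing_distance_is_coverage_error(self):
        with pytest.raises(CoverageError):
            classify_against_structure(self.table, {"near": 12.0})


class TestSyntheticRoundTrip:
    def test_zero_noise_unequal_scales_full_concordance(self):
        ds = make_pre_dataset(scale_para=0.6, scale_dia=1.4, noise_rms=0.0, seed=2)
        t = normalize_to_max(compute_ratios(ds.para, ds.dia))
        cls = classify_against_structure(
            t, dict(zip(ds.truth["residue_id"], ds.truth["distance_A"]))
        )
        merged = cls.merge(ds.truth, on="residue_id", suffixes=("", "_true"))
        assert (merged["observed"] == merged["expected_true"]).all()
        assert merged["concordant"].all()

    def test_normalization_cancels_global_scales(self):
        a = make_pre_dataset(scale_para=1.0, scale_dia=1.0, noise_rms=0.0, seed=3)
        b = make_pre_dataset(scale_para=0.25, scale_dia=2.0, noise_rms=0.0, seed=3)
        ta = normalize_to_max(compute_ratios(a.para, a.dia)).data
        tb = normalize_to_max(compute_ratios(b.para, b.dia)).data
        # agreement up to the positive-intensity floor on bleached signals
        assert np.allclose(ta["norm_ratio"], tb["norm_ratio"], atol=1e-6)
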