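"""Standard-curve fitting, relative quantification and derived indices."""

import math

import numpy as np
import pandas as pd
import pytest

from splicexport import qpcr_quant as qq
from splicexport import synthetic_data as sd
from splicexport.exceptions import FitError, ParameterError, SchemaError


def _perfect_series(efficiency=2.0, intercept=25.0, dilutions=(1, 0.1, 0.01, 1e-3, 1e-4)):
    logc = np.log10(dilutions)
    cq = intercept - logc / math.log10(efficiency)
    return logc, cq


class TestStandardCurve:
    def test_perfect_tenfold_series_gives_efficiency_two(self):
        logc, cq = _perfect_series()
        curve = qq.fit_standard_curve(logc, cq)
        assert curve.efficiency == pytest.approx(2.0, abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0)

    def test_constant_cq_rejected(self):
        with pytest.raises(FitError):
            qq.fit_standard_curve([0, -1, -2], [20.0, 20.0, 20.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            qq.fit_standard_curve([0, -1], [20, 23.3])

    def test_noiseless_generator_curves_recovered(self):
        spec = sd.CqSpec(efficiencies={"ACTB": 2.0, "ATM_pre": 1.85}, seed=1)
        table, truth = sd.generate_cq_table(spec)
        curves = qq.fit_curves_from_table(table)
        for primer, eff in truth.efficiencies.items():
            assert curves[primer].efficiency == pytest.approx(eff, abs=1e-9)
            assert curves[primer].intercept == pytest.approx(truth.intercept, abs=1e-9)


class TestQuantify:
    def test_cq_at_intercept_is_unit_concentration(self):
        curve = qq.fit_standard_curve(*_perfect_series(intercept=24.0))
        assert qq.quantify(24.0, curve) == pytest.approx(1.0, rel=1e-9)

    def test_one_cycle_earlier_doubles_concentration(self):
        curve = qq.fit_standard_curve(*_perfect_series())
        assert qq.quantify(24.0, curve) / qq.quantify(25.0, curve) == pytest.approx(2.0, rel=1e-9)

    def test_generate_fit_quantify_round_trip(self):
        conc = [
            {"primer": "ACTB", "sample": f"s{i}", "condition": "c",
             "compartment": "nuclear", "concentration": v}
            for i, v in enumerate((3.0, 0.37, 0.0041))
        ]
        table, _ = sd.generate_cq_table(
            sd.CqSpec(efficiencies={"ACTB": 1.9}, true_concentrations=conc, seed=2)
        )
        quantified = qq.quantify_table(table)
        got = quantified.sort_values("sample")["concentration"].to_numpy()
        np.testing.assert_allclose(got, [3.0, 0.37, 0.0041], rtol=1e-9)


class TestNormalization:
    def test_target_equal_reference_gives_ones(self):
        np.testing.assert_allclose(qq.normalize_to_reference([2.0, 5.0], [2.0, 5.0]), 1.0)

    def test_linearity(self):
        base = qq.normalize_to_reference([1.0, 2.0], [4.0, 4.0])
        doubled = qq.normalize_to_reference([2.0, 4.0], [4.0, 4.0])
        np.testing.assert_allclose(doubled, 2 * base)

    def test_nonpositive_reference_flagged_nan(self):
        out = qq.normalize_to_reference([1.0, 1.0], [0.0, 2.0])
        assert np.isnan(out[0]) and out[1] == 0.5


class TestQc:
    def test_purity_pass_fail_and_indeterminate(self):
        assert qq.purity_check(0.0, 5.0) == "pass"
        assert qq.purity_check(1.0, 1.0, max_ratio=0.1) == "fail"
        assert qq.purity_check(1.0, 0.0) == "indeterminate"

    def test_purity_threshold_sweep_monotone(self):
        ratio_pairs = [(0.01, 1.0), (0.05, 1.0), (0.2, 1.0), (0.9, 1.0)]
        passes = []
        for max_ratio in (0.5, 0.1, 0.02):
            passes.append(sum(qq.purity_check(c, n, max_ratio) == "pass"
                              for c, n in ratio_pairs))
        assert passes == sorted(passes, reverse=True)

    def test_rt_minus_flags_recovered_exactly(self):
        spec = sd.CqSpec(
            efficiencies={"ACTB": 2.0, "ATM_pre": 1.9, "MALAT1": 2.0},
            contaminated_primers=("ATM_pre",),
            seed=3,
        )
        table, truth = sd.generate_cq_table(spec)
        qc = qq.rt_minus_check(table).set_index("primer")["status"]
        assert qc["ATM_pre"] == "fail"
        assert qc["ACTB"] == "pass" and qc["MALAT1"] == "pass"


def _scenario_table(export_scale=1.0, pre_scale=1.0, post_scale=1.0, seed=4):
    """Control vs knockdown samples for one transcript with pre/post primers."""
    primers = {"ACTB": 2.0, "ATM_pre": 1.9, "ATM_post": 1.95}
    conc = []
    for cond, perturbed in (("siCtrl", False), ("siTHRAP3+siBCLAF1", True)):
        for compartment in ("nuclear", "cytoplasmic"):
            sample = f"{cond}_{compartment}"
            pre = 0.05 * (pre_scale if perturbed else 1.0)
            post = 0.5 * (post_scale if perturbed else 1.0)
            if compartment == "cytoplasmic":
                post *= export_scale if perturbed else 1.0
            conc += [
                {"primer": "ACTB", "sample": sample, "condition": cond,
                 "compartment": compartment, "concentration": 1.0},
                {"primer": "ATM_pre", "sample": sample, "condition": cond,
                 "compartment": compartment, "concentration": pre},
                {"primer": "ATM_post", "sample": sample, "condition": cond,
                 "compartment": compartment, "concentration": post},
            ]
    table, _ = sd.generate_cq_table(
        sd.CqSpec(efficiencies=primers, true_concentrations=conc, seed=seed)
    )
    return table


class TestSplicingExportIndices:
    def test_identical_compartments_give_unit_nc_ratio(self):
        table = _scenario_table()
        indices = qq.splicing_export_indices(qq.quantify_table(table))
        ctrl = indices[indices["condition"] == "siCtrl"]
        pre = ctrl[ctrl["kind"] == "pre_spliced"].iloc[0]
        assert pre["nc_ratio"] == pytest.approx(1.0, rel=1e-9)

    def test_export_defect_scales_nc_ratio_by_inverse_factor(self):
        table = _scenario_table(export_scale=1 / math.e)
        indices = qq.splicing_export_indices(qq.quantify_table(table))
        post = indices[indices["kind"] == "post_spliced"].set_index("condition")
        ratio = post.loc["siTHRAP3+siBCLAF1", "nc_ratio"] / post.loc["siCtrl", "nc_ratio"]
        assert ratio == pytest.approx(math.e, rel=1e-9)

    def test_splicing_defect_reproduces_planted_factors(self):
        table = _scenario_table(pre_scale=3.0, post_scale=0.25)
        indices = qq.splicing_export_indices(qq.quantify_table(table))
        nucl = indices.set_index(["kind", "condition"])
        pre_ratio = (nucl.loc[("pre_spliced", "siTHRAP3+siBCLAF1"), "nuclear"]
                     / nucl.loc[("pre_spliced", "siCtrl"), "nuclear"])
        post_ratio = (nucl.loc[("post_spliced", "siTHRAP3+siBCLAF1"), "nuclear"]
                      / nucl.loc[("post_spliced", "siCtrl"), "nuclear"])
        assert pre_ratio == pytest.approx(3.0, rel=1e-9)
        assert post_ratio == pytest.approx(0.25, rel=1e-9)

    def test_missing_compartment_flagged(self):
        table = _scenario_table()
        quantified = qq.quantify_table(table)
        quantified = quantified[quantified["compartment"] != "cytoplasmic"]
        indices = qq.splicing_export_indices(quantified)
        assert (indices["nc_ratio_flag"] == "missing_compartment").all()

    def test_indices_invariant_under_global_concentration_rescale(self):
        t1 = _scenario_table(seed=5)
        quantified = qq.quantify_table(t1)
        scaled = quantified.assign(concentration=quantified["concentration"] * 37.0)
        i1 = qq.splicing_export_indices(quantified)
        i2 = qq.splicing_export_indices(scaled)
        np.testing.assert_allclose(i1["normalized"].to_numpy()
                                   if "normalized" in i1 else i1["nuclear"].to_numpy(),
                                   i2["nuclear"].to_numpy() if "normalized" in i1
                                   else i2["nuclear"].to_numpy(), rtol=1e-9)
        np.testing.assert_allclose(i1["nc_ratio"].to_numpy(), i2["nc_ratio"].to_numpy(),
                                   rtol=1e-9)

    def test_missing_reference_rejected(self):
        table = _scenario_table()
        quantified = qq.quantify_table(table)
        with pytest.raises(SchemaError):
            qq.splicing_export_indices(quantified[quantified["primer"] != "ACTB"])


class TestEndToEndRecovery:
    def test_noiseless_chain_recovers_true_relative_values(self):
        table = _scenario_table(export_scale=0.4, pre_scale=2.0, post_scale=0.5, seed=6)
        indices = qq.splicing_export_indices(qq.quantify_table(table))
        vals = indices.set_index(["kind", "condition"])
        # normalized nuclear pre-spliced: 0.05 control, 0.1 knockdown (ACTB = 1)
        assert vals.loc[("pre_spliced", "siCtrl"), "nuclear"] == pytest.approx(0.05, rel=1e-6)
        assert vals.loc[("pre_spliced", "siTHRAP3+siBCLAF1"), "nuclear"] == pytest.approx(
            0.1, rel=1e-6
        )
        assert vals.loc[("post_spliced", "siTHRAP3+siBCLAF1"), "cytoplasmic"] == pytest.approx(
            0.5 * 0.5 * 0.4, rel=1e-6
        )

    def test_noisy_chain_median_relative_error_under_ten_percent(self):
        errors = []
        for seed in range(12):
            conc = [
                {"primer": "ACTB", "sample": "s", "condition": "c",
                 "compartment": "nuclear", "concentration": 1.0},
                {"primer": "ATM_post", "sample": "s", "condition": "c",
                 "compartment": "nuclear", "concentration": 0.37},
            ]
            table, _ = sd.generate_cq_table(sd.CqSpec(
                efficiencies={"ACTB": 2.0, "ATM_post": 1.95},
                true_concentrations=conc, cq_noise_sd=0.2,
                n_technical_reps=3, seed=seed,
            ))
            q = qq.quantify_table(table).set_index("primer")["concentration"]
            normalized = q["ATM_post"] / q["ACTB"]
            errors.append(abs(normalized - 0.37) / 0.37)
        assert np.median(errors) < 0.10
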