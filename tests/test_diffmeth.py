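"""Regression scans: oracle agreement, calibration, power, consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methlink import SimulationConfig, diffmeth
from methlink.errors import (
    CohortCompositionError,
    InputDataError,
    InsufficientDataError,
    InsufficientVariationError,
    SingularDesignError,
)
from methlink.simulate import simulate_methylation_cohort


def bh_stepup_oracle(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def normal_equations_oracle(y, X):
    """Coefficients and t-test p-values from explicit normal equations."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    pvals = 2 * stats.t.sf(np.abs(beta / se), dof)
    return beta, pvals


class TestFitLinearModel:
    def test_exact_disease_indicator_recovered(self):
        rng = np.random.default_rng(0)
        disease = np.repeat([0.0, 1.0], 20)
        design = pd.DataFrame({"disease": disease, "age": rng.normal(50, 10, 40)})
        coef, p = diffmeth.fit_linear_model(disease, design, "disease")
        assert coef == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-12

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = 12
            design = pd.DataFrame(
                {"x": rng.normal(size=n), "z": rng.normal(size=n)}
            )
            y = 2.0 * design["x"] - 0.5 * design["z"] + rng.normal(size=n)
            coef, p = diffmeth.fit_linear_model(y, design, "x")
            X = np.column_stack([np.ones(n), design.to_numpy()])
            beta, pvals = normal_equations_oracle(y, X)
            assert coef == pytest.approx(beta[1], abs=1e-10)
            assert p == pytest.approx(pvals[1], rel=1e-8)

    def test_null_p_values_are_uniform(self):
        # 1000 independent null responses, n=40: rejection rate near nominal
        rng = np.random.default_rng(7)
        n = 40
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        Y = rng.normal(size=(1000, n))
        _, pvals = diffmeth._ols_scan(Y, X, 1)
        assert 0.03 <= np.mean(pvals < 0.05) <= 0.07

    def test_rank_deficiency_names_collinear_columns(self):
        n = 20
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        design = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(SingularDesignError):
            diffmeth.fit_linear_model(rng.normal(size=n), design, "x")

    def test_too_few_observations_raise(self):
        design = pd.DataFrame({"x": [1.0, 2.0, 3.0], "z": [0.0, 1.0, 0.0]})
        with pytest.raises(InsufficientDataError):
            diffmeth.fit_linear_model([1.0, 2.0, 3.0], design, "x")

    def test_listwise_deletion_of_missing_values(self):
        design = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, np.nan, 6.0]})
        y = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 999.0, 12.0]
        coef, _ = diffmeth.fit_linear_model(y, design, "x")
        assert coef == pytest.approx(2.0, abs=1e-10)


class TestBHAdjust:
    def test_worked_example(self):
        adj = diffmeth.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones(self):
        assert diffmeth.bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(diffmeth.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputDataError):
            diffmeth.bh_adjust([0.5, 1.2])
        with pytest.raises(InputDataError):
            diffmeth.bh_adjust([])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=60)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_stepup_oracle(self, pvec):
        adj = diffmeth.bh_adjust(pvec)
        oracle = bh_stepup_oracle(pvec)
        assert np.allclose(adj, oracle, atol=1e-12)
        assert adj.max() <= 1.0 and np.all(adj >= np.asarray(pvec) - 1e-15)


def _planted_cohort(seed, **kw):
    base = dict(
        genes=("GA", "GB", "GC", "GD", "GE"),
        n_probes_per_gene=10,
        fraction_affected=0.5,
        disease_effect=0.5,
        hyper_fraction=1.0,
        n_decoy_distal=0,
        n_decoy_snp=0,
    )
    base.update(kw)
    config = SimulationConfig(**base)
    return config, simulate_methylation_cohort(config, "discovery", seed=seed)


def _probe_sets(truth):
    out = {}
    for gene, sub in truth.probes.groupby("gene"):
        ok = (sub["tss_distance"].abs() <= 1500) & ~sub["snp_overlap"]
        out[gene] = set(sub.loc[ok, "probe_id"])
    return out


class TestDiscoveryScan:
    def test_planted_probes_detected_nulls_spared(self):
        # 5 genes, 5 of 10 probes planted each: per replicate >=4/5 of planted
        # probes detected on average and at most ~1 of 5 nulls per gene
        hits, false_hits = 0, 0
        reps = 20
        for seed in range(reps):
            config, cohort = _planted_cohort(seed)
            scan = diffmeth.discovery_scan(cohort.beta, cohort.samples, _probe_sets(cohort.truth))
            truth = cohort.truth.probes.set_index("probe_id")
            merged = scan.join(truth[["affected"]], on="probe_id")
            planted_sig = merged.loc[merged["affected"], "significant"]
            null_sig = merged.loc[~merged["affected"], "significant"]
            hits += int(planted_sig.mean() >= 0.8)
            false_hits += int(null_sig.mean() <= 0.2)
        assert hits >= 0.9 * reps
        assert false_hits >= 0.9 * reps

    def test_null_cohort_yields_no_discoveries(self):
        clean = 0
        for seed in range(10):
            config, cohort = _planted_cohort(
                seed + 100, disease_effect=0.0, genes=tuple(f"G{i}" for i in range(20))
            )
            scan = diffmeth.discovery_scan(cohort.beta, cohort.samples, _probe_sets(cohort.truth))
            clean += int(scan["significant"].sum() <= 2)
        assert clean >= 9

    def test_sample_order_permutation_invariant(self):
        config, cohort = _planted_cohort(3)
        scan1 = diffmeth.discovery_scan(cohort.beta, cohort.samples, _probe_sets(cohort.truth))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort.samples))
        samples2 = cohort.samples.iloc[perm].reset_index(drop=True)
        beta2 = cohort.beta.iloc[:, rng.permutation(cohort.beta.shape[1])]
        scan2 = diffmeth.discovery_scan(beta2, samples2, _probe_sets(cohort.truth))
        pd.testing.assert_frame_equal(scan1, scan2)

    def test_agrees_with_single_fit_path(self):
        # the vectorised scan must reproduce statsmodels per-probe fits
        config, cohort = _planted_cohort(5)
        probe_sets = _probe_sets(cohort.truth)
        scan = diffmeth.discovery_scan(cohort.beta, cohort.samples, probe_sets)
        meta = cohort.samples.set_index("sample_id")
        design = pd.DataFrame(
            {
                "disease": (meta["diagnosis"] != "control").astype(float),
                "age": meta["age"].astype(float),
                "sex": (meta["sex"] == "male").astype(float),
                "bmi": meta["bmi"].astype(float),
            }
        )
        for row in scan.drop_duplicates("probe_id").itertuples(index=False):
            y = cohort.beta.loc[row.probe_id, design.index]
            coef, p = diffmeth.fit_linear_model(y, design, "disease")
            assert row.coefficient == pytest.approx(coef, abs=1e-8)
            assert row.raw_p == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_missing_diagnosis_class_raises(self):
        config, cohort = _planted_cohort(6)
        controls_only = cohort.samples[cohort.samples["diagnosis"] == "control"]
        beta = cohort.beta[list(controls_only["sample_id"])]
        with pytest.raises(CohortCompositionError):
            diffmeth.discovery_scan(beta, controls_only, _probe_sets(cohort.truth))


class TestValidationScan:
    def _staged_cohort(self, seed, **kw):
        config = SimulationConfig(
            genes=("GA",),
            n_probes_per_gene=6,
            disease_effect=0.5,
            hyper_fraction=1.0,
            n_decoy_distal=0,
            n_decoy_snp=0,
            **kw,
        )
        return simulate_methylation_cohort(config, "validation", seed=seed)

    def test_fibrosis_detected_steatosis_spared(self):
        # effects are driven by fibrosis stage; steatosis carries no signal
        fib_ok, ste_ok = 0, 0
        reps = 20
        for seed in range(reps):
            cohort = self._staged_cohort(seed)
            sets = _probe_sets(cohort.truth)
            fib = diffmeth.validation_scan(cohort.beta, cohort.samples, sets, "fibrosis")
            ste = diffmeth.validation_scan(cohort.beta, cohort.samples, sets, "steatosis")
            truth = cohort.truth.probes.set_index("probe_id")
            planted = truth.index[truth["affected"]]
            fib_ok += int(fib.set_index("probe_id").loc[planted, "significant"].mean() >= 2 / 3)
            ste_ok += int(ste["significant"].mean() <= 1 / 3)
        assert fib_ok >= 0.9 * reps
        assert ste_ok >= 0.9 * reps

    def test_detected_signs_match_planted_direction(self):
        for seed in range(5):
            cohort = self._staged_cohort(seed + 50)
            fib = diffmeth.validation_scan(
                cohort.beta, cohort.samples, _probe_sets(cohort.truth), "fibrosis"
            )
            truth = cohort.truth.probes.set_index("probe_id")
            detected = fib[fib["significant"]].join(truth[["affected", "logit_effect"]], on="probe_id")
            planted = detected[detected["affected"]]
            assert (np.sign(planted["coefficient"]) == np.sign(planted["logit_effect"])).all()

    def test_constant_stage_variable_raises(self):
        cohort = self._staged_cohort(1)
        samples = cohort.samples.copy()
        samples["fibrosis_stage"] = 1.0
        with pytest.raises(InsufficientVariationError):
            diffmeth.validation_scan(cohort.beta, samples, _probe_sets(cohort.truth), "fibrosis")

    def test_no_fdr_column_in_validation(self):
        cohort = self._staged_cohort(2)
        fib = diffmeth.validation_scan(cohort.beta, cohort.samples, _probe_sets(cohort.truth))
        assert fib["adjusted_p"].isna().all()


class TestConsistency:
    def _results(self, fdr_d, p_v, coef_d, coef_v):
        disc = pd.DataFrame(
            {
                "gene": ["G"],
                "probe_id": ["cg1"],
                "coefficient": [coef_d],
                "raw_p": [fdr_d / 2],
                "adjusted_p": [fdr_d],
            }
        )
        val = pd.DataFrame(
            {"gene": ["G"], "probe_id": ["cg1"], "coefficient": [coef_v], "raw_p": [p_v]}
        )
        return disc, val

    @pytest.mark.parametrize(
        "fdr_d,p_v,coef_d,coef_v,validated,direction",
        [
            (0.01, 0.01, 0.3, 0.2, True, "hyper"),
            (0.01, 0.01, -0.3, -0.2, True, "hypo"),
            (0.01, 0.01, 0.3, -0.2, False, None),  # sign disagreement
            (0.01, 0.2, 0.3, 0.2, False, None),  # validation miss
            (0.2, 0.01, 0.3, 0.2, False, None),  # discovery miss
        ],
    )
    def test_validation_truth_table(self, fdr_d, p_v, coef_d, coef_v, validated, direction):
        disc, val = self._results(fdr_d, p_v, coef_d, coef_v)
        out = diffmeth.consistent_validated_sites(disc, val)
        assert (len(out) == 1) is validated
        if validated:
            assert out.loc[0, "direction"] == direction
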