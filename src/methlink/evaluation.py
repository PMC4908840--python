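"""Synthetic benchmark experiments for the pipeline's statistical guarantees.

Three seeded experiments quantify how the analysis behaves under its own
generative model:

* :func:`null_calibration` — type-I error of the per-probe discovery scan
  and the FDR-significant fraction under a global null;
* :func:`chain_sensitivity` — sensitivity of the full discovery +
  validation + consistency chain for planted logit effects;
* :func:`gamma_recovery` — recovery of planted methylation-expression
  coupling slopes by the robust association stage, run in the
  expression-on-methylation orientation where the generative slope lives.

Problem sizes default to the study's cohort sizes (74 / 54 / 50) with probe
counts chosen so each experiment completes in seconds.
"""

from __future__ import annotations

import numpy as np

from . import diffmeth, genelevel, methexpr, simulate


def _probe_sets_from_truth(truth: simulate.GroundTruth) -> dict[str, set[str]]:
    out = {}
    for gene, sub in truth.probes.groupby("gene"):
        ok = (sub["tss_distance"].abs() <= 1500) & ~sub["snp_overlap"]
        out[gene] = set(sub.loc[ok, "probe_id"])
    return out


def null_calibration(
    seed: int, n_reps: int = 20, n_genes: int = 25, n_probes_per_gene: int = 8
) -> dict:
    """Discovery-scan calibration under a global null (no planted effects).

    Returns the pooled fraction of raw p-values below 0.05 (nominal: 0.05)
    and the mean fraction of FDR-significant probes per replicate.
    """
    rng = np.random.default_rng(seed)
    raw_hits = total = 0
    fdr_fractions = []
    for _ in range(n_reps):
        config = simulate.SimulationConfig(
            genes=tuple(f"NULL{i:03d}" for i in range(n_genes)),
            n_probes_per_gene=n_probes_per_gene,
            disease_effect=0.0,
            n_decoy_distal=0,
            n_decoy_snp=0,
        )
        cohort = simulate.simulate_methylation_cohort(
            config, "discovery", seed=int(rng.integers(2**31 - 1))
        )
        scan = diffmeth.discovery_scan(
            cohort.beta, cohort.samples, _probe_sets_from_truth(cohort.truth)
        )
        per_probe = scan.drop_duplicates("probe_id")
        raw_hits += int((per_probe["raw_p"] < 0.05).sum())
        total += len(per_probe)
        fdr_fractions.append(per_probe["significant"].mean())
    return {
        "raw_rejection_rate": raw_hits / total,
        "fdr_significant_fraction": float(np.mean(fdr_fractions)),
        "n_tests": total,
    }


def chain_sensitivity(
    seed: int, effect: float = 0.5, n_reps: int = 20, n_genes: int = 10
) -> dict:
    """Sensitivity of discovery + validation + consistency for planted probes.

    Planted logit effects of ``effect`` drive both the case-control contrast
    and the fibrosis-stage gradient; sensitivity is the pooled fraction of
    planted probes that survive the whole chain with the correct sign.
    """
    rng = np.random.default_rng(seed)
    n_planted = n_validated = n_sign_correct = 0
    for _ in range(n_reps):
        config = simulate.SimulationConfig(
            genes=tuple(f"EFF{i:03d}" for i in range(n_genes)),
            disease_effect=effect,
            hyper_fraction=1.0,
            n_decoy_distal=0,
            n_decoy_snp=0,
        )
        study = simulate.simulate_study(config, seed=int(rng.integers(2**31 - 1)))
        sets = _probe_sets_from_truth(study.truth)
        disc = diffmeth.discovery_scan(study.discovery.beta, study.discovery.samples, sets)
        val = diffmeth.validation_scan(
            study.validation.beta, study.validation.samples, sets, "fibrosis"
        )
        validated = diffmeth.consistent_validated_sites(disc, val)
        truth = study.truth.probes
        planted = truth.loc[truth["affected"]]
        n_planted += len(planted)
        got = validated.merge(planted, on=["gene", "probe_id"])
        n_validated += len(got)
        n_sign_correct += int(
            (np.sign(got["coef_discovery"]) == np.sign(got["logit_effect"])).sum()
        )
    return {
        "sensitivity": n_validated / n_planted,
        "sign_accuracy": n_sign_correct / max(n_validated, 1),
        "n_planted": n_planted,
    }


def gamma_recovery(
    seed: int,
    gammas: tuple[float, ...] = (-1.0, -0.5, 0.5),
    n_reps: int = 20,
    n_genes: int = 10,
) -> dict:
    """Median recovered coupling slope per planted gamma.

    Each replicate simulates ``n_genes`` coupled genes at n=50 matched
    samples, runs the full chain to gene-level M-value profiles, and fits
    the robust association in the expression-on-methylation orientation; the
    median over all replicate x gene estimates is reported per gamma.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for gamma in gammas:
        estimates = []
        for _ in range(n_reps):
            config = simulate.SimulationConfig(
                genes=tuple(f"CPL{i:03d}" for i in range(n_genes)),
                disease_effect=0.5,
                hyper_fraction=1.0,
                coupled_fraction=1.0,
                coupling_slope=gamma,
                n_decoy_distal=0,
                n_decoy_snp=0,
            )
            study = simulate.simulate_study(config, seed=int(rng.integers(2**31 - 1)))
            sets = _probe_sets_from_truth(study.truth)
            disc = diffmeth.discovery_scan(study.discovery.beta, study.discovery.samples, sets)
            val = diffmeth.validation_scan(
                study.validation.beta, study.validation.samples, sets, "fibrosis"
            )
            validated = diffmeth.consistent_validated_sites(disc, val)
            profiles = genelevel.gene_methylation_profiles(study.ec.beta, validated)
            fib = (
                study.ec.samples.set_index("sample_id")["fibrosis_stage"]
            )
            expr = study.ec.expression
            for (gene, _), sub in profiles.groupby(["gene", "direction"]):
                sub = sub.set_index("sample_id")
                shared = [s for s in sub.index if s in expr.columns]
                fit = methexpr.robust_regression(
                    sub.loc[shared, "m_value"].to_numpy(),
                    expr.loc[gene, shared].to_numpy(),
                    fib.loc[shared].to_numpy(),
                    response="expr",
                )
                estimates.append(fit.coefficient)
        out[gamma] = {
            "median_estimate": float(np.median(estimates)),
            "n_estimates": len(estimates),
        }
    return out
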