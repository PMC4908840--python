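"""Synthetic matched methylation/expression cohorts with planted effects.

The generator emulates the structure of a three-cohort liver methylation
study: a case-control discovery cohort (n=74: 45 controls, 29 NAFLD), a
staged NAFLD-only validation cohort (n=54, fibrosis stage 0-2 and steatosis
grade 0-3 recorded) and a matched methylation+expression cohort (n=50: 30
controls, 20 NAFLD).

The generative model is logit-normal: for probe j and sample i,

    logit(beta_ij) = a_j + b_j * (disease_i + s_f * fibrosis_i)
                     + c_age * age_i + c_sex * sex_i + c_bmi * bmi_i
                     + u_{g(j),i} + e_ij

where ``a_j`` is the probe baseline, ``b_j`` the planted logit effect of a
probe (zero for unaffected probes, sign = hyper/hypo direction), ``u`` a
shared per-gene per-sample component (promoter CpGs are co-methylated) and
``e`` probe-level noise.  Working on the logit scale makes planted effects
linear on the analysis (M-value) scale; beta shifts of ~3-6 % at mid-range
baselines correspond to the default disease effect of 0.2 logits.

Expression for gene g in sample i is

    x_gi = mu_g + gamma_g * Mbar_gi + delta_g * fibrosis_i + eta_gi

with ``Mbar`` the gene-level M-value of sample i: the M transform of the
mean beta over the gene's affected probes — the same statistic (average
first, transform second) the analysis computes — so a planted coupling
slope ``gamma`` is exactly the quantity the association stage estimates
when run in the expression-on-methylation orientation.

Every cohort carries a ground-truth ledger (per-probe direction and effect,
per-gene coupling slope) so downstream stages are testable without array
downloads.  All randomness flows from numpy Generators seeded explicitly;
identical (config, seed) pairs reproduce matrices bitwise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import annotation as ann
from .errors import ConfigurationError, MethlinkError

logger = logging.getLogger(__name__)

BETA_EPS = 1e-6
_LOG2E = 1.0 / np.log(2.0)

#: stage distributions approximating the published cohort tables
_VALIDATION_FIBROSIS_P = (0.0, 0.593, 0.407)
_VALIDATION_STEATOSIS_P = (0.074, 0.426, 0.296, 0.204)
_EC_FIBROSIS_P = {
    "control": (0.90, 0.10, 0.0),
    "SS": (0.77, 0.23, 0.0),
    "NASH": (0.57, 0.29, 0.14),
}
_EC_STEATOSIS_P = {
    "control": (0.77, 0.23, 0.0, 0.0),
    "SS": (0.0, 0.15, 0.39, 0.46),
    "NASH": (0.0, 0.0, 0.14, 0.86),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the published study conditions: cohort sizes 74/54/50,
    per-probe logit disease effects of 0.2 (≈3-6 % beta shift at mid-range
    baselines), fibrosis-stage effects of the same magnitude per stage, and
    no steatosis effect (fibrosis, not steatosis, drives the methylation
    signal).  ``genes=None`` uses the built-in bile-acid and drug-metabolism
    cluster members laid out on a synthetic chromosome.
    """

    genes: tuple[str, ...] | None = None
    n_discovery: int = 74
    n_discovery_controls: int = 45
    n_validation: int = 54
    n_ec: int = 50
    n_ec_controls: int = 30
    n_probes_per_gene: int = 8
    n_decoy_distal: int = 2
    n_decoy_snp: int = 1
    probe_window: int = ann.TSS_WINDOW
    gene_spacing: int = 100_000
    fraction_affected: float = 0.5
    hyper_fraction: float = 0.75
    baseline_logit_mean: float = 0.0
    baseline_logit_sd: float = 1.0
    disease_effect: float = 0.2
    fibrosis_effect_scale: float = 1.0
    steatosis_effect: float = 0.0
    age_effect: float = 0.004
    sex_effect: float = 0.05
    bmi_effect: float = 0.004
    gene_noise_sd: float = 0.4
    probe_noise_sd: float = 0.3
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 1.0
    coupling_slope: float = -0.5
    coupled_fraction: float = 0.4
    expression_fibrosis_effect: float = -0.3
    expression_noise_sd: float = 0.5
    neighbor_coupling: Mapping[tuple[str, str], float] = field(default_factory=dict)
    null_genes: tuple[str, ...] = ()  # genes forced to carry no planted effects
    female_fraction: float = 0.72
    age_mean: float = 50.0
    age_sd: float = 12.0
    bmi_mean: float = 40.0
    bmi_sd: float = 10.0
    truth_seed: int | None = None

    def validate(self) -> None:
        for name in ("n_discovery", "n_validation", "n_ec", "n_probes_per_gene"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.n_discovery_controls < self.n_discovery:
            raise ConfigurationError("n_discovery_controls must split the discovery cohort")
        if not 0 < self.n_ec_controls < self.n_ec:
            raise ConfigurationError("n_ec_controls must split the EC cohort")
        for name in (
            "baseline_logit_sd",
            "gene_noise_sd",
            "probe_noise_sd",
            "expression_noise_sd",
            "expression_baseline_sd",
            "age_sd",
            "bmi_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("fraction_affected", "hyper_fraction", "coupled_fraction", "female_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_decoy_distal < 0 or self.n_decoy_snp < 0:
            raise ConfigurationError("decoy counts must be >= 0")

    def gene_list(self) -> tuple[str, ...]:
        if self.genes is not None:
            return tuple(g.upper() for g in self.genes)
        c1, c2 = ann.builtin_gene_clusters()
        seen: dict[str, None] = {}
        for g in c1.genes + c2.genes:
            seen.setdefault(g)
        return tuple(seen)


@dataclass
class GroundTruth:
    """Planted effects: one row per probe and one per gene."""

    probes: pd.DataFrame  # probe_id, gene, tss_distance, snp_overlap, affected, direction, logit_effect
    genes: pd.DataFrame  # gene, chrom, tss_pos, strand, mu, gamma, delta, affected_fraction
    seed: int

    def probe_records(self) -> list[ann.ProbeRecord]:
        tss = dict(zip(self.genes["gene"], self.genes["tss_pos"]))
        chrom = dict(zip(self.genes["gene"], self.genes["chrom"]))
        return [
            ann.ProbeRecord(
                probe_id=r.probe_id,
                chrom=chrom[r.gene],
                pos=int(tss[r.gene] + r.tss_distance),
                gene=r.gene,
                tss_distance=int(r.tss_distance),
                snp_overlap=bool(r.snp_overlap),
            )
            for r in self.probes.itertuples(index=False)
        ]

    def gene_records(self) -> list[ann.GeneRecord]:
        return [
            ann.GeneRecord(gene=r.gene, chrom=r.chrom, tss_pos=int(r.tss_pos), strand=r.strand)
            for r in self.genes.itertuples(index=False)
        ]


@dataclass
class SimulatedCohort:
    """One cohort: beta matrix (probes x samples), metadata, optional expression."""

    role: str
    beta: pd.DataFrame
    samples: pd.DataFrame
    truth: GroundTruth
    expression: pd.DataFrame | None = None
    seed: int | None = None


def draw_ground_truth(config: SimulationConfig, seed: int) -> GroundTruth:
    """Draw probe placements and planted effects shared across cohorts."""
    config.validate()
    rng = np.random.default_rng(seed)
    genes = config.gene_list()

    gene_rows = []
    for i, gene in enumerate(genes):
        gene_rows.append(
            {
                "gene": gene,
                "chrom": "chrS1",
                "tss_pos": 1_000_000 + i * config.gene_spacing,
                "strand": "+" if i % 2 == 0 else "-",
                "mu": config.expression_baseline_mean
                + config.expression_baseline_sd * rng.standard_normal(),
                "gamma": 0.0,
                "delta": 0.0,
                "affected_fraction": config.fraction_affected,
            }
        )
    gene_df = pd.DataFrame(gene_rows)
    null_genes = {g.upper() for g in config.null_genes}
    coupled = (rng.random(len(genes)) < config.coupled_fraction) & ~gene_df["gene"].isin(
        null_genes
    ).to_numpy()
    gene_df.loc[coupled, "gamma"] = config.coupling_slope
    gene_df.loc[coupled, "delta"] = config.expression_fibrosis_effect

    probe_rows = []
    counter = 0
    w = config.probe_window
    for gene in genes:
        n_in = config.n_probes_per_gene
        n_affected = int(round(config.fraction_affected * n_in))
        if gene in null_genes:
            n_affected = 0
        affected_idx = rng.choice(n_in, size=n_affected, replace=False)
        hyper = rng.random(n_in) < config.hyper_fraction
        dists = rng.integers(-w, w + 1, size=n_in)
        for j in range(n_in):
            counter += 1
            is_affected = j in affected_idx
            direction = "null"
            effect = 0.0
            if is_affected:
                direction = "hyper" if hyper[j] else "hypo"
                effect = config.disease_effect if hyper[j] else -config.disease_effect
            probe_rows.append(
                {
                    "probe_id": f"cgS{counter:06d}",
                    "gene": gene,
                    "tss_distance": int(dists[j]),
                    "snp_overlap": False,
                    "affected": is_affected,
                    "direction": direction,
                    "logit_effect": effect,
                }
            )
        # decoys exercising the annotation filter: distal and SNP-flagged, never affected
        for _ in range(config.n_decoy_distal):
            counter += 1
            sign = 1 if rng.random() < 0.5 else -1
            probe_rows.append(
                {
                    "probe_id": f"cgS{counter:06d}",
                    "gene": gene,
                    "tss_distance": int(sign * rng.integers(w + 1, 4 * w)),
                    "snp_overlap": False,
                    "affected": False,
                    "direction": "null",
                    "logit_effect": 0.0,
                }
            )
        for _ in range(config.n_decoy_snp):
            counter += 1
            probe_rows.append(
                {
                    "probe_id": f"cgS{counter:06d}",
                    "gene": gene,
                    "tss_distance": int(rng.integers(-w, w + 1)),
                    "snp_overlap": True,
                    "affected": False,
                    "direction": "null",
                    "logit_effect": 0.0,
                }
            )
    return GroundTruth(probes=pd.DataFrame(probe_rows), genes=gene_df, seed=seed)


def _simulate_samples(config: SimulationConfig, role: str, rng: np.random.Generator) -> pd.DataFrame:
    if role == "discovery":
        n = config.n_discovery
        n_control = config.n_discovery_controls
        n_nafld = n - n_control
        diagnosis = ["control"] * n_control + ["SS"] * (n_nafld // 2) + ["NASH"] * (
            n_nafld - n_nafld // 2
        )
    elif role == "validation":
        n = config.n_validation
        diagnosis = ["unknown"] * n  # NAFLD-only, SS/NASH split not recorded
    elif role == "ec":
        n = config.n_ec
        n_control = config.n_ec_controls
        n_nafld = n - n_control
        n_ss = int(round(n_nafld * 0.65))
        diagnosis = ["control"] * n_control + ["SS"] * n_ss + ["NASH"] * (n_nafld - n_ss)
    else:
        raise ConfigurationError(f"unknown cohort role: {role!r}")

    df = pd.DataFrame(
        {
            "sample_id": [f"{role}_{i:03d}" for i in range(n)],
            "cohort": role,
            "diagnosis": diagnosis,
            "age": np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 85).round(1),
            "sex": np.where(rng.random(n) < config.female_fraction, "female", "male"),
            "bmi": np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 17, 75).round(1),
        }
    )
    fibrosis = np.full(n, np.nan)
    steatosis = np.full(n, np.nan)
    if role == "validation":
        fibrosis = rng.choice(3, size=n, p=_VALIDATION_FIBROSIS_P).astype(float)
        steatosis = rng.choice(4, size=n, p=_VALIDATION_STEATOSIS_P).astype(float)
    elif role == "ec":
        for i, diag in enumerate(diagnosis):
            fibrosis[i] = rng.choice(3, p=_EC_FIBROSIS_P[diag])
            steatosis[i] = rng.choice(4, p=_EC_STEATOSIS_P[diag])
    df["fibrosis_stage"] = fibrosis
    df["steatosis_grade"] = steatosis
    return df


def simulate_methylation_cohort(
    config: SimulationConfig,
    cohort_role: str,
    seed: int,
    truth: GroundTruth | None = None,
) -> SimulatedCohort:
    """Simulate one cohort's beta matrix and sample table.

    Deterministic given ``(config, seed)``; ``truth`` may be shared across
    cohorts so that the same planted probe effects are measured in each.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = draw_ground_truth(config, seed=int(rng.integers(2**31 - 1)))
    samples = _simulate_samples(config, cohort_role, rng)
    n = len(samples)

    probes = truth.probes
    n_probes = len(probes)
    baseline = rng.normal(config.baseline_logit_mean, config.baseline_logit_sd, n_probes)

    disease = (samples["diagnosis"] != "control").to_numpy(float)
    fibrosis = samples["fibrosis_stage"].fillna(0.0).to_numpy(float)
    steatosis = samples["steatosis_grade"].fillna(0.0).to_numpy(float)
    severity = disease + config.fibrosis_effect_scale * fibrosis
    covar = (
        config.age_effect * (samples["age"].to_numpy(float) - config.age_mean)
        + config.sex_effect * (samples["sex"] == "male").to_numpy(float)
        + config.bmi_effect * (samples["bmi"].to_numpy(float) - config.bmi_mean)
    )

    effects = probes["logit_effect"].to_numpy()
    logit = baseline[:, None] + effects[:, None] * severity[None, :] + covar[None, :]
    if config.steatosis_effect:
        logit += config.steatosis_effect * np.sign(effects)[:, None] * steatosis[None, :]

    # shared per-gene per-sample component: promoter CpGs are co-methylated
    gene_codes, gene_index = pd.factorize(probes["gene"])
    u = rng.normal(0.0, config.gene_noise_sd, size=(len(gene_index), n))
    logit += u[gene_codes, :]
    logit += rng.normal(0.0, config.probe_noise_sd, size=(n_probes, n))

    beta = np.clip(expit(logit), BETA_EPS, 1.0 - BETA_EPS)
    beta_df = pd.DataFrame(beta, index=probes["probe_id"].to_numpy(), columns=samples["sample_id"])
    beta_df.index.name = "probe_id"
    return SimulatedCohort(role=cohort_role, beta=beta_df, samples=samples, truth=truth, seed=seed)


def simulate_expression(cohort: SimulatedCohort, config: SimulationConfig, seed: int) -> SimulatedCohort:
    """Attach a gene x sample expression matrix coupled to methylation.

    Expression of a coupled gene follows ``mu + gamma * Mbar + delta *
    fibrosis + noise`` where ``Mbar`` is the gene-level M-value: the logit
    (base 2) of the per-sample mean beta over the gene's affected probes
    (all in-window probes for uncoupled genes) — averaging before the
    transform, matching the analysis order.  Cross-gene couplings listed in
    ``config.neighbor_coupling`` add ``slope * Mbar_source`` to the target
    gene's expression.
    """
    if cohort.beta is None or cohort.beta.empty:
        raise MethlinkError("cohort has no beta matrix; simulate methylation first")
    rng = np.random.default_rng(seed)
    truth = cohort.truth
    samples = cohort.samples
    fibrosis = samples["fibrosis_stage"].fillna(0.0).to_numpy(float)

    mbar: dict[str, np.ndarray] = {}
    for gene, sub in truth.probes.groupby("gene", sort=False):
        chosen = sub.loc[sub["affected"], "probe_id"]
        if chosen.empty:
            chosen = sub.loc[
                (sub["tss_distance"].abs() <= config.probe_window) & ~sub["snp_overlap"],
                "probe_id",
            ]
        mean_beta = cohort.beta.loc[chosen].mean(axis=0).to_numpy()
        mbar[gene] = np.log2(mean_beta / (1.0 - mean_beta))

    rows = {}
    for r in truth.genes.itertuples(index=False):
        x = r.mu + r.gamma * mbar[r.gene] + r.delta * fibrosis
        rows[r.gene] = x
    for (src, target), slope in config.neighbor_coupling.items():
        src, target = src.upper(), target.upper()
        if src not in mbar:
            raise ConfigurationError(f"neighbor_coupling source {src} not simulated")
        if target not in rows:
            raise ConfigurationError(f"neighbor_coupling target {target} not simulated")
        rows[target] = rows[target] + slope * mbar[src]
    expr = pd.DataFrame(rows).T
    expr.columns = samples["sample_id"]
    expr += rng.normal(0.0, config.expression_noise_sd, size=expr.shape)
    expr.index.name = "gene"
    return dataclasses.replace(cohort, expression=expr)


@dataclass
class SimulatedStudy:
    """The three cohorts plus their shared ground truth."""

    discovery: SimulatedCohort
    validation: SimulatedCohort
    ec: SimulatedCohort
    truth: GroundTruth
    config: SimulationConfig
    seed: int

    @property
    def cohorts(self) -> dict[str, SimulatedCohort]:
        return {"discovery": self.discovery, "validation": self.validation, "ec": self.ec}


def simulate_study(config: SimulationConfig, seed: int) -> SimulatedStudy:
    """Simulate the full three-cohort study.

    Probe effects are shared across cohorts (drawn from ``config.truth_seed``
    when set, otherwise derived from ``seed``); sample draws are independent
    per cohort.  The validation cohort is NAFLD-only with fibrosis stages,
    and the EC cohort carries matched expression.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    child = rng.integers(2**31 - 1, size=4)
    truth_seed = config.truth_seed if config.truth_seed is not None else int(child[0])
    truth = draw_ground_truth(config, seed=truth_seed)
    discovery = simulate_methylation_cohort(config, "discovery", seed=int(child[1]), truth=truth)
    validation = simulate_methylation_cohort(config, "validation", seed=int(child[2]), truth=truth)
    ec = simulate_methylation_cohort(config, "ec", seed=int(child[3]), truth=truth)
    ec = simulate_expression(ec, config, seed=int(child[3]) + 1)
    return SimulatedStudy(
        discovery=discovery, validation=validation, ec=ec, truth=truth, config=config, seed=seed
    )


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write cohort matrices, metadata, annotation, truth ledger and manifest.

    Emits the same CSV/TSV formats the pipeline consumes.  Returns the
    manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probes = study.truth.probe_records()
    pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "chrom": [p.chrom for p in probes],
            "pos": [p.pos for p in probes],
            "gene": [p.gene for p in probes],
            "tss_distance": [p.tss_distance for p in probes],
            "snp_overlap": [p.snp_overlap for p in probes],
        }
    ).to_csv(outdir / "probe_annotation.tsv", sep="\t", index=False)
    study.truth.genes[["gene", "chrom", "tss_pos", "strand"]].to_csv(
        outdir / "gene_coordinates.tsv", sep="\t", index=False
    )
    study.truth.probes.to_csv(outdir / "ground_truth_probes.tsv", sep="\t", index=False)
    study.truth.genes.to_csv(outdir / "ground_truth_genes.tsv", sep="\t", index=False)
    for role, cohort in study.cohorts.items():
        cohort.beta.to_csv(outdir / f"beta_{role}.tsv", sep="\t")
        cohort.samples.to_csv(outdir / f"samples_{role}.tsv", sep="\t", index=False)
        if cohort.expression is not None:
            cohort.expression.to_csv(outdir / f"expression_{role}.tsv", sep="\t")
    manifest = {
        "seed": study.seed,
        "truth_seed": study.truth.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(study.config).items()
            if k != "neighbor_coupling"
        },
        "cohort_sizes": {role: len(c.samples) for role, c in study.cohorts.items()},
        "n_probes": int(len(study.truth.probes)),
    }
    (outdir / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
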