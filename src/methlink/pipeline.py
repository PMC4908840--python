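"""End-to-end orchestration and the gene-by-gene summary report.

``run_pipeline`` chains the stages — annotation filtering, discovery scan,
staged validation, cross-cohort consistency, gene-level summarisation,
methylation-expression association and the neighbouring-gene scan — once per
gene cluster, on either files on disk or a seeded synthetic study.  All
intermediate tables are written as TSV, with a JSON manifest recording
configuration, seed and per-stage record counts.

``render_summary`` condenses the results into one row per gene x direction:
the strength category (1-3), the methylation direction (hyper/hypo) and the
association status — *inverse* when the methylation-expression slope is
negative, *parallel* when positive, *none* when no model reached
significance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._version import __version__
from . import annotation as ann
from . import diffmeth, genelevel, methexpr, simulate
from .errors import ConfigurationError, InputDataError, MethlinkError, PipelineStageError

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["gene", "cluster", "direction", "category", "association", "label"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs: inputs, thresholds and options.

    When ``annotation_path`` is unset the pipeline simulates a study from
    ``simulation`` and ``seed``.  Thresholds default to the published
    analysis: discovery FDR 0.05, validation raw 0.05, association 0.05,
    binomial null rate 0.05, TSS window 1500 bp.
    """

    annotation_path: str | None = None
    gene_coordinates_path: str | None = None
    beta_paths: dict = field(default_factory=dict)  # role -> path
    sample_paths: dict = field(default_factory=dict)
    expression_path: str | None = None
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    clusters: tuple[str, ...] = ("bile_acid", "drug_metabolism")
    include_cluster_extras: bool = False
    alpha_discovery: float = 0.05
    alpha_validation: float = 0.05
    alpha_association: float = 0.05
    binomial_p0: float = 0.05
    tss_window: int = ann.TSS_WINDOW
    covariates: tuple[str, ...] = diffmeth.DEFAULT_COVARIATES
    validation_stage_variable: str = "fibrosis"
    orientation: str = "m"
    estimator: str = "bisquare"
    neighbor_k: int = 5
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_discovery", "alpha_validation", "alpha_association", "binomial_p0"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if self.tss_window <= 0:
            raise ConfigurationError("tss_window must be positive")
        known = {"bile_acid", "drug_metabolism"}
        if not set(self.clusters) <= known:
            raise ConfigurationError(f"unknown cluster(s): {sorted(set(self.clusters) - known)}")


@dataclass
class ResultBundle:
    """All tables produced by one pipeline run plus the run manifest."""

    discovery: pd.DataFrame
    validation_fibrosis: pd.DataFrame
    validation_steatosis: pd.DataFrame
    validated_sites: pd.DataFrame
    gene_summaries: pd.DataFrame
    profiles: pd.DataFrame
    associations: pd.DataFrame
    neighbor_associations: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "discovery": self.discovery,
            "validation_fibrosis": self.validation_fibrosis,
            "validation_steatosis": self.validation_steatosis,
            "validated_sites": self.validated_sites,
            "gene_summaries": self.gene_summaries,
            "profiles": self.profiles,
            "associations": self.associations,
            "neighbor_associations": self.neighbor_associations,
            "summary": self.summary,
        }


def _load_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"matrix file not found: {path}")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise InputDataError(f"matrix file has no rows: {path}")
    return df


def _load_samples(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"sample table not found: {path}")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    return pd.read_csv(path, sep=sep)


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MethlinkError) and not isinstance(
                exc, PipelineStageError
            ):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def _gather_inputs(config: PipelineConfig):
    if config.annotation_path is None:
        study = simulate.simulate_study(config.simulation, seed=config.seed)
        probes = study.truth.probe_records()
        gene_records = study.truth.gene_records()
        data = {
            role: (c.beta, c.samples) for role, c in study.cohorts.items()
        }
        expression = study.ec.expression
        return probes, gene_records, data, expression
    probes = ann.load_probe_annotation(config.annotation_path)
    gene_records = (
        ann.load_gene_coordinates(config.gene_coordinates_path)
        if config.gene_coordinates_path
        else []
    )
    data = {}
    for role in ("discovery", "validation", "ec"):
        if role not in config.beta_paths or role not in config.sample_paths:
            raise InputDataError(f"missing beta or sample path for cohort '{role}'")
        data[role] = (_load_matrix(config.beta_paths[role]), _load_samples(config.sample_paths[role]))
    if config.expression_path is None:
        raise InputDataError("expression_path is required when running from files")
    expression = _load_matrix(config.expression_path)
    return probes, gene_records, data, expression


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full per-cluster analysis; deterministic given config and seed."""
    config.validate()
    with _stage("inputs"):
        probes, gene_records, data, expression = _gather_inputs(config)
    beta_disc, samples_disc = data["discovery"]
    beta_val, samples_val = data["validation"]
    beta_ec, samples_ec = data["ec"]

    clusters = {
        c.name: c
        for c in ann.builtin_gene_clusters(include_extras=config.include_cluster_extras)
    }
    parts: dict[str, list[pd.DataFrame]] = {key: [] for key in (
        "discovery", "validation_fibrosis", "validation_steatosis", "validated_sites",
        "gene_summaries", "profiles", "associations", "neighbor_associations",
    )}
    counts: dict[str, dict[str, int]] = {}

    for cluster_name in config.clusters:
        cluster = clusters[cluster_name]
        with _stage(f"annotation[{cluster_name}]"):
            probe_sets = {
                gene: ids
                for gene in cluster.members(include_extras=config.include_cluster_extras)
                if (ids := ann.select_tss1500_probes(probes, gene, window=config.tss_window))
            }
        if not probe_sets:
            logger.warning("cluster %s has no annotated TSS probes; skipped", cluster_name)
            continue
        with _stage(f"discovery[{cluster_name}]"):
            disc = diffmeth.discovery_scan(
                beta_disc, samples_disc, probe_sets,
                covariates=config.covariates, alpha=config.alpha_discovery,
            )
        with _stage(f"validation[{cluster_name}]"):
            val_fib = diffmeth.validation_scan(
                beta_val, samples_val, probe_sets, stage_variable="fibrosis",
                covariates=config.covariates, alpha=config.alpha_validation,
            )
            val_ste = diffmeth.validation_scan(
                beta_val, samples_val, probe_sets, stage_variable="steatosis",
                covariates=config.covariates, alpha=config.alpha_validation,
            )
        with _stage(f"consistency[{cluster_name}]"):
            val_for_consistency = (
                val_fib if config.validation_stage_variable == "fibrosis" else val_ste
            )
            validated = diffmeth.consistent_validated_sites(
                disc, val_for_consistency,
                alpha_discovery=config.alpha_discovery,
                alpha_validation=config.alpha_validation,
            )
        with _stage(f"genelevel[{cluster_name}]"):
            summaries = genelevel.summarize_genes(
                validated, probe_sets, cluster=cluster_name, p0=config.binomial_p0
            )
            profiles = genelevel.gene_methylation_profiles(beta_ec, validated)
            profiles["cluster"] = cluster_name
        with _stage(f"association[{cluster_name}]"):
            assoc_frames, neighbor_frames = [], []
            for (gene, direction), _ in genelevel.split_by_direction(validated).items():
                prof = profiles[(profiles["gene"] == gene) & (profiles["direction"] == direction)]
                if prof.empty:
                    continue
                assoc_frames.append(
                    methexpr.associate_gene(
                        gene, direction, prof, expression, samples_ec,
                        orientation=config.orientation, alpha=config.alpha_association,
                    )
                )
                if gene_records:
                    neighbor_frames.append(
                        methexpr.neighbor_expression_scan(
                            gene, direction, prof, expression, gene_records, samples_ec,
                            k=config.neighbor_k, orientation=config.orientation,
                        )
                    )
            assoc = (
                pd.concat(assoc_frames, ignore_index=True)
                if assoc_frames
                else pd.DataFrame(columns=methexpr.ASSOCIATION_COLUMNS)
            )
            neigh = (
                pd.concat(neighbor_frames, ignore_index=True)
                if neighbor_frames
                else pd.DataFrame(columns=methexpr.ASSOCIATION_COLUMNS)
            )
            assoc["cluster"] = cluster_name
            neigh["cluster"] = cluster_name

        for key, frame in (
            ("discovery", disc.assign(cluster=cluster_name)),
            ("validation_fibrosis", val_fib.assign(cluster=cluster_name)),
            ("validation_steatosis", val_ste.assign(cluster=cluster_name)),
            ("validated_sites", validated.assign(cluster=cluster_name)),
            ("gene_summaries", summaries),
            ("profiles", profiles),
            ("associations", assoc),
            ("neighbor_associations", neigh),
        ):
            parts[key].append(frame)
        counts[cluster_name] = {
            "probes_scanned": int(disc["probe_id"].nunique()),
            "validated_sites": int(len(validated)),
            "gene_direction_summaries": int(len(summaries)),
            "association_rows": int(len(assoc)),
            "neighbor_rows": int(len(neigh)),
        }

    frames = {k: (pd.concat(v, ignore_index=True) if v else pd.DataFrame()) for k, v in parts.items()}
    summary = render_summary_tables(
        frames["gene_summaries"], frames["associations"], alpha=config.alpha_association
    )
    manifest = {
        "software": {"name": "methlink", "version": __version__},
        "seed": config.seed,
        "config": _jsonable_config(config),
        "per_cluster_counts": counts,
        "table_rows": {k: int(len(v)) for k, v in frames.items()} | {"summary": int(len(summary))},
    }
    bundle = ResultBundle(
        discovery=frames["discovery"],
        validation_fibrosis=frames["validation_fibrosis"],
        validation_steatosis=frames["validation_steatosis"],
        validated_sites=frames["validated_sites"],
        gene_summaries=frames["gene_summaries"],
        profiles=frames["profiles"],
        associations=frames["associations"],
        neighbor_associations=frames["neighbor_associations"],
        summary=summary,
        manifest=manifest,
    )
    if config.outdir:
        write_bundle(bundle, config.outdir)
    return bundle


def _jsonable_config(config: PipelineConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["simulation"].pop("neighbor_coupling", None)

    def conv(v):
        if isinstance(v, tuple):
            return list(v)
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        return v

    return {k: conv(v) for k, v in raw.items()}


def render_summary_tables(
    gene_summaries: pd.DataFrame, associations: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """One row per gene x direction combining category and association status.

    The association status is read from the adjusted robust model of the
    gene's own expression: *inverse* for a significant negative
    methylation-expression slope, *parallel* for a significant positive one,
    *none* otherwise.
    """
    if gene_summaries.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    rows = []
    for r in gene_summaries.itertuples(index=False):
        status = "none"
        if not associations.empty:
            own = associations[
                (associations["gene"] == r.gene)
                & (associations["direction"] == r.direction)
                & (associations["model"] == "robust_adjusted")
                & (associations["neighbor_of"].isna())
            ]
            if "cluster" in associations.columns:
                own = own[own["cluster"] == r.cluster]
            if len(own) and float(own.iloc[0]["p"]) < alpha:
                status = "inverse" if float(own.iloc[0]["coefficient"]) < 0 else "parallel"
        rows.append(
            {
                "gene": r.gene,
                "cluster": r.cluster,
                "direction": r.direction,
                "category": int(r.category),
                "association": status,
                "label": f"{r.direction} / {status}",
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS).sort_values(
        ["cluster", "gene", "direction"], ignore_index=True
    )


def render_summary(bundle: ResultBundle, alpha: float = 0.05) -> pd.DataFrame:
    """Summary table for a completed :class:`ResultBundle`."""
    return render_summary_tables(bundle.gene_summaries, bundle.associations, alpha=alpha)


def write_bundle(bundle: ResultBundle, outdir) -> None:
    """Write every result table as TSV plus the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in bundle.tables().items():
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    (outdir / "run_manifest.json").write_text(json.dumps(bundle.manifest, indent=2))


def summary_from_tables(outdir, alpha: float = 0.05) -> pd.DataFrame:
    """Rebuild the final summary from previously written intermediate tables.

    Re-running this on a written bundle reproduces ``summary.tsv`` exactly.
    """
    outdir = Path(outdir)
    gene_summaries = pd.read_csv(outdir / "gene_summaries.tsv", sep="\t")
    associations = pd.read_csv(outdir / "associations.tsv", sep="\t")
    if "neighbor_of" not in associations.columns:
        associations["neighbor_of"] = pd.NA
    return render_summary_tables(gene_summaries, associations, alpha=alpha)
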