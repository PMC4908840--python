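"""Methylation-expression association in the matched (EC) cohort.

Each gene's promoter methylation (per-sample mean M-value over its validated
hyper- or hypomethylated sites) is related to transcription intra-
individually in four ways:

* a robust linear model adjusting for fibrosis stage;
* the same model with a fibrosis x expression interaction term (the reported
  coefficient and p refer to the expression main effect; the interaction
  term is emitted as auxiliary output);
* uncorrected Pearson correlations separately in the NAFLD (SS & NASH) and
  control subgroups.

The robust fits use redescending M-estimation (Tukey bisquare, tuning 4.685,
~95 % Gaussian efficiency) solved by iteratively reweighted least squares
from a monotone Huber start, so isolated gross outliers cannot dominate a
slope.  The default orientation regresses the M-value on expression plus
fibrosis; the reversed orientation (expression on methylation) is available
and is the natural scale for recovering a generative methylation-to-
expression coupling slope.

A final scan re-runs the adjusted robust model against the expression of the
k nearest genes up- and downstream of each target, flagging associations
that spill over onto neighbouring transcription units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import annotation as ann
from .errors import (
    CorrelationError,
    FitConvergenceError,
    InsufficientDataError,
    InsufficientVariationError,
)

logger = logging.getLogger(__name__)

TUKEY_TUNING = 4.685
ASSOCIATION_COLUMNS = [
    "gene",
    "direction",
    "model",
    "coefficient",
    "p",
    "n_used",
    "neighbor_of",
    "interaction_coefficient",
    "interaction_p",
]


@dataclass(frozen=True)
class RobustFit:
    """Result of a robust (or OLS) linear fit."""

    coefficient: float  # slope of the primary predictor
    p: float
    n_used: int
    interaction_coefficient: float | None = None
    interaction_p: float | None = None
    iterations: int = 0


def robust_regression(
    m,
    expr,
    fibrosis=None,
    interaction: bool = False,
    estimator: str = "bisquare",
    tuning: float = TUKEY_TUNING,
    maxiter: int = 300,
    tol: float = 1e-6,
    response: str = "m",
) -> RobustFit:
    """Robust fit relating per-sample methylation M-values to expression.

    With ``response="m"`` (default) the model is
    ``M ~ expr + fibrosis (+ expr:fibrosis)``; with ``response="expr"`` the
    orientation is reversed (``expr ~ M + fibrosis (+ M:fibrosis)``).  The
    returned coefficient and two-sided p-value (robust standard errors,
    normal reference) belong to the non-response methylation/expression term
    in either orientation.

    ``estimator`` is ``"bisquare"`` (Tukey redescending weights, Huber
    start), ``"huber"`` or ``"ols"`` (constant weights; the robust path
    reduces to this solution on clean data).
    """
    m = np.asarray(m, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if m.shape != expr.shape:
        raise InsufficientDataError("methylation and expression vectors differ in length")
    keep = np.isfinite(m) & np.isfinite(expr)
    if fibrosis is not None:
        fibrosis = np.asarray(fibrosis, dtype=float)
        keep &= np.isfinite(fibrosis)
    m, expr = m[keep], expr[keep]
    fib = fibrosis[keep] if fibrosis is not None else None

    if response == "m":
        y, x = m, expr
    elif response == "expr":
        y, x = expr, m
    else:
        raise InsufficientDataError(f"unknown response orientation: {response!r}")
    if np.ptp(x) == 0:
        raise InsufficientVariationError("predictor is constant; cannot estimate a slope")

    cols = {"slope": x}
    if fib is not None:
        cols["fibrosis"] = fib
        if interaction:
            cols["slope:fibrosis"] = x * fib
    X = pd.DataFrame(cols)
    n, k = X.shape
    if n < k + 1 + 3:
        raise InsufficientDataError(f"{n} samples are too few for {k} model terms")
    X = sm.add_constant(X, has_constant="add")

    if estimator == "ols":
        res = sm.OLS(y, X).fit()
        iterations = 0
    else:
        # converge on parameter change: the deviance of a redescending norm can
        # creep long after the slope has stabilised
        huber = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit(
            maxiter=maxiter, tol=tol, conv="coefs"
        )
        if estimator == "huber":
            res = huber
        elif estimator == "bisquare":
            res = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=tuning)).fit(
                maxiter=maxiter, start_params=huber.params, tol=tol, conv="coefs"
            )
        else:
            raise InsufficientDataError(f"unknown estimator: {estimator!r}")
        iterations = len(res.fit_history.get("params", []))
        if not np.all(np.isfinite(res.params)):
            raise FitConvergenceError(
                f"robust fit diverged after {iterations} iteration(s)",
                iterations=iterations,
                maxiter=maxiter,
            )
        if iterations >= maxiter:
            raise FitConvergenceError(
                f"robust fit did not converge within {maxiter} iterations",
                iterations=iterations,
                maxiter=maxiter,
            )

    return RobustFit(
        coefficient=float(res.params["slope"]),
        p=float(res.pvalues["slope"]),
        n_used=n,
        interaction_coefficient=(
            float(res.params["slope:fibrosis"]) if interaction and fib is not None else None
        ),
        interaction_p=(
            float(res.pvalues["slope:fibrosis"]) if interaction and fib is not None else None
        ),
        iterations=iterations,
    )


def pearson_subgroup(m, expr, mask=None) -> tuple[float, float]:
    """Pearson correlation of methylation and expression within a subgroup.

    Returns ``(r, p)`` with the usual two-sided t-approximation (df = n-2).
    """
    m = np.asarray(m, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        m, expr = m[mask], expr[mask]
    keep = np.isfinite(m) & np.isfinite(expr)
    m, expr = m[keep], expr[keep]
    if len(m) < 3:
        raise CorrelationError(f"subgroup of size {len(m)} is too small to correlate")
    if np.ptp(m) == 0 or np.ptp(expr) == 0:
        raise CorrelationError("zero variance in methylation or expression vector")
    r, p = stats.pearsonr(m, expr)
    return float(r), float(p)


def collapse_transcripts(expression: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple transcript rows per gene symbol by their mean."""
    if expression.index.has_duplicates:
        counts = expression.index.value_counts()
        multi = counts[counts > 1]
        logger.info(
            "collapsing %d gene(s) with multiple transcript rows (max %d rows)",
            len(multi),
            int(multi.max()),
        )
        return expression.groupby(level=0, sort=False).mean()
    return expression


def _aligned_vectors(
    profile: pd.DataFrame, expression: pd.DataFrame, samples: pd.DataFrame, expr_gene: str
):
    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    prof = profile.set_index("sample_id")
    shared = [s for s in prof.index if s in expression.columns and s in meta.index]
    m = prof.loc[shared, "m_value"].to_numpy(float)
    x = expression.loc[expr_gene, shared].to_numpy(float)
    meta = meta.loc[shared]
    fib = np.array([ann.map_fibrosis_stage(v) if pd.notna(v) else np.nan for v in meta["fibrosis_stage"]], float)
    is_case = (meta["diagnosis"].astype(str).str.lower() != "control").to_numpy()
    return m, x, fib, is_case


def associate_gene(
    gene: str,
    direction: str,
    profile: pd.DataFrame,
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    orientation: str = "m",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Four association rows for one gene x direction in the matched cohort.

    ``profile`` must carry ``sample_id`` and ``m_value`` columns for this
    gene/direction.  Emits robust adjusted, robust interaction, and Pearson
    rows for the NAFLD and control subgroups.  A gene absent from the
    expression matrix is skipped with a log entry (empty result, not an
    error).
    """
    expression = collapse_transcripts(expression)
    if gene not in expression.index:
        logger.warning("gene %s absent from expression matrix; skipped", gene)
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    m, x, fib, is_case = _aligned_vectors(profile, expression, samples, gene)

    rows = []
    adjusted = robust_regression(m, x, fib, interaction=False, response=orientation)
    rows.append(("robust_adjusted", adjusted))
    inter = robust_regression(m, x, fib, interaction=True, response=orientation)
    rows.append(("robust_interaction", inter))
    for model, mask in (("pearson_cases", is_case), ("pearson_controls", ~is_case)):
        try:
            r, p = pearson_subgroup(m, x, mask)
            rows.append((model, RobustFit(coefficient=r, p=p, n_used=int(mask.sum()))))
        except CorrelationError as exc:
            logger.warning("%s for gene %s skipped: %s", model, gene, exc)

    return pd.DataFrame(
        [
            {
                "gene": gene,
                "direction": direction,
                "model": model,
                "coefficient": fit.coefficient,
                "p": fit.p,
                "n_used": fit.n_used,
                "neighbor_of": None,
                "interaction_coefficient": fit.interaction_coefficient,
                "interaction_p": fit.interaction_p,
            }
            for model, fit in rows
        ],
        columns=ASSOCIATION_COLUMNS,
    )


def neighbor_expression_scan(
    gene: str,
    direction: str,
    profile: pd.DataFrame,
    expression: pd.DataFrame,
    gene_records: Sequence[ann.GeneRecord],
    samples: pd.DataFrame,
    k: int = 5,
    orientation: str = "m",
) -> pd.DataFrame:
    """Adjusted robust model of one gene's methylation against each
    neighbouring gene's expression.

    Rows carry ``gene`` = the neighbouring (expression) gene and
    ``neighbor_of`` = the methylation source gene.  Neighbours without
    expression data are skipped with a log entry.
    """
    if k <= 0:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    expression = collapse_transcripts(expression)
    rows = []
    for neighbor in ann.neighbor_genes(gene_records, gene, k=k):
        if neighbor not in expression.index:
            logger.info("neighbor %s of %s lacks expression data; skipped", neighbor, gene)
            continue
        m, x, fib, _ = _aligned_vectors(profile, expression, samples, neighbor)
        fit = robust_regression(m, x, fib, interaction=False, response=orientation)
        rows.append(
            {
                "gene": neighbor,
                "direction": direction,
                "model": "robust_adjusted",
                "coefficient": fit.coefficient,
                "p": fit.p,
                "n_used": fit.n_used,
                "neighbor_of": gene,
                "interaction_coefficient": None,
                "interaction_p": None,
            }
        )
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
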