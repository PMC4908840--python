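"""Collapse validated CpG sites to per-gene statistics.

A gene's promoter signal is summarised by: the count of its TSS1500 probes,
the count validated as hyper- or hypomethylated, the rounded percent
significant, an upper-tail binomial overrepresentation p-value (is the
significant fraction larger than the 5 % expected if every site were
independently significant at the nominal rate?), and a three-level category
describing the strength of the methylation shift:

* category 1 — at least 7 TSS1500 sites and >= 50 % of them changed;
* category 2 — 3-6 sites with >= 50 % changed, or >= 7 sites with 30-50 %
  changed (the 50 % boundary belongs to the higher category, the 30 %
  boundary to category 2);
* category 3 — everything else (fewer than 3 sites, or < 30 % changed, or
  3-6 sites below 50 %).

Per-sample methylation of a gene is the arithmetic mean beta over its
validated sites of one direction, transformed to the M-value scale
``M = log2(beta / (1 - beta))`` for correlation with expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import AggregationError, InputDataError

M_CLAMP_EPS = 1e-6


def binomial_overrepresentation(n_sig: int, n_total: int, p0: float = 0.05) -> float:
    """Upper-tail probability P(X >= n_sig) for X ~ Binomial(n_total, p0).

    Computed through the regularised incomplete beta function, numerically
    stable far into the tail (~1e-20).
    """
    n_sig, n_total = int(n_sig), int(n_total)
    if n_total < 1:
        raise InputDataError("n_total must be >= 1")
    if not 0 <= n_sig <= n_total:
        raise InputDataError(f"n_sig={n_sig} outside [0, n_total={n_total}]")
    if not 0 < p0 < 1:
        raise InputDataError("p0 must lie in (0, 1)")
    if n_sig == 0:
        return 1.0
    return float(binom.sf(n_sig - 1, n_total, p0))


def percent_significant(n_sig: int, n_total: int) -> int:
    """Integer percent of significant sites, rounded half away from zero."""
    n_sig, n_total = int(n_sig), int(n_total)
    if n_total < 1:
        raise InputDataError("n_total must be >= 1")
    if not 0 <= n_sig <= n_total:
        raise InputDataError(f"n_sig={n_sig} outside [0, n_total={n_total}]")
    return (200 * n_sig + n_total) // (2 * n_total)


def categorize_gene(n_total: int, n_sig: int) -> int:
    """Assign the three-level strength category from integer site counts."""
    n_total, n_sig = int(n_total), int(n_sig)
    if n_total < 0 or not 0 <= n_sig <= max(n_total, 0):
        raise InputDataError(f"invalid counts: n_total={n_total}, n_sig={n_sig}")
    if n_total == 0:
        return 3
    half = 2 * n_sig >= n_total  # fraction >= 0.5
    third = 10 * n_sig >= 3 * n_total  # fraction >= 0.3
    if n_total >= 7:
        if half:
            return 1
        if third:
            return 2
        return 3
    if 3 <= n_total <= 6 and half:
        return 2
    return 3


def split_by_direction(validated: pd.DataFrame) -> dict[tuple[str, str], tuple[str, ...]]:
    """Partition validated sites into per-gene hyper and hypo probe sets.

    ``validated`` needs columns ``gene``, ``probe_id`` and ``direction``; a
    gene may appear under both directions.  Probe ids are returned sorted for
    determinism.
    """
    required = {"gene", "probe_id", "direction"}
    missing = required - set(validated.columns)
    if missing:
        raise InputDataError(f"validated sites table missing column(s): {sorted(missing)}")
    bad = set(validated["direction"]) - {"hyper", "hypo"}
    if bad:
        raise InputDataError(f"unknown direction label(s): {sorted(bad)}")
    out: dict[tuple[str, str], tuple[str, ...]] = {}
    for (gene, direction), sub in validated.groupby(["gene", "direction"], sort=True):
        out[(gene, direction)] = tuple(sorted(sub["probe_id"].unique()))
    return out


def average_beta(beta: pd.DataFrame, sites) -> pd.Series:
    """Per-sample arithmetic mean beta over a probe set."""
    sites = list(sites)
    if not sites:
        raise AggregationError("cannot average over an empty site set")
    missing = [s for s in sites if s not in beta.index]
    if missing:
        raise AggregationError(f"site(s) absent from beta matrix: {missing[:5]}")
    return beta.loc[sites].mean(axis=0)


def beta_to_m(beta_mean, eps: float = M_CLAMP_EPS):
    """M-value transform ``log2(beta / (1 - beta))``.

    Accepts scalars or arrays in [0, 1]; values at the boundaries are clamped
    to ``[eps, 1 - eps]`` before the logit.  Strictly increasing in beta and
    antisymmetric about 0.5.
    """
    arr = np.asarray(beta_mean, dtype=float)
    if np.any(np.isnan(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise InputDataError("beta values must lie in [0, 1]")
    clamped = np.clip(arr, eps, 1.0 - eps)
    m = np.log2(clamped / (1.0 - clamped))
    if np.isscalar(beta_mean):
        return float(m)
    if isinstance(beta_mean, pd.Series):
        return pd.Series(m, index=beta_mean.index)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (away from the clamp boundaries)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.power(2.0, -arr))
    return float(b) if np.isscalar(m) else b


def summarize_genes(
    validated: pd.DataFrame,
    probe_sets,
    cluster: str | None = None,
    p0: float = 0.05,
) -> pd.DataFrame:
    """Per gene x direction summary of validated sites.

    ``n_total`` counts all TSS1500 probes of the gene (``probe_sets[gene]``)
    regardless of direction; ``n_sig`` counts validated sites of the row's
    direction; the strength category is computed from the combined validated
    count across directions (the categorisation is direction-agnostic).
    """
    by_dir = split_by_direction(validated) if len(validated) else {}
    combined: dict[str, int] = {}
    for (gene, _), probes in by_dir.items():
        combined[gene] = combined.get(gene, 0) + len(probes)
    rows = []
    for (gene, direction), probes in by_dir.items():
        n_total = len(probe_sets[gene])
        n_sig = len(probes)
        rows.append(
            {
                "gene": gene,
                "direction": direction,
                "n_total": n_total,
                "n_sig": n_sig,
                "pct_sig": percent_significant(n_sig, n_total),
                "p_binomial": binomial_overrepresentation(n_sig, n_total, p0=p0),
                "category": categorize_gene(n_total, combined[gene]),
                "cluster": cluster,
            }
        )
    columns = ["gene", "direction", "n_total", "n_sig", "pct_sig", "p_binomial", "category", "cluster"]
    return pd.DataFrame(rows, columns=columns).sort_values(["gene", "direction"], ignore_index=True)


def gene_methylation_profiles(
    beta: pd.DataFrame, validated: pd.DataFrame
) -> pd.DataFrame:
    """Tidy per-sample methylation profiles for each gene x direction.

    Averages beta over the validated sites of one direction, then applies the
    M-value transform to the mean (averaging precedes the transform).
    Returns columns ``gene, direction, sample_id, mean_beta, m_value``.
    """
    frames = []
    for (gene, direction), probes in split_by_direction(validated).items():
        present = [p for p in probes if p in beta.index]
        if not present:
            continue
        mean_b = average_beta(beta, present)
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "direction": direction,
                    "sample_id": mean_b.index,
                    "mean_beta": mean_b.to_numpy(),
                    "m_value": beta_to_m(mean_b).to_numpy(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["gene", "direction", "sample_id", "mean_beta", "m_value"])
    return pd.concat(frames, ignore_index=True)
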