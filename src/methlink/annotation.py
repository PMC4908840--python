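"""Probe and gene annotation for the targeted promoter-methylation analysis.

The analysis is restricted to CpG probes lying within 1500 bp up- or
downstream of a gene's transcription start site (the TSS1500 interval, the
boundary being inclusive per the Illumina naming convention) and free of
known SNP overlap.  Two curated gene clusters are shipped with the package:
43 genes covering bile-acid synthesis, transport, conjugation and signalling,
and 40 genes covering drug-metabolising phase I/II enzymes, transporters and
their transcriptional regulators.  A probe annotated to several genes
contributes independently to each gene's probe set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from numbers import Real
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, GeneLookupError, InputDataError, StagingError

logger = logging.getLogger(__name__)

TSS_WINDOW = 1500

#: canonical column names for probe annotation tables
DEFAULT_DIALECT = {
    "probe_id": "probe_id",
    "chrom": "chrom",
    "pos": "pos",
    "gene": "gene",
    "tss_distance": "tss_distance",
    "snp_overlap": "snp_overlap",
}

_TRUTHY = {"true", "t", "yes", "y", "1"}
_FALSY = {"false", "f", "no", "n", "0", ""}


@dataclass(frozen=True)
class ProbeRecord:
    """One probe-gene annotation pair.

    ``tss_distance`` is the signed distance in bp from the probe to the
    nearest TSS of ``gene`` (negative = upstream); ``pos`` is 1-based.
    """

    probe_id: str
    chrom: str
    pos: int
    gene: str
    tss_distance: int
    snp_overlap: bool


@dataclass(frozen=True)
class GeneRecord:
    """TSS coordinate of a gene (1-based), used for neighbour resolution."""

    gene: str
    chrom: str
    tss_pos: int
    strand: str = "+"


@dataclass(frozen=True)
class GeneCluster:
    """A named, ordered gene set with per-gene functional categories.

    ``extras`` lists optional members that are shipped for completeness but
    are not counted in the cluster's canonical size (currently NAT2 in the
    drug-metabolism cluster).
    """

    name: str
    genes: tuple[str, ...]
    categories: Mapping[str, str] = field(default_factory=dict)
    aliases: Mapping[str, str] = field(default_factory=dict)
    extras: tuple[str, ...] = ()

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes or gene.upper() in self.extras

    def __len__(self) -> int:
        return len(self.genes)

    def members(self, include_extras: bool = False) -> tuple[str, ...]:
        return self.genes + self.extras if include_extras else self.genes


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"annotation file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".bed"} else None
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, _csv.Error) as exc:
        raise InputDataError(f"annotation file is empty or undelimited: {path}") from exc
    if df.empty:
        raise InputDataError(f"annotation file has no rows: {path}")
    return df


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY or text == "nan":
        return False
    raise ValueError(f"unparseable boolean flag: {value!r}")


def load_probe_annotation(path, dialect: Mapping[str, str] | None = None) -> list[ProbeRecord]:
    """Read a probe annotation table into one :class:`ProbeRecord` per probe-gene pair.

    Parameters
    ----------
    path:
        CSV or TSV file with one row per probe-gene pair.
    dialect:
        Optional mapping from canonical field names (``probe_id``, ``chrom``,
        ``pos``, ``gene``, ``tss_distance``, ``snp_overlap``) to the column
        names actually present in the file.

    Rows whose position or TSS distance cannot be parsed as integers are
    dropped with a logged count.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect keys: {sorted(unknown)}")
        cols.update(dialect)
    df = _read_table(path)
    missing = [name for name in cols.values() if name not in df.columns]
    if missing:
        raise ConfigurationError(
            f"annotation file {path} is missing required column(s): {missing}"
        )

    records: list[ProbeRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        data = dict(zip(df.columns, row))
        try:
            records.append(
                ProbeRecord(
                    probe_id=str(data[cols["probe_id"]]).strip(),
                    chrom=str(data[cols["chrom"]]).strip(),
                    pos=int(float(data[cols["pos"]])),
                    gene=str(data[cols["gene"]]).strip().upper(),
                    tss_distance=int(float(data[cols["tss_distance"]])),
                    snp_overlap=_parse_bool(data[cols["snp_overlap"]]),
                )
            )
        except (ValueError, TypeError):
            n_rejected += 1
    if n_rejected:
        logger.warning("rejected %d unparseable annotation row(s) in %s", n_rejected, path)
    return records


def select_tss1500_probes(
    probes: Iterable[ProbeRecord], gene: str, window: int = TSS_WINDOW
) -> set[str]:
    """Probe ids for ``gene`` within the TSS window and free of SNP overlap.

    The boundary is inclusive (``|tss_distance| <= window``).  Returns an
    empty set for genes absent from the annotation.
    """
    gene = gene.upper()
    return {
        p.probe_id
        for p in probes
        if p.gene == gene and abs(p.tss_distance) <= window and not p.snp_overlap
    }


def builtin_gene_clusters(include_extras: bool = False) -> tuple[GeneCluster, GeneCluster]:
    """The two curated gene clusters shipped with the package.

    Returns ``(bile_acid, drug_metabolism)`` with 43 and 40 canonical members
    respectively.  ``include_extras=True`` folds flagged optional members
    (NAT2) into the returned gene tuples.
    """
    with resources.files("methlink.data").joinpath("gene_clusters.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"extra": int}).fillna({"alias": ""})
    clusters = []
    for name in ("bile_acid", "drug_metabolism"):
        sub = df[df["cluster"] == name]
        core = tuple(sub.loc[sub["extra"] == 0, "gene"])
        extras = tuple(sub.loc[sub["extra"] == 1, "gene"])
        genes = core + extras if include_extras else core
        clusters.append(
            GeneCluster(
                name=name,
                genes=genes,
                categories=dict(zip(sub["gene"], sub["functional_category"])),
                aliases={g: a for g, a in zip(sub["gene"], sub["alias"]) if a},
                extras=() if include_extras else extras,
            )
        )
    return tuple(clusters)


def load_gene_coordinates(path) -> list[GeneRecord]:
    """Read gene TSS coordinates from a BED-like TSV (gene, chrom, tss_pos, strand)."""
    df = _read_table(path)
    required = {"gene", "chrom", "tss_pos", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"gene coordinate file missing column(s): {sorted(missing)}")
    return [
        GeneRecord(
            gene=str(r.gene).strip().upper(),
            chrom=str(r.chrom).strip(),
            tss_pos=int(float(r.tss_pos)),
            strand=str(r.strand).strip(),
        )
        for r in df.itertuples(index=False)
    ]


def neighbor_genes(records: Sequence[GeneRecord], gene: str, k: int = 5) -> list[str]:
    """Up to ``k`` genes on either side of ``gene`` on the same chromosome.

    Neighbours are ordered by absolute TSS distance (nearest first, ties by
    symbol); fewer are returned near a chromosome end.  Positional, not
    strand-aware.
    """
    gene = gene.upper()
    center = next((r for r in records if r.gene == gene), None)
    if center is None:
        raise GeneLookupError(f"no coordinate record for gene {gene}")
    if k <= 0:
        return []
    same_chrom = [r for r in records if r.chrom == center.chrom and r.gene != gene]
    upstream = sorted(
        (r for r in same_chrom if r.tss_pos < center.tss_pos),
        key=lambda r: (center.tss_pos - r.tss_pos, r.gene),
    )[:k]
    downstream = sorted(
        (r for r in same_chrom if r.tss_pos >= center.tss_pos),
        key=lambda r: (r.tss_pos - center.tss_pos, r.gene),
    )[:k]
    merged = sorted(
        upstream + downstream, key=lambda r: (abs(r.tss_pos - center.tss_pos), r.gene)
    )
    return [r.gene for r in merged]


def _normalize_label(value: str) -> str:
    return (
        str(value)
        .strip()
        .lower()
        .replace("–", "-")
        .replace("—", "-")
        .replace(" ", "")
        .replace("%", "")
    )


_FIBROSIS_LABELS = {"insignificant": 0, "mild": 1, "advanced": 2}
_STEATOSIS_LABELS = {"<5": 0, "5-33": 1, "34-66": 2, ">66": 3}


def map_fibrosis_stage(value) -> int:
    """Map a fibrosis label or numeric code to the ordinal scale {0, 1, 2}.

    Numeric 0 and 0.5 both map to 0 ("insignificant"), 1 to "mild" and 2 to
    "advanced", matching the harmonisation between the staged cohorts.
    """
    if isinstance(value, Real) and not isinstance(value, bool):
        v = float(value)
        if v in (0.0, 0.5):
            return 0
        if v in (1.0, 2.0):
            return int(v)
        raise StagingError(f"unknown fibrosis stage code: {value!r}")
    label = _normalize_label(value)
    try:
        return _FIBROSIS_LABELS[label]
    except KeyError:
        try:
            return map_fibrosis_stage(float(label))
        except (ValueError, StagingError):
            raise StagingError(f"unknown fibrosis stage label: {value!r}") from None


def map_steatosis_grade(value) -> int:
    """Map a steatosis label or numeric code to the ordinal scale {0, 1, 2, 3}.

    Percent-range labels (``<5 %``, ``5-33 %``, ``34-66 %``, ``>66 %``) map to
    0..3; numeric codes 0..3 pass through.
    """
    if isinstance(value, Real) and not isinstance(value, bool):
        v = float(value)
        if v in (0.0, 1.0, 2.0, 3.0):
            return int(v)
        raise StagingError(f"unknown steatosis grade code: {value!r}")
    label = _normalize_label(value)
    if label in _STEATOSIS_LABELS:
        return _STEATOSIS_LABELS[label]
    try:
        return map_steatosis_grade(float(label))
    except (ValueError, StagingError):
        raise StagingError(f"unknown steatosis grade label: {value!r}") from None
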