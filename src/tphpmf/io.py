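"""Readers and writers for the TSV/CSV formats the pipeline exchanges.

Count matrices: first column sample id, header row taxon ids (or the
transpose with ``orientation="taxa-rows"``).  Distance matrices: square,
header plus first column carrying taxon ids.  Covariates: sample id column
matching the count matrix.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import PhyloHierarchy, TaxonDistanceMatrix
from .preprocessing import CountMatrix, LogMatrix
from .zero_identification import ZeroFlagReport

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_matrix",
    "read_distance_matrix",
    "read_covariates",
    "write_hierarchy",
    "write_flag_report",
]


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_count_matrix(
    path: str | Path, orientation: str = "samples-rows"
) -> CountMatrix:
    """Read a count matrix; ``orientation`` says what the rows are."""
    if orientation not in ("samples-rows", "taxa-rows"):
        raise ValueError("orientation must be 'samples-rows' or 'taxa-rows'")
    sep = _sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    col_kind = "taxon" if orientation == "samples-rows" else "sample"
    dupes = pd.Series(header)[pd.Series(header).duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate {col_kind} id(s): {', '.join(dupes)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "taxa-rows":
        df = df.T
    sample_ids = [str(s) for s in df.index]
    taxon_ids = [str(t) for t in df.columns]
    for name, ids in (("sample", sample_ids), ("taxon", taxon_ids)):
        dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
        if len(dupes):
            raise ValueError(f"duplicate {name} id(s): {', '.join(dupes)}")
    return CountMatrix(df.to_numpy(dtype=float), sample_ids, taxon_ids)


def write_matrix(matrix: CountMatrix | LogMatrix, path: str | Path,
                 na_missing: bool = False) -> None:
    """Write a matrix as TSV/CSV (samples as rows).  For a LogMatrix with
    ``na_missing=True``, masked entries are written as NA."""
    values = matrix.values
    if na_missing and isinstance(matrix, LogMatrix):
        values = values.copy()
        values[matrix.missing_mask] = np.nan
    df = pd.DataFrame(values, index=matrix.sample_ids, columns=matrix.taxon_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep(path))


def read_distance_matrix(path: str | Path) -> TaxonDistanceMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValueError("distance matrix row/column ids differ")
    return TaxonDistanceMatrix(df.to_numpy(dtype=float), row_ids)


def read_covariates(path: str | Path, sample_ids: list[str]) -> pd.DataFrame:
    """Read a covariate table and align it to the count matrix's samples.

    Out-of-order samples are reordered by id (logged); missing or unknown
    sample ids are an error.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValueError(f"covariates missing for sample(s): {', '.join(missing)}")
    extra = [s for s in df.index if s not in set(sample_ids)]
    if extra:
        raise ValueError(f"covariates for unknown sample(s): {', '.join(extra)}")
    if list(df.index) != sample_ids:
        logger.info("covariate table reordered to match count matrix")
        df = df.loc[sample_ids]
    return df


def write_hierarchy(hierarchy: PhyloHierarchy, path: str | Path) -> None:
    rows = {
        "taxon_id": hierarchy.taxon_ids,
        **{
            lvl: [hierarchy.assignment[lvl][t] for t in hierarchy.taxon_ids]
            for lvl in ("S", "G", "F")
        },
    }
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def write_flag_report(
    report: ZeroFlagReport, log_matrix: LogMatrix, flags_path: str | Path,
    summary_path: str | Path,
) -> None:
    """Write the flag mask and a per-taxon fit summary."""
    pd.DataFrame(
        report.flags.astype(int),
        index=log_matrix.sample_ids,
        columns=log_matrix.taxon_ids,
    ).rename_axis("sample_id").to_csv(flags_path, sep=_sep(flags_path))
    rows = []
    for taxon in log_matrix.taxon_ids:
        fit = report.fits.get(taxon)
        rows.append(
            {
                "taxon_id": taxon,
                "kept": taxon in report.kept_taxa,
                "fitted": fit is not None,
                "p": fit.p if fit else np.nan,
                "alpha": fit.alpha if fit else np.nan,
                "beta": fit.beta if fit else np.nan,
                "sigma": fit.sigma if fit else np.nan,
                "lrt_pvalue": fit.lrt_pvalue if fit else np.nan,
                "converged": fit.converged if fit else False,
                "error": report.failures.get(taxon, ""),
            }
        )
    pd.DataFrame(rows).to_csv(summary_path, sep=_sep(summary_path), index=False)
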