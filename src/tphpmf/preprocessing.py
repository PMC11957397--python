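"""Normalization, log transformation and missing-entry marking.

Microbiome taxon count matrices carry wildly different library sizes, so
raw counts are first rescaled so every sample (row) totals a common library
size (10**6 by default), then moved to a log10 scale with a pseudo-count
offset strictly greater than 1 so that every transformed value is strictly
positive.  Zero counts map to ``log10(offset)``; the subset of those zeros
judged non-biological is recorded in an explicit boolean mask and excluded
from all downstream likelihood terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_LIBRARY_SIZE = 1e6
DEFAULT_OFFSET = 1.01

__all__ = [
    "CountMatrix",
    "LogMatrix",
    "normalize_counts",
    "log_transform",
    "mark_missing",
    "inverse_transform",
    "DEFAULT_LIBRARY_SIZE",
    "DEFAULT_OFFSET",
]


@dataclass
class CountMatrix:
    """Non-negative sample-by-taxon abundance matrix with identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.taxon_ids = list(self.taxon_ids)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.taxon_ids) != m:
            raise ValueError(f"{len(self.taxon_ids)} taxon ids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != m:
            raise ValueError("duplicate taxon ids")
        if np.any(self.values < 0):
            raise ValueError("negative entries in count matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in count matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LogMatrix:
    """log10-scale abundance matrix with a missing-entry mask.

    ``missing_mask`` is True on entries to be imputed; those entries retain
    the placeholder value ``log10(offset)`` but carry no information.
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    offset: float = DEFAULT_OFFSET
    library_size: float = DEFAULT_LIBRARY_SIZE
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        if self.offset <= 1:
            raise ValueError("offset must be > 1 for strict positivity")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def zero_value(self) -> float:
        """Transformed value of a zero count."""
        return float(np.log10(self.offset))

    def copy(self) -> "LogMatrix":
        return replace(
            self, values=self.values.copy(), missing_mask=self.missing_mask.copy()
        )


def normalize_counts(
    counts: CountMatrix, library_size: float = DEFAULT_LIBRARY_SIZE
) -> CountMatrix:
    """Rescale every sample so its total count equals ``library_size``.

    Raises
    ------
    ValueError
        If any sample has zero total count (an empty library is a data
        error, not something to drop silently).
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    totals = counts.values.sum(axis=1)
    empty = np.flatnonzero(totals <= 0)
    if empty.size:
        bad = ", ".join(counts.sample_ids[i] for i in empty)
        raise ValueError(f"zero library size for sample(s): {bad}")
    scaled = library_size * counts.values / totals[:, None]
    return CountMatrix(scaled, counts.sample_ids, counts.taxon_ids)


def log_transform(
    normalized: CountMatrix, offset: float = DEFAULT_OFFSET,
    library_size: float = DEFAULT_LIBRARY_SIZE,
) -> LogMatrix:
    """Apply ``log10(x + offset)`` entrywise; ``offset > 1`` keeps all
    transformed values strictly positive."""
    if offset <= 1:
        raise ValueError("offset must be > 1 to guarantee positive values")
    values = np.log10(normalized.values + offset)
    return LogMatrix(
        values,
        normalized.sample_ids,
        normalized.taxon_ids,
        offset=offset,
        library_size=library_size,
    )


def mark_missing(log_matrix: LogMatrix, flags: np.ndarray) -> LogMatrix:
    """Return a copy with ``flags`` as the missing mask.

    Only entries equal to the zero placeholder ``log10(offset)`` may be
    flagged: non-zero observations are data, never imputation targets.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != log_matrix.shape:
        raise ValueError("flag shape does not match matrix")
    is_zero = np.isclose(log_matrix.values, log_matrix.zero_value, atol=1e-12)
    offending = flags & ~is_zero
    if offending.any():
        i, j = np.argwhere(offending)[0]
        raise ValueError(
            "cannot flag non-zero entry "
            f"({log_matrix.sample_ids[i]}, {log_matrix.taxon_ids[j]})"
        )
    out = log_matrix.copy()
    out.missing_mask = flags.copy()
    return out


def inverse_transform(
    log_matrix: LogMatrix, original_totals: np.ndarray | None = None
) -> CountMatrix:
    """Map a log-scale matrix back to the count scale.

    Entries become ``max(0, 10**value - offset)``; if per-sample original
    totals are given the result is rescaled from the common library size
    back to each sample's native depth.
    """
    counts = np.maximum(0.0, 10.0 ** log_matrix.values - log_matrix.offset)
    if original_totals is not None:
        original_totals = np.asarray(original_totals, dtype=float)
        counts = counts * (original_totals[:, None] / log_matrix.library_size)
    return CountMatrix(counts, log_matrix.sample_ids, log_matrix.taxon_ids)
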