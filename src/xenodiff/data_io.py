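"""Expression-matrix container, delimited-text I/O, missingness filtering
and nearest-neighbor imputation.

The pipeline's universal input is a cells x genes table of continuous
log-scale expression values (e.g. single-cell Biomark qPCR readouts) with
one class label per cell. Missing measurements are tracked explicitly in a
boolean mask so that filtering and imputation are separate, auditable steps.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateResultError,
    FormatError,
    ParameterError,
)

#: Tokens (case-insensitive) treated as a missing measurement on load.
DEFAULT_MISSING_TOKENS = frozenset({"", "na", "nan"})


@dataclass
class ExpressionMatrix:
    """Cells x genes continuous expression with labels and a missing mask.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_genes)
        Continuous expression values. Entries where ``missing_mask`` is True
        are placeholders (NaN) until imputed.
    cell_ids, gene_ids : list of str
        Ordered, duplicate-free identifiers.
    labels : ndarray of str, shape (n_cells,)
        Per-cell class label (e.g. ``"human"`` / ``"pdx"``).
    missing_mask : ndarray of bool, shape (n_cells, n_genes)
        True exactly where the measurement is absent.
    provenance : dict
        Free-form record of filtering/imputation applied so far.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray
    missing_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_cells, n_genes = self.values.shape
        if self.missing_mask.shape != self.values.shape:
            raise FormatError("values and missing_mask shapes differ")
        if len(self.labels) != n_cells:
            raise FormatError("labels length does not match number of cells")
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise FormatError("identifier lists do not match matrix shape")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene identifiers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list:
        return sorted(set(self.labels.tolist()))

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        """Return a DataFrame (cells as rows) with the label column last."""
        df = pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)
        df = df.mask(pd.DataFrame(self.missing_mask, index=df.index, columns=df.columns))
        df[label_column] = self.labels
        return df


def load_matrix(
    path,
    label_column: str = "label",
    delimiter: str = ",",
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> ExpressionMatrix:
    """Read a delimited cells x genes table into an :class:`ExpressionMatrix`.

    The first column is taken as the cell identifier; every other column
    except ``label_column`` is a gene. Row and column order are preserved.
    Fields matching ``missing_tokens`` (case-insensitive) become missing
    entries; any other non-numeric field raises :class:`FormatError` naming
    the offending row and column.
    """
    tokens = {t.lower() for t in missing_tokens}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        rows = list(reader)

    id_col, *columns = header
    if label_column not in columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found among {columns}"
        )
    if len(set(columns)) != len(columns):
        dupes = sorted({c for c in columns if columns.count(c) > 1})
        raise FormatError(f"duplicate column identifiers: {dupes}")

    label_idx = columns.index(label_column)
    gene_ids = [c for i, c in enumerate(columns) if i != label_idx]

    cell_ids, labels = [], []
    values = np.empty((len(rows), len(gene_ids)))
    mask = np.zeros_like(values, dtype=bool)
    for r, row in enumerate(rows):
        if len(row) != len(header):
            raise FormatError(f"row {r + 1}: expected {len(header)} fields, got {len(row)}")
        cell_ids.append(row[0])
        fields = row[1:]
        labels.append(fields[label_idx])
        j = 0
        for i, raw in enumerate(fields):
            if i == label_idx:
                continue
            if raw.strip().lower() in tokens:
                values[r, j] = np.nan
                mask[r, j] = True
            else:
                try:
                    values[r, j] = float(raw)
                except ValueError:
                    raise FormatError(
                        f"row {cell_ids[-1]!r}, column {gene_ids[j]!r}: "
                        f"cannot parse {raw!r} as a number"
                    ) from None
            j += 1

    return ExpressionMatrix(values, cell_ids, gene_ids, np.array(labels), mask)


def write_matrix(m: ExpressionMatrix, path, label_column: str = "label",
                 delimiter: str = ",") -> None:
    """Write the matrix back to delimited text (round-trips with load_matrix)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["cell_id", *m.gene_ids, label_column])
        for i, cid in enumerate(m.cell_ids):
            row = [
                "NA" if m.missing_mask[i, j] else repr(float(m.values[i, j]))
                for j in range(m.n_genes)
            ]
            writer.writerow([cid, *row, str(m.labels[i])])


def write_provenance(m: ExpressionMatrix, path) -> None:
    """Write the provenance sidecar (filters/imputation applied) as JSON."""
    with open(path, "w") as fh:
        json.dump(m.provenance, fh, indent=2, sort_keys=True)


def filter_missing(
    m: ExpressionMatrix, gene_frac: float = 0.5, cell_frac: float = 0.5
) -> ExpressionMatrix:
    """Drop genes, then cells, with too much missing data.

    A gene is removed when it is missing in strictly more than ``gene_frac``
    of cells; afterwards a cell is removed when it is missing in strictly
    more than ``cell_frac`` of the *retained* genes. Ties at the threshold
    are kept. Removal counts are recorded in ``provenance``.
    """
    for name, frac in (("gene_frac", gene_frac), ("cell_frac", cell_frac)):
        if not 0 < frac <= 1:
            raise ParameterError(f"{name} must be in (0, 1], got {frac}")

    gene_missing = m.missing_mask.mean(axis=0)
    keep_genes = gene_missing <= gene_frac
    if not keep_genes.any():
        raise DegenerateResultError("all genes removed by missingness filter")

    mask_g = m.missing_mask[:, keep_genes]
    cell_missing = mask_g.mean(axis=1)
    keep_cells = cell_missing <= cell_frac
    if not keep_cells.any():
        raise DegenerateResultError("all cells removed by missingness filter")

    prov = dict(m.provenance)
    prov["filter_missing"] = {
        "gene_frac": gene_frac,
        "cell_frac": cell_frac,
        "genes_removed": int((~keep_genes).sum()),
        "cells_removed": int((~keep_cells).sum()),
        "genes_kept": int(keep_genes.sum()),
        "cells_kept": int(keep_cells.sum()),
    }
    return ExpressionMatrix(
        m.values[np.ix_(keep_cells, keep_genes)],
        [c for c, k in zip(m.cell_ids, keep_cells) if k],
        [g for g, k in zip(m.gene_ids, keep_genes) if k],
        m.labels[keep_cells],
        m.missing_mask[np.ix_(keep_cells, keep_genes)],
        prov,
    )


def _pairwise_distances(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean squared difference over genes observed in both cells.

    Normalizing by the number of shared observed genes corrects the scale
    bias of raw Euclidean distance over unequal support. Pairs sharing no
    observed gene get distance +inf.
    """
    obs = ~mask
    vals = np.where(obs, values, 0.0)
    # sum over shared genes of (x - y)^2, expanded so missing entries drop out
    sq = vals**2
    shared = obs.astype(float) @ obs.T.astype(float)
    cross = vals @ vals.T
    s1 = sq @ obs.T.astype(float)
    ssd = s1 + s1.T - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(shared > 0, ssd / shared, np.inf)
    np.clip(d, 0.0, None, out=d)  # guard tiny negative rounding
    return d


def impute_nn(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing entries by nearest-neighbor averaging.

    Each missing entry (cell *i*, gene *g*) becomes the mean of *g* over the
    ``k`` nearest cells to *i* that observe *g*, nearest by mean squared
    difference over mutually observed genes; neighbors lacking *g* are
    skipped and the next nearest used. If no neighbor observes *g* the
    gene's overall observed mean is used. Ties in distance are broken by
    input row order. Observed values are never modified.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > m.n_cells - 1:
        raise ParameterError(
            f"k={k} exceeds the number of other cells ({m.n_cells - 1})"
        )
    obs = ~m.missing_mask
    if (~obs.any(axis=1)).any():
        raise ParameterError("a cell has no observed gene; filter first")
    if (~obs.any(axis=0)).any():
        raise ParameterError("a gene is observed in no cell; filter first")

    if not m.missing_mask.any():
        return replace(m, provenance={**m.provenance, "impute_nn": {"k": k, "imputed": 0}})

    values = m.values.copy()
    dist = _pairwise_distances(m.values, m.missing_mask)
    np.fill_diagonal(dist, np.inf)
    col_means = np.array(
        [m.values[obs[:, j], j].mean() for j in range(m.n_genes)]
    )

    n_imputed = 0
    for i, j in zip(*np.nonzero(m.missing_mask)):
        order = np.argsort(dist[i], kind="stable")
        donors = [c for c in order if np.isfinite(dist[i, c]) and obs[c, j]][:k]
        if donors:
            values[i, j] = m.values[donors, j].mean()
        else:
            values[i, j] = col_means[j]
        n_imputed += 1

    prov = dict(m.provenance)
    prov["impute_nn"] = {"k": k, "imputed": n_imputed}
    return ExpressionMatrix(
        values, list(m.cell_ids), list(m.gene_ids), m.labels.copy(),
        np.zeros_like(m.missing_mask), prov,
    )
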