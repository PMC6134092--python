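"""OTU tables, taxonomy maps, and sample metadata.

File dialects are the classic tab-separated ones used across amplicon
workflows: an OTU x sample count table whose header row may be a
``#OTU ID`` comment line and whose last column may be a taxonomy string;
a two-column taxonomy map (otu_id <TAB> rank-prefixed lineage); and a
sample metadata table keyed by its first column.  Lines starting with
``#`` are comments, except a ``#OTU ID``-style header.

The OTU filter reproduces the common low-frequency / low-abundance
rule: drop OTUs detected in fewer than ``min_prevalence`` samples or
with total abundance below ``min_total`` (both bounds exclusive, i.e.
an OTU present in exactly 9 samples with total exactly 10 is kept under
the defaults).
"""

from __future__ import annotations

import io
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import TableError
from .tree import PhyloTree

__all__ = [
    "read_table",
    "write_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "filter_otus",
    "align_tree_table",
]

_TAX_COLUMNS = {"taxonomy", "consensus lineage", "consensuslineage", "lineage"}


def _read_tsv_lines(path) -> Tuple[str, list]:
    """Split a file into (header line, data lines), honouring comments."""
    header = None
    data = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                # '#OTU ID'-style header or plain comment
                if header is None and "\t" in line:
                    header = line.lstrip("#").lstrip()
                continue
            if header is None:
                header = line
            else:
                data.append(line)
    if header is None:
        raise TableError(f"{path}: no header line found")
    return header, data


def read_table(path) -> Tuple[pd.DataFrame, Optional[Dict[str, str]]]:
    """Read an OTU x sample count table.

    Returns ``(table, taxonomy)`` where ``taxonomy`` is the split-off
    trailing taxonomy column as an ``{otu_id: lineage}`` dict, or None.
    """
    header, data = _read_tsv_lines(path)
    cols = header.split("\t")
    ncol = len(cols)
    tax_col = cols[-1].strip().lower() in _TAX_COLUMNS
    sample_ids = cols[1 : ncol - 1 if tax_col else ncol]
    if len(sample_ids) != len(set(sample_ids)):
        raise TableError(f"{path}: duplicate sample ids in header")
    if not sample_ids:
        raise TableError(f"{path}: table has no sample columns")

    otu_ids, rows, taxonomy = [], [], {}
    for lineno, line in enumerate(data, start=2):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise TableError(
                f"{path}: row {lineno} has {len(fields)} fields, expected {ncol}"
            )
        otu = fields[0]
        if tax_col:
            taxonomy[otu] = fields[-1]
            fields = fields[:-1]
        try:
            values = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise TableError(f"{path}: row {lineno}: non-numeric count ({exc})")
        if any(v < 0 for v in values):
            raise TableError(f"{path}: row {lineno}: negative count")
        otu_ids.append(otu)
        rows.append(values)
    if len(otu_ids) != len(set(otu_ids)):
        dupes = sorted({o for o in otu_ids if otu_ids.count(o) > 1})
        raise TableError(f"{path}: duplicate OTU ids: {', '.join(dupes)}")
    if not otu_ids:
        raise TableError(f"{path}: table has no OTU rows")

    arr = np.asarray(rows)
    if np.allclose(arr, np.round(arr)):
        arr = arr.astype(np.int64)
    table = pd.DataFrame(arr, index=pd.Index(otu_ids, name="otu_id"),
                         columns=sample_ids)
    return table, (taxonomy if tax_col else None)


def write_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> Dict[str, str]:
    """Read a two-column taxonomy map: otu_id <TAB> lineage."""
    header, data = _read_tsv_lines(path)
    out: Dict[str, str] = {}
    first = header.split("\t")
    # tolerate headerless two-column files
    lines = data if first[0].lower() in {"otu_id", "otu id", "feature id"} \
        else [header] + data
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise TableError(f"{path}: line {lineno}: expected 2 columns")
        if fields[0] in out:
            raise TableError(f"{path}: duplicate OTU id {fields[0]!r}")
        out[fields[0]] = fields[1].strip()
    return out


def write_taxonomy(taxonomy: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\ttaxonomy\n")
        for otu, lineage in taxonomy.items():
            fh.write(f"{otu}\t{lineage}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata keyed by the first column."""
    header, data = _read_tsv_lines(path)
    buf = io.StringIO("\n".join([header] + data))
    df = pd.read_csv(buf, sep="\t", dtype=str)
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise TableError(f"{path}: duplicate sample ids: {', '.join(dupes)}")
    return df


def filter_otus(
    table: pd.DataFrame,
    min_prevalence: int = 9,
    min_total: float = 10,
    presence_min: float = 1,
) -> pd.DataFrame:
    """Drop low-frequency and low-abundance OTUs.

    Keeps OTUs detected (count >= ``presence_min``) in at least
    ``min_prevalence`` samples AND with total count >= ``min_total``.
    Idempotent and monotone in both thresholds.
    """
    if min_prevalence < 0 or min_total < 0:
        raise TableError("filter thresholds must be nonnegative")
    prevalence = (table >= presence_min).sum(axis=1)
    total = table.sum(axis=1)
    keep = (prevalence >= min_prevalence) & (total >= min_total)
    if not keep.any():
        raise TableError(
            "all OTUs removed by filtering; lower --min-prevalence/--min-total"
        )
    return table.loc[keep]


def align_tree_table(
    tree: PhyloTree, table: pd.DataFrame
) -> Tuple[PhyloTree, pd.DataFrame]:
    """Reconcile tree tips with table rows (intersection), matching order."""
    shared = set(tree.tip_labels) & set(table.index)
    if not shared:
        raise TableError("tree tips and table OTU ids do not overlap")
    pruned = tree.prune(shared)
    aligned = table.loc[pruned.tip_labels]
    return pruned, aligned
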