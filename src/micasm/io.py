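"""Readers and writers for the experiment's on-disk formats.

Canonical formats are plain text for diff-ability: TSV for the OTU count
table, sample metadata, chemistry time series and copy-number map; Newick
for the phylogeny; YAML for run configuration; JSON for results.  All
readers validate and reject malformed values rather than coercing them;
every writer produces files its own reader accepts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

METADATA_COLUMNS = ("treatment", "batch", "replicate", "day")
CHEM_COLUMNS = ("microcosm_id", "treatment", "replicate", "batch",
                "compound", "day", "concentration_ugL")

_BATCH_RE = re.compile(r"^B(\d+)$")


def batch_index(label: str) -> int:
    """Numeric suffix of a batch label, e.g. ``'B3' -> 3``."""
    m = _BATCH_RE.match(str(label))
    if not m:
        raise ValidationError(f"batch label {label!r} does not match 'B<number>'")
    return int(m.group(1))


def sort_batches(labels) -> list[str]:
    """Batch labels ordered by their numeric suffix."""
    return sorted(set(labels), key=batch_index)


@dataclass
class CommunityTable:
    """Integer OTU counts (samples x OTUs) joined to sample metadata.

    ``counts`` is indexed by sample id with OTU ids as columns; ``metadata``
    is indexed by sample id with columns treatment / batch / replicate / day.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate OTU ids: {dupes}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(arr < 0):
            raise FormatError("counts must be non-negative")
        if np.any(arr != np.floor(arr)):
            raise FormatError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        missing = [s for s in self.counts.index if s not in self.metadata.index]
        if missing:
            raise ValidationError(
                f"samples missing from metadata: {missing}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise FormatError(f"metadata lacks required column {col!r}")
        self.metadata = self.metadata.loc[self.counts.index]
        self.counts.index.name = "sample_id"
        self.counts.columns.name = None
        self.metadata.index.name = "sample_id"

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total count: {empty}")
        return self.counts.div(totals, axis=0)

    def subset_samples(self, sample_ids) -> "CommunityTable":
        ids = list(sample_ids)
        return CommunityTable(self.counts.loc[ids].copy(),
                              self.metadata.loc[ids].copy())

    def samples_for(self, treatment: str | None = None,
                    batches=None) -> list[str]:
        md = self.metadata
        mask = pd.Series(True, index=md.index)
        if treatment is not None:
            mask &= md["treatment"] == treatment
        if batches is not None:
            mask &= md["batch"].isin(list(batches))
        return list(md.index[mask])


def read_community(table_path, metadata_path) -> CommunityTable:
    """Load and validate a count table plus its sample metadata."""
    counts = pd.read_csv(table_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CommunityTable(counts, metadata)


def write_community(table: CommunityTable, table_path, metadata_path) -> None:
    table.counts.to_csv(table_path, sep="\t", index_label="sample_id")
    table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


# -- phylogeny ------------------------------------------------------------

def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("tree tip labels are not unique")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree.as_string(schema="newick"))


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric tip-to-tip path-length (cophenetic) distance matrix.

    Computed by accumulating root-to-node depths and subtracting twice the
    depth of the most recent common ancestor, which is linear per tip pair
    after one traversal.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[id(node)] = (depth[id(parent)] + edge) if parent is not None else 0.0
    leaf_index = {id(lf): i for i, lf in enumerate(leaves)}
    depth_arr = np.array([depth[id(lf)] for lf in leaves])
    D = np.zeros((n, n))
    # postorder sweep: each internal node is the MRCA of every pair of
    # leaves drawn from two different child subtrees
    under: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            under[id(node)] = [leaf_index[id(node)]]
            continue
        groups = [under.pop(id(c)) for c in node.child_nodes()]
        d_node = depth[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a], dtype=int)
                ib = np.asarray(groups[b], dtype=int)
                block = depth_arr[ia][:, None] + depth_arr[ib][None, :] - 2.0 * d_node
                D[np.ix_(ia, ib)] = block
                D[np.ix_(ib, ia)] = block.T
        merged = []
        for g in groups:
            merged.extend(g)
        under[id(node)] = merged
    return pd.DataFrame(D, index=labels, columns=labels)


def check_tree_covers(tree_or_matrix, otu_ids) -> None:
    """Raise listing any OTU ids absent from the tree / distance matrix."""
    if isinstance(tree_or_matrix, pd.DataFrame):
        have = set(tree_or_matrix.index)
    else:
        have = {leaf.taxon.label for leaf in tree_or_matrix.leaf_node_iter()}
    missing = sorted(set(otu_ids) - have)
    if missing:
        raise ValidationError(f"OTU ids absent from tree: {missing}")


# -- chemistry ------------------------------------------------------------

def validate_chem(chem: pd.DataFrame) -> pd.DataFrame:
    for col in CHEM_COLUMNS:
        if col not in chem.columns:
            raise FormatError(f"chemistry table lacks column {col!r}")
    if (chem["concentration_ugL"] < 0).any():
        raise FormatError("negative concentration in chemistry table")
    return chem


def read_chem(path) -> pd.DataFrame:
    return validate_chem(pd.read_csv(path, sep="\t"))


def write_chem(chem: pd.DataFrame, path) -> None:
    validate_chem(chem).to_csv(path, sep="\t", index=False)


# -- copy numbers ---------------------------------------------------------

def read_copy_numbers(path) -> pd.Series:
    """OTU id -> 16S copy number (possibly partial map, values >= 1)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("copy-number map needs columns otu_id, copy_number")
    ser = pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                    index=pd.Index(df.iloc[:, 0].astype(str).to_numpy()),
                    name="copy_number")
    if ser.index.duplicated().any():
        raise FormatError("duplicate OTU ids in copy-number map")
    if (ser < 1).any():
        bad = ser.index[ser < 1].tolist()
        raise FormatError(f"copy numbers below 1 for: {bad}")
    return ser


def write_copy_numbers(cn: pd.Series, path) -> None:
    pd.DataFrame({"otu_id": cn.index, "copy_number": cn.to_numpy()}).to_csv(
        path, sep="\t", index=False)
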