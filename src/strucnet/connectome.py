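"""FA-weighted connectivity matrices: container, construction, validation and I/O.

A structural connectome is represented as a symmetric ``n x n`` matrix whose
entry ``(a, b)`` is the mean fractional anisotropy (FA) along the white-matter
connection between gray-matter regions ``a`` and ``b``.  FA is a scalar
diffusion measure bounded in [0, 1]; an entry of 0 means the connection is
absent (no streamline survived filtering).

The default parcellation is the Desikan-Killiany cortical atlas (34 regions
per hemisphere) plus 8 subcortical structures per hemisphere, giving the
84-node network used throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "build_connectivity_matrix",
    "count_possible_connections",
    "validate_matrix",
    "read_matrix",
    "write_matrix",
    "default_node_table",
    "DK_CORTICAL_REGIONS",
    "SUBCORTICAL_REGIONS",
]

SYMMETRY_TOL = 1e-12

#: Desikan-Killiany cortical parcellation, one hemisphere (34 regions).
DK_CORTICAL_REGIONS: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

#: Subcortical gray-matter structures, one hemisphere (8 regions).
SUBCORTICAL_REGIONS: tuple[str, ...] = (
    "thalamus", "caudate", "putamen", "pallidum",
    "hippocampus", "amygdala", "accumbens", "cerebellumcortex",
)


class MatrixFormatError(ValueError):
    """A connectivity-matrix file or array violates a container invariant."""


@dataclass
class ConnectivityMatrix:
    """Symmetric FA-weighted adjacency matrix with node labels.

    Parameters
    ----------
    weights
        ``(n, n)`` float array, symmetric, zero diagonal, entries in [0, 1].
    node_labels
        ``n`` unique region names, in matrix order.
    """

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.node_labels:
            self.node_labels = [f"node{i}" for i in range(self.weights.shape[0])]
        self.node_labels = list(self.node_labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        """Raise :class:`MatrixFormatError` on the first violated invariant."""
        report = validate_matrix(self)
        if report:
            raise MatrixFormatError("; ".join(report))

    def upper_triangle(self) -> np.ndarray:
        """Edge-value vector over unordered pairs (row-major upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        return self.weights[iu]

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(self.weights.copy(), list(self.node_labels))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConnectivityMatrix):
            return NotImplemented
        return (
            self.node_labels == other.node_labels
            and self.weights.shape == other.weights.shape
            and bool(np.array_equal(self.weights, other.weights))
        )


def count_possible_connections(n_nodes: int) -> int:
    """Number of unordered region pairs, ``n (n - 1) / 2``.

    For the 84-region parcellation this is the 3486 connections of interest.
    """
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


def validate_matrix(matrix: ConnectivityMatrix) -> list[str]:
    """Check every container invariant; return a report of violations.

    An empty list means the matrix is valid.  Each entry names the violated
    invariant and, where applicable, the offending indices.
    """
    report: list[str] = []
    w = matrix.weights
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        report.append(f"matrix is not square: shape {w.shape}")
        return report
    n = w.shape[0]
    if len(matrix.node_labels) != n:
        report.append(
            f"label count {len(matrix.node_labels)} does not match size {n}"
        )
    if len(set(matrix.node_labels)) != len(matrix.node_labels):
        report.append("node labels are not unique")
    if not np.all(np.isfinite(w)):
        report.append("non-finite entries present")
        return report
    asym = np.abs(w - w.T)
    if asym.max(initial=0.0) > SYMMETRY_TOL:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        report.append(
            f"symmetry violation at ({i}, {j}): "
            f"{w[i, j]!r} vs {w[j, i]!r}"
        )
    diag = np.abs(np.diag(w))
    if diag.max(initial=0.0) > 0:
        report.append(f"nonzero diagonal at node {int(np.argmax(diag))}")
    if w.min(initial=0.0) < 0:
        i, j = np.unravel_index(int(np.argmin(w)), w.shape)
        report.append(f"range violation: negative entry {w[i, j]!r} at ({i}, {j})")
    if w.max(initial=0.0) > 1:
        i, j = np.unravel_index(int(np.argmax(w)), w.shape)
        report.append(f"range violation: FA entry {w[i, j]!r} > 1 at ({i}, {j})")
    return report


def build_connectivity_matrix(
    filtered_sets: Mapping[tuple[int, int], Iterable],
    n_nodes: int,
    node_labels: Sequence[str] | None = None,
    weight_by_track: bool = False,
) -> ConnectivityMatrix:
    """Assemble an FA-weighted matrix from per-connection streamline sets.

    Entry ``(a, b)`` is the arithmetic mean of the per-streamline mean-FA
    values of the surviving records for pair ``(a, b)`` (0 where no record
    survives).  With ``weight_by_track=True`` the mean is weighted by track
    weight instead.

    Records are expected to be already filtered (see :mod:`strucnet.aec`).
    """
    weights = np.zeros((n_nodes, n_nodes), dtype=float)
    for (a, b), records in filtered_sets.items():
        records = list(records)
        if not records:
            continue
        for r in records:
            if r.node_a >= n_nodes or r.node_b >= n_nodes:
                raise ValueError(
                    f"record {r.streamline_id} references node index "
                    f">= n_nodes={n_nodes}"
                )
        fa = np.array([r.mean_fa for r in records], dtype=float)
        if weight_by_track:
            wts = np.array([r.weight for r in records], dtype=float)
            value = float(np.average(fa, weights=wts))
        else:
            value = float(fa.mean())
        weights[a, b] = weights[b, a] = value
    labels = list(node_labels) if node_labels is not None else None
    matrix = ConnectivityMatrix(weights, labels or [])
    matrix.validate()
    return matrix


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Write a matrix as labelled TSV (lossless at full float precision)."""
    matrix.validate()
    df = pd.DataFrame(
        matrix.weights, index=matrix.node_labels, columns=matrix.node_labels
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path) -> ConnectivityMatrix:
    """Read a labelled-TSV matrix, validating every container invariant."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MatrixFormatError(f"matrix is not square: shape {values.shape}")
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if row_labels != col_labels:
        raise MatrixFormatError("row and column labels differ")
    matrix = ConnectivityMatrix(values, row_labels)
    matrix.validate()
    return matrix


def write_edgelist(matrix: ConnectivityMatrix, path) -> None:
    """Export nonzero edges as TSV (node_a_label, node_b_label, weight)."""
    rows = []
    iu = zip(*np.triu_indices(matrix.n, k=1))
    for i, j in iu:
        w = matrix.weights[i, j]
        if w > 0:
            rows.append((matrix.node_labels[i], matrix.node_labels[j], w))
    pd.DataFrame(rows, columns=["node_a_label", "node_b_label", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def default_node_table() -> pd.DataFrame:
    """84-region node table: 34 DK cortical + 8 subcortical per hemisphere.

    Columns: ``index`` (0-based, contiguous), ``label`` (unique), ``hemisphere``
    (left/right), ``class`` (cortical/subcortical).  Left-hemisphere regions
    come first, cortical before subcortical within each hemisphere.
    """
    rows = []
    for hemi in ("left", "right"):
        prefix = "lh" if hemi == "left" else "rh"
        for name in DK_CORTICAL_REGIONS:
            rows.append((f"ctx-{prefix}-{name}", hemi, "cortical"))
        for name in SUBCORTICAL_REGIONS:
            rows.append((f"{prefix}-{name}", hemi, "subcortical"))
    df = pd.DataFrame(rows, columns=["label", "hemisphere", "class"])
    df.insert(0, "index", np.arange(len(df)))
    return df
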