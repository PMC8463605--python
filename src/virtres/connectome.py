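"""Structural connectivity matrices and the transforms used to build them.

A structural connectome is held as a square, symmetric, non-negative
adjacency matrix over brain regions (92 AAL/FIRST regions in the study
design this package follows, but any size works).  Raw tractography output
is directed and noisy, so the standard construction is: symmetrize by
averaging both directions, then threshold to a fixed connection density
(11% by default, matching a literature-based healthy structural network)
and binarize.  Weighted and log-weighted variants are kept for sensitivity
analyses.

Node indexing is 0-based everywhere, including all file interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import MatrixDomainError, MatrixFormatError, ParameterError

__all__ = [
    "ConnectomeMatrix",
    "SeedSet",
    "symmetrize",
    "threshold_to_density",
    "log_transform",
    "average_cohort",
    "read_connectome",
    "write_connectome",
    "write_edge_list",
]

_SYMMETRY_TOL = 1e-12
_READ_SYMMETRY_TOL = 1e-9


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"ROI{i:03d}" for i in range(n))


@dataclass(frozen=True)
class ConnectomeMatrix:
    """A validated symmetric non-negative adjacency matrix with node labels.

    Parameters
    ----------
    values
        N x N symmetric non-negative matrix with a zero diagonal.  Entries
        are tract-count-like weights, or {0, 1} for a binarized network.
    labels
        One region name per node; generated ``ROI000 ...`` when omitted.
    is_binary
        Whether the matrix is a binarized network.  Inferred from the
        entries when not given explicitly.
    """

    values: np.ndarray
    labels: tuple[str, ...] = field(default=())
    is_binary: bool = field(default=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixFormatError(f"matrix must be square, got shape {v.shape}")
        if np.any(v < 0):
            raise MatrixDomainError("matrix entries must be non-negative")
        if np.max(np.abs(v - v.T), initial=0.0) > _SYMMETRY_TOL:
            raise MatrixDomainError(
                "matrix is not symmetric within tolerance "
                f"{_SYMMETRY_TOL:g}; call symmetrize() first"
            )
        if np.any(np.diagonal(v) != 0):
            raise MatrixDomainError("matrix diagonal must be zero (no self-loops)")
        labels = tuple(self.labels) if self.labels else _default_labels(v.shape[0])
        if len(labels) != v.shape[0]:
            raise MatrixFormatError(
                f"{len(labels)} labels for {v.shape[0]} nodes"
            )
        binary = bool(np.isin(v, (0.0, 1.0)).all())
        if self.is_binary and not binary:
            raise MatrixDomainError("is_binary=True but entries are not all in {0,1}")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "is_binary", self.is_binary or binary)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def density(self) -> float:
        """Fraction of possible undirected edges present."""
        n = self.n_nodes
        iu = np.triu_indices(n, k=1)
        return float(np.count_nonzero(self.values[iu]) / (n * (n - 1) // 2))

    def edges(self) -> list[tuple[int, int]]:
        """Present upper-triangle edges in ascending (i, j) order."""
        i, j = np.nonzero(np.triu(self.values, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def degree(self) -> np.ndarray:
        """Binary degree (neighbor count) per node."""
        return np.count_nonzero(self.values, axis=1)


@dataclass(frozen=True)
class SeedSet:
    """The hypothesized epileptogenic-zone (EZ) nodes.

    Seizures are seeded on these nodes and their mean eigenvector
    centrality is the surrogate optimization target.
    """

    node_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.node_indices)
        if len(idx) == 0:
            raise ParameterError("seed set must be non-empty")
        if len(set(idx)) != len(idx):
            raise ParameterError("seed set contains duplicate node indices")
        if any(i < 0 for i in idx):
            raise ParameterError("seed node indices must be non-negative")
        object.__setattr__(self, "node_indices", idx)

    def __len__(self) -> int:
        return len(self.node_indices)

    def __iter__(self):
        return iter(self.node_indices)

    def validate_for(self, connectome: ConnectomeMatrix) -> None:
        n = connectome.n_nodes
        if any(i >= n for i in self.node_indices):
            raise ParameterError(
                f"seed index out of range for a {n}-node connectome: "
                f"{self.node_indices}"
            )

    def mask(self, n: int) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        m[list(self.node_indices)] = True
        return m


def symmetrize(values: np.ndarray) -> np.ndarray:
    """Average a square matrix with its transpose and zero the diagonal.

    This is the standard fix for directed tract counts: the (i, j) and
    (j, i) streamline counts are averaged into one undirected weight.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise MatrixFormatError(f"matrix must be square, got shape {v.shape}")
    if np.any(v < 0):
        raise MatrixDomainError("matrix entries must be non-negative")
    out = (v + v.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero; np.round would round half to even
    return int(math.floor(x + 0.5))


def threshold_to_density(
    connectome: ConnectomeMatrix, target_density: float, binarize: bool = True
) -> ConnectomeMatrix:
    """Keep only the strongest edges so the network has a fixed density.

    The ``E = round(d * N(N-1)/2)`` largest-weight upper-triangle entries
    are retained (half-away-from-zero rounding) and mirrored.  Ties at the
    cutoff weight are broken by ascending (i, j) edge index, so results are
    deterministic.  With ``binarize`` the kept entries become 1.
    """
    if not 0 < target_density <= 1:
        raise ParameterError(f"target_density must be in (0, 1], got {target_density}")
    n = connectome.n_nodes
    m_possible = n * (n - 1) // 2
    n_keep = _round_half_away(target_density * m_possible)
    if n_keep == 0:
        raise ParameterError(
            f"target_density={target_density} keeps zero edges on {n} nodes"
        )
    iu, ju = np.triu_indices(n, k=1)
    w = connectome.values[iu, ju]
    if np.count_nonzero(w) < n_keep:
        raise ParameterError(
            f"matrix has only {np.count_nonzero(w)} nonzero edges; "
            f"cannot reach density {target_density} ({n_keep} edges)"
        )
    # primary key: weight descending; ties: ascending (i, j)
    order = np.lexsort((ju, iu, -w))[:n_keep]
    out = np.zeros_like(connectome.values)
    kept_w = np.ones(n_keep) if binarize else w[order]
    out[iu[order], ju[order]] = kept_w
    out[ju[order], iu[order]] = kept_w
    return ConnectomeMatrix(out, labels=connectome.labels, is_binary=binarize)


def log_transform(connectome: ConnectomeMatrix) -> ConnectomeMatrix:
    """Compress tract-count weights as ``w -> ln(1 + w)``; zeros stay zero.

    Raw streamline counts span orders of magnitude, which lets a handful of
    very strong connections dominate spectral measures; the log restores a
    comparable scale.  ``ln(1+w)`` rather than ``ln(w)`` keeps the map
    defined (and monotone) at w = 0 and for weights below 1.
    """
    if connectome.is_binary:
        raise ParameterError("log transform of a binary matrix is meaningless")
    return ConnectomeMatrix(np.log1p(connectome.values), labels=connectome.labels)


def average_cohort(matrices: Sequence[ConnectomeMatrix]) -> ConnectomeMatrix:
    """Elementwise mean of full weighted matrices across subjects.

    The average is taken *before* any thresholding; apply
    :func:`threshold_to_density` to the result separately.
    """
    if len(matrices) < 2:
        raise ParameterError("need at least 2 matrices to average")
    first = matrices[0]
    for c in matrices:
        if c.n_nodes != first.n_nodes:
            raise MatrixFormatError("matrices differ in node count")
        if c.labels != first.labels:
            raise MatrixFormatError("matrices differ in node labels")
        if c.is_binary:
            raise ParameterError("average_cohort expects weighted matrices")
    mean = np.mean([c.values for c in matrices], axis=0)
    return ConnectomeMatrix(mean, labels=first.labels)


def _sniff_delimiter(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "," if "," in line else None
    raise MatrixFormatError(f"{path} is empty")


def read_connectome(
    path: str | Path, labels_path: str | Path | None = None
) -> ConnectomeMatrix:
    """Read a delimited (comma or whitespace) square matrix file.

    Mild asymmetry (max |A - A.T| <= 1e-9, e.g. from limited print
    precision) is repaired by :func:`symmetrize`; larger asymmetry is an
    error because it indicates an un-symmetrized tractography matrix.
    An optional sidecar file provides one region label per line.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    try:
        values = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise MatrixFormatError(f"could not parse {path}: {exc}") from exc
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MatrixFormatError(
            f"{path}: matrix must be square, got shape {values.shape}"
        )
    if np.any(values < 0):
        raise MatrixDomainError(f"{path}: negative entries are not allowed")
    if np.max(np.abs(values - values.T), initial=0.0) > _READ_SYMMETRY_TOL:
        raise MatrixDomainError(
            f"{path}: asymmetry exceeds {_READ_SYMMETRY_TOL:g}; "
            "symmetrize the raw matrix explicitly"
        )
    labels: tuple[str, ...] = ()
    if labels_path is not None:
        lines = [ln.strip() for ln in Path(labels_path).read_text().splitlines()]
        labels = tuple(ln for ln in lines if ln)
        if len(labels) != values.shape[0]:
            raise MatrixFormatError(
                f"{labels_path}: {len(labels)} labels for "
                f"{values.shape[0]} nodes"
            )
    return ConnectomeMatrix(symmetrize(values), labels=labels)


def write_connectome(connectome: ConnectomeMatrix, path: str | Path) -> None:
    """Write as headerless CSV with 12 significant digits."""
    np.savetxt(path, connectome.values, delimiter=",", fmt="%.12g")


def write_edge_list(connectome: ConnectomeMatrix, path: str | Path) -> None:
    """Write present upper-triangle edges as TSV: node_i, node_j, weight (0-based)."""
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for i, j in connectome.edges():
            fh.write(f"{i}\t{j}\t{connectome.values[i, j]:.12g}\n")
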