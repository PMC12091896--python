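"""Distance-binned adjacency tensors over binding-site atoms.

An adjacency scheme is an ordered list of half-open distance intervals
(lo, hi] in Angstrom.  Slice k of the tensor connects atom pairs whose
distance falls in interval k; with ``inter_only`` schemes only
protein-ligand pairs qualify, so every edge is an inter-molecular contact.
Normalization adds self-loops per slice and applies the symmetric degree
scaling D^{-1/2} (A + I) D^{-1/2} used by spectral graph convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structures import BindingSite

__all__ = [
    "AdjacencyScheme",
    "AdjacencyTensor",
    "NormalizedAdjacency",
    "SCHEMES",
    "get_scheme",
    "build_adjacency_tensor",
    "normalize",
]


@dataclass(frozen=True)
class AdjacencyScheme:
    name: str
    ranges: tuple[tuple[float, float], ...]  # (lo, hi], Angstrom
    inter_only: bool

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for lo, hi in self.ranges:
            if hi <= lo:
                raise ValueError(f"{self.name}: empty interval ({lo}, {hi}]")
            if lo < prev_hi:
                raise ValueError(f"{self.name}: overlapping intervals")
            prev_hi = hi

    @property
    def K(self) -> int:
        return len(self.ranges)


SCHEMES = {
    # two inter-molecular contact ranges: the default
    "AGIMA_2": AdjacencyScheme("AGIMA_2", ((2.0, 3.0), (3.0, 4.0)), inter_only=True),
    # single-adjacency-matrix ablation: one merged range
    "AGIMA_SAM": AdjacencyScheme("AGIMA_SAM", ((2.0, 4.0),), inter_only=True),
    # GraphBAR-style schemes keep intra-molecular contacts too
    "GRAPHBAR_2AM": AdjacencyScheme(
        "GRAPHBAR_2AM", ((0.0, 2.0), (2.0, 4.0)), inter_only=False
    ),
    "GRAPHBAR_3AM": AdjacencyScheme(
        "GRAPHBAR_3AM", ((0.0, 2.0), (2.0, 3.0), (3.0, 4.0)), inter_only=False
    ),
}


def get_scheme(name: str) -> AdjacencyScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise KeyError(f"unknown adjacency scheme {name!r}; choose from {sorted(SCHEMES)}")


@dataclass
class AdjacencyTensor:
    """Binary n x n x K tensor; slices are symmetric, zero-diagonal, disjoint."""

    slices: np.ndarray  # (n, n, K) uint8
    scheme: AdjacencyScheme

    @property
    def n(self) -> int:
        return self.slices.shape[0]

    @property
    def K(self) -> int:
        return self.slices.shape[2]


@dataclass
class NormalizedAdjacency:
    """Per-slice D^{-1/2} (A + I) D^{-1/2}, dense float matrices."""

    slices: list[np.ndarray]
    scheme: AdjacencyScheme

    @property
    def n(self) -> int:
        return self.slices[0].shape[0]

    @property
    def K(self) -> int:
        return len(self.slices)


def build_adjacency_tensor(
    site: BindingSite, scheme: AdjacencyScheme | str
) -> AdjacencyTensor:
    """Bin the site's pairwise distances into the scheme's slices.

    A_ijk = 1 iff d_ij in (lo_k, hi_k] and, for inter-only schemes, atoms
    i and j come from different molecules.  The diagonal stays zero;
    self-loops are added only at normalization time.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    D = site.distance_matrix
    n = D.shape[0]
    A = np.zeros((n, n, scheme.K), dtype=np.uint8)
    if scheme.inter_only:
        lig = site.origin_mask
        pair_ok = lig[:, None] != lig[None, :]
    else:
        pair_ok = ~np.eye(n, dtype=bool)
    off_diag = ~np.eye(n, dtype=bool)
    for k, (lo, hi) in enumerate(scheme.ranges):
        A[:, :, k] = ((D > lo) & (D <= hi) & pair_ok & off_diag).astype(np.uint8)
    return AdjacencyTensor(slices=A, scheme=scheme)


def normalize(tensor: AdjacencyTensor) -> NormalizedAdjacency:
    """Self-loop normalization of each slice.

    C_k = A_k + I; D_ii = sum_j C_ij; returns D^{-1/2} C_k D^{-1/2}.
    Degrees are >= 1 after the self-loops, so the scaling is always
    defined; an isolated node's row is the unit basis vector.
    """
    n = tensor.n
    out = []
    eye = np.eye(n)
    for k in range(tensor.K):
        C = tensor.slices[:, :, k].astype(float) + eye
        d = C.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(d)
        out.append(C * inv_sqrt[:, None] * inv_sqrt[None, :])
    return NormalizedAdjacency(slices=out, scheme=tensor.scheme)


def export_tensor(tensor: AdjacencyTensor, path) -> None:
    """Coordinate-list text export: one '(i, j, k, 1)' row per set entry."""
    with open(path, "w") as fh:
        for k, (lo, hi) in enumerate(tensor.scheme.ranges):
            fh.write(f"# slice {k}: ({lo}, {hi}] A, inter_only={tensor.scheme.inter_only}\n")
        ii, jj, kk = np.nonzero(tensor.slices)
        for i, j, k in zip(ii, jj, kk):
            fh.write(f"{i}\t{j}\t{k}\t1\n")
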