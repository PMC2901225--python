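"""Simple Mantel test between two binary adjacency matrices.

The consistency statistic r is the Pearson correlation of the strictly
lower-triangular entries of the PPI adjacency matrix A and the CT adjacency
matrix B over the same gene order.  Significance comes from permuting one
matrix's rows and columns simultaneously (one-sided, upper tail: consistency
means positive r), with the add-one p estimator; ties r_perm = r_obs count
toward the tail.  Across many gene sets, p-values are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .network import IntegratedNetwork

STATUS_TESTED = "tested"
STATUS_ZERO_VARIANCE = "untestable_zero_variance"
STATUS_NO_EDGES = "untestable_no_edges"

_TIE_TOL = 1e-12
_EXACT_MAX_N = 8


def _validate_matrix(m: np.ndarray, name: str, n: int) -> np.ndarray:
    m = np.asarray(m)
    if m.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}")
    if not np.array_equal(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.isin(m, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    if np.diagonal(m).any():
        raise ValueError(f"{name} must have a zero diagonal")
    return m.astype(np.int8)


@dataclass(frozen=True)
class AdjacencyPair:
    """Gene-ordered 0/1 adjacency matrices: A for the PPI layer, B for CT."""

    genes: tuple[str, ...]
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genes)
        object.__setattr__(self, "A", _validate_matrix(self.A, "A", n))
        object.__setattr__(self, "B", _validate_matrix(self.B, "B", n))

    @property
    def n(self) -> int:
        return len(self.genes)


def adjacency_pair(net: IntegratedNetwork, genes) -> AdjacencyPair:
    """Extract the PPI/CT sub-network adjacency matrices for ``genes``."""
    genes = tuple(sorted(genes))
    stray = set(genes) - net.gene_set
    if stray:
        raise ValueError(f"genes absent from network: {sorted(stray)[:5]}")
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    A = np.zeros((n, n), dtype=np.int8)
    B = np.zeros((n, n), dtype=np.int8)
    gene_set = set(genes)
    for mat, layer in ((A, net.ppi), (B, net.ct)):
        for a, b in layer.edges:
            if a in gene_set and b in gene_set:
                i, j = index[a], index[b]
                mat[i, j] = mat[j, i] = 1
    return AdjacencyPair(genes, A, B)


@dataclass(frozen=True)
class MantelResult:
    r: float | None
    p: float | None
    q: float | None
    n_permutations: int
    status: str

    @property
    def tested(self) -> bool:
        return self.status == STATUS_TESTED


def _tri_vectors(pair: AdjacencyPair) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    il = np.tril_indices(pair.n, -1)
    return pair.A[il].astype(float), pair.B[il].astype(float), il


def _status(a: np.ndarray, b: np.ndarray, n: int) -> str:
    if a.sum() == 0 or b.sum() == 0:
        return STATUS_NO_EDGES
    if n < 3 or a.std() == 0 or b.std() == 0:
        return STATUS_ZERO_VARIANCE
    return STATUS_TESTED


def mantel_r(pair: AdjacencyPair) -> float | None:
    """Pearson correlation over the n(n-1)/2 strictly-lower-triangle entries;
    ``None`` (undefined) when either vector is constant or n < 3."""
    a, b, _ = _tri_vectors(pair)
    if _status(a, b, pair.n) != STATUS_TESTED:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def _untestable(status: str) -> MantelResult:
    return MantelResult(r=None, p=None, q=None, n_permutations=0, status=status)


def mantel_permutation_test(
    pair: AdjacencyPair,
    n_permutations: int = 10000,
    seed: int = 0,
    exact: bool = False,
) -> MantelResult:
    """One-sided Mantel permutation test.

    Each permutation relabels B's rows and columns simultaneously (A fixed)
    and recomputes r.  With ``exact=True`` (n <= 8) all n! relabelings are
    enumerated and p is the exact tail fraction (the identity is included, so
    p > 0); otherwise p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).
    """
    a, b, il = _tri_vectors(pair)
    status = _status(a, b, pair.n)
    if status != STATUS_TESTED:
        return _untestable(status)
    n = pair.n
    m = len(a)
    a_mean, a_std = a.mean(), a.std()
    b_mean, b_std = b.mean(), b.std()  # invariant under vertex relabeling
    r_obs = float(((a - a_mean) * (b - b_mean)).mean() / (a_std * b_std))
    B = pair.B.astype(float)

    def batch_r(perms: np.ndarray) -> np.ndarray:
        rows = perms[:, il[0]]
        cols = perms[:, il[1]]
        bp = B[rows, cols]
        return (bp @ a / m - a_mean * b_mean) / (a_std * b_std)

    if exact:
        if n > _EXACT_MAX_N:
            raise ValueError(f"exact enumeration limited to n <= {_EXACT_MAX_N}")
        perms = np.array(list(itertools.permutations(range(n))))
        r_perm = batch_r(perms)
        tail = int((r_perm >= r_obs - _TIE_TOL).sum())
        total = math.factorial(n)
        return MantelResult(
            r=r_obs, p=tail / total, q=None, n_permutations=total, status=STATUS_TESTED
        )

    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    rng = np.random.default_rng(seed)
    base = np.arange(n)
    tail = 0
    remaining = n_permutations
    while remaining > 0:
        batch = min(remaining, 2048)
        perms = rng.permuted(np.tile(base, (batch, 1)), axis=1)
        tail += int((batch_r(perms) >= r_obs - _TIE_TOL).sum())
        remaining -= batch
    p = (1 + tail) / (1 + n_permutations)
    return MantelResult(
        r=r_obs, p=p, q=None, n_permutations=n_permutations, status=STATUS_TESTED
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
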