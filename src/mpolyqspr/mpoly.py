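"""M-polynomials and degree-based topological indices.

The M-polynomial of a graph G is the bivariate generating function

    M(G; x, y) = sum_{i <= j} m_ij x^i y^j,

where m_ij counts the edges joining a degree-i and a degree-j vertex.
Every degree-based index treated here is a weighted sum over the edge
partition, sum_{i<=j} m_ij * kernel(i, j); the four integer-order indices
(M1, M2, F, HM) can equivalently be read off the polynomial with the
operators Dx = x d/dx, Dy = y d/dy evaluated at x = y = 1, which this
module implements exactly on integer coefficients as a cross-check.

Kernel summation over the edge partition is the single source of truth
for index values; the operator route exists for the integer-order indices
only, because the fractional operators needed for R, SCI and ABC are
neither unique nor numerically preferable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import pandas as pd

from .molgraph import EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "MPolynomial",
    "INDEX_KERNELS",
    "INDEX_NAMES",
    "m_polynomial",
    "evaluate",
    "apply_operator",
    "add",
    "topological_index",
    "index_via_operators",
    "all_indices",
    "descriptor_table",
]


@dataclass(frozen=True)
class MPolynomial:
    """Sparse bivariate polynomial: map (i, j) exponent pair -> coefficient."""

    coefficients: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (i, j), c in self.coefficients.items():
            if i < 1 or j < 1 or i != int(i) or j != int(j):
                raise ValueError(f"exponent pair ({i}, {j}) must be positive integers")
            if c <= 0:
                raise ValueError(f"coefficient of x^{i} y^{j} must be positive, got {c}")


def _abc_kernel(i: int, j: int) -> float:
    # (1,1) would make the radicand negative-free but zero; such an edge only
    # occurs in K2, and a zero contribution keeps batch runs alive.
    if i == 1 and j == 1:
        return 0.0
    return math.sqrt((i + j - 2) / (i * j))


INDEX_KERNELS: dict[str, Callable[[int, int], float]] = {
    "M1": lambda i, j: i + j,
    "M2": lambda i, j: i * j,
    "HM": lambda i, j: (i + j) ** 2,
    "R": lambda i, j: 1.0 / math.sqrt(i * j),
    "H": lambda i, j: 2.0 / (i + j),
    "SCI": lambda i, j: 1.0 / math.sqrt(i + j),
    "F": lambda i, j: i * i + j * j,
    "GA": lambda i, j: 2.0 * math.sqrt(i * j) / (i + j),
    "ABC": _abc_kernel,
}

INDEX_NAMES: tuple[str, ...] = tuple(INDEX_KERNELS)

#: indices whose kernels are integer-valued; exact through the operator route
_INTEGER_INDICES = ("M1", "M2", "HM", "F")


def m_polynomial(p: EdgePartition) -> MPolynomial:
    """M(G;x,y) of an edge partition: coefficients are the m_ij counts."""
    if not p.counts:
        raise ValueError("empty edge partition: a molecular graph has at least one edge")
    return MPolynomial(dict(p.counts))


def evaluate(mp: MPolynomial, x: float, y: float) -> float:
    """Evaluate sum m_ij x^i y^j at a point."""
    return sum(c * x**i * y**j for (i, j), c in mp.coefficients.items())


def apply_operator(mp: MPolynomial, op: str) -> MPolynomial:
    """Apply one of the M-polynomial operators Dx, Dy, Sx, Sy.

    Dx = x d/dx multiplies each coefficient by its x-exponent i (Dy by j);
    Sx divides by i (Sy by j).  Exponents are unchanged.  Integer
    coefficients stay integers under Dx/Dy, which keeps the operator route
    to M1/M2/F/HM exact.
    """
    if op not in ("Dx", "Dy", "Sx", "Sy"):
        raise ValueError(f"unknown operator {op!r}; expected Dx, Dy, Sx or Sy")
    out: dict[tuple[int, int], float] = {}
    for (i, j), c in mp.coefficients.items():
        k = i if op in ("Dx", "Sx") else j
        if op.startswith("S"):
            if k == 0:
                raise ValueError(f"{op} undefined on zero exponent in term ({i},{j})")
            out[(i, j)] = c / k
        else:
            out[(i, j)] = c * k
    return MPolynomial(out)


def add(a: MPolynomial, b: MPolynomial) -> MPolynomial:
    """Sum of two polynomials (coefficient-wise)."""
    out = dict(a.coefficients)
    for key, c in b.coefficients.items():
        out[key] = out.get(key, 0) + c
    return MPolynomial(out)


def topological_index(p: EdgePartition, kind: str) -> float:
    """Kernel summation: sum over degree pairs of m_ij * kernel(i, j)."""
    try:
        kernel = INDEX_KERNELS[kind]
    except KeyError:
        raise ValueError(
            f"unknown index kind {kind!r}; expected one of {INDEX_NAMES}"
        ) from None
    return sum(m * kernel(i, j) for (i, j), m in p.counts.items())


def index_via_operators(mp: MPolynomial, kind: str) -> float:
    """Integer-order index read off the polynomial by operator calculus.

    M1 = (Dx + Dy)M |_(1,1);  M2 = (Dx Dy)M |_(1,1);
    F  = (Dx^2 + Dy^2)M |_(1,1);  HM = (Dx + Dy)^2 M |_(1,1).
    Only defined for the integer-order kinds.
    """
    if kind not in _INTEGER_INDICES:
        raise ValueError(
            f"operator route only defined for {_INTEGER_INDICES}, not {kind!r}"
        )
    Dx = lambda q: apply_operator(q, "Dx")
    Dy = lambda q: apply_operator(q, "Dy")
    if kind == "M1":
        poly = add(Dx(mp), Dy(mp))
    elif kind == "M2":
        poly = Dx(Dy(mp))
    elif kind == "F":
        poly = add(Dx(Dx(mp)), Dy(Dy(mp)))
    else:  # HM
        once = add(Dx(mp), Dy(mp))
        poly = add(Dx(once), Dy(once))
    return evaluate(poly, 1, 1)


def all_indices(g: MolecularGraph) -> dict[str, float]:
    """All nine index values of one graph, keyed by index name."""
    p = edge_partition(g)
    return {kind: topological_index(p, kind) for kind in INDEX_NAMES}


def descriptor_table(graphs: Mapping[str, MolecularGraph]) -> pd.DataFrame:
    """One row per compound id, columns = the nine indices.

    Per-graph failures propagate with the offending id attached.
    """
    rows = {}
    for cid, g in graphs.items():
        try:
            rows[cid] = all_indices(g)
        except Exception as exc:
            raise type(exc)(f"compound {cid!r}: {exc}") from exc
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(INDEX_NAMES))
    df.index.name = "id"
    return df
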