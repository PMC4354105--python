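"""Exact rational linear algebra over :class:`fractions.Fraction`.

The binary null-space algorithm needs an unambiguous notion of "this entry is
zero": with floating point, the superset test that decides elementarity of an
intermediate mode becomes tolerance-dependent.  All matrix transforms in this
package therefore run over exact rationals.  Matrices are plain lists of lists
of Fractions (row major); the functions here are deliberately small and have no
pivoting heuristics beyond "first nonzero", which keeps the row/column order —
and hence the identity-block convention of the kernel — fully deterministic.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence

Row = list[Fraction]
Matrix = list[Row]

ZERO = Fraction(0)
ONE = Fraction(1)


def as_fraction(x) -> Fraction:
    """Convert ints, Fractions, decimal strings and floats to Fraction.

    Floats are converted through their shortest decimal repr so that SBML
    coefficients like 0.5 come out as 1/2, with a denominator cap as a guard
    against binary noise.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x)
    if isinstance(x, float):
        if x == int(x):
            return Fraction(int(x))
        try:
            return Fraction(repr(x))
        except ValueError:  # pragma: no cover - exotic float reprs
            return Fraction(x).limit_denominator(10**9)
    raise TypeError(f"cannot convert {x!r} to Fraction")


def rref(matrix: Matrix) -> tuple[Matrix, list[int]]:
    """Reduced row echelon form; returns (R, pivot_columns)."""
    rows = [list(r) for r in matrix]
    if not rows:
        return rows, []
    m, n = len(rows), len(rows[0])
    pivots: list[int] = []
    r = 0
    for c in range(n):
        if r == m:
            break
        pr = next((i for i in range(r, m) if rows[i][c] != 0), None)
        if pr is None:
            continue
        rows[r], rows[pr] = rows[pr], rows[r]
        piv = rows[r][c]
        rows[r] = [v / piv for v in rows[r]]
        for i in range(m):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
    return rows, pivots


def rank(matrix: Matrix) -> int:
    return len(rref(matrix)[1])


def nullspace(matrix: Matrix, ncols: int) -> list[list[Fraction]]:
    """Basis of {v : A v = 0} as a list of length-``ncols`` vectors.

    The basis follows the free-column convention: one vector per non-pivot
    column f, with v[f] = 1 and v[p] = -R[i][f] for pivot columns p.
    """
    if not matrix:
        return [[ONE if i == j else ZERO for i in range(ncols)] for j in range(ncols)]
    R, pivots = rref(matrix)
    free = [c for c in range(ncols) if c not in pivots]
    basis = []
    for f in free:
        v = [ZERO] * ncols
        v[f] = ONE
        for i, p in enumerate(pivots):
            v[p] = -R[i][f]
        basis.append(v)
    return basis


def primitive(values: Sequence[Fraction]) -> list[Fraction]:
    """Scale a rational vector to coprime integers, preserving sign."""
    nz = [v for v in values if v != 0]
    if not nz:
        return list(values)
    from math import lcm

    denom = lcm(*(v.denominator for v in nz))
    ints = [v * denom for v in values]
    g = 0
    for v in ints:
        g = gcd(g, int(v))
    return [v / g for v in ints]


def columns(matrix: Matrix, idx: Iterable[int]) -> Matrix:
    """Sub-matrix restricted to the given columns (order preserved)."""
    idx = list(idx)
    return [[row[j] for j in idx] for row in matrix]
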