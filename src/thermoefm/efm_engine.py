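"""Elementary flux mode enumeration via the binary null-space algorithm.

A variant of the double description method: starting from an exact rational
kernel basis of S whose leading rows form an identity block, constraint rows
(reactions) are processed one at a time.  Modes with negative value at the
current row are paired with positive ones to cancel it; a combinatorial
superset test keeps only support-minimal candidates.  Processed rows are
stored as inherited activity bits — once a bit is set in a mode it is set in
every descendant, which is what makes in-loop thermodynamic pruning safe in
the integrated pipeline.

All arithmetic is exact (Fractions normalized to coprime integers), so "is
this entry zero" — the question the superset test hinges on — has an
unambiguous answer at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable

from ._exact import ZERO, columns, nullspace, primitive
from .model_io import KernelBasis, MetabolicModel, SplitMap, kernel


@dataclass(eq=False)
class IntermediateMode:
    """Hybrid binary/numeric column of the DDM tableau.

    ``bits`` is a mask over tableau rows already converted to binary
    (1 = active); ``numeric`` holds exact values for unprocessed rows only
    (zeros omitted).  ``generation`` counts combination depth (diagnostics).
    """

    bits: int
    numeric: dict[int, Fraction]
    generation: int = 0

    def support_mask(self) -> int:
        m = self.bits
        for row in self.numeric:
            m |= 1 << row
        return m


@dataclass(frozen=True)
class EFM:
    """Support-minimal nonnegative steady-state flux vector.

    ``flux`` is indexed by the model's reactions; the smallest positive entry
    is normalized to 1.
    """

    flux: tuple[Fraction, ...]
    support: frozenset[int]

    def support_ids(self, model: MetabolicModel) -> frozenset[str]:
        return frozenset(model.reaction_ids[j] for j in self.support)


@dataclass
class IterationStats:
    row: int  # original reaction index of the pivot
    n_pos: int
    n_zero: int
    n_neg: int
    candidates_generated: int
    candidates_kept: int
    lp_calls: int = 0
    cache_hits: int = 0
    pruned: int = 0


@dataclass
class EnumerationStats:
    iterations: list[IterationStats] = field(default_factory=list)
    final_pruned: int = 0
    final_lp_calls: int = 0

    @property
    def total_candidates(self) -> int:
        return sum(i.candidates_generated for i in self.iterations)

    @property
    def total_kept(self) -> int:
        return sum(i.candidates_kept for i in self.iterations)

    @property
    def total_lp_calls(self) -> int:
        return self.final_lp_calls + sum(i.lp_calls for i in self.iterations)

    @property
    def total_pruned(self) -> int:
        return self.final_pruned + sum(i.pruned for i in self.iterations)


class EnumerationError(RuntimeError):
    """Internal consistency violation: signals an enumeration bug."""


# ---------------------------------------------------------------------------
# tableau construction and iteration
# ---------------------------------------------------------------------------

def init_tableau(basis: KernelBasis) -> list[IntermediateMode]:
    """One mode per kernel column; identity rows enter as processed bits."""
    k = basis.dim
    modes = []
    for j in range(k):
        col = [basis.matrix[i][j] for i in range(basis.n_rows)]
        col = primitive(col)
        numeric = {i: col[i] for i in range(k, basis.n_rows) if col[i] != 0}
        modes.append(IntermediateMode(bits=1 << j, numeric=numeric))
    return modes


def select_next_row(modes: list[IntermediateMode], unprocessed: set[int]) -> int:
    """The unprocessed row minimizing |pos|*|neg|; ties to the smallest index."""
    if not unprocessed:
        raise ValueError("no unprocessed rows left")
    best, best_cost = None, None
    for row in sorted(unprocessed):
        pos = neg = 0
        for m in modes:
            v = m.numeric.get(row, ZERO)
            if v > 0:
                pos += 1
            elif v < 0:
                neg += 1
        cost = pos * neg
        if best_cost is None or cost < best_cost:
            best, best_cost = row, cost
    return best


def _combine(p: IntermediateMode, n: IntermediateMode, row: int) -> IntermediateMode:
    """Nonnegative combination cancelling ``row`` exactly; gcd-normalized."""
    alpha = -n.numeric[row]  # > 0
    beta = p.numeric[row]  # > 0
    keys = set(p.numeric) | set(n.numeric)
    keys.discard(row)
    keys = sorted(keys)
    vals = [alpha * p.numeric.get(i, ZERO) + beta * n.numeric.get(i, ZERO) for i in keys]
    vals = primitive(vals)
    numeric = {i: v for i, v in zip(keys, vals) if v != 0}
    return IntermediateMode(bits=p.bits | n.bits, numeric=numeric,
                            generation=max(p.generation, n.generation) + 1)


def process_row(modes: list[IntermediateMode], row: int) -> tuple[list[IntermediateMode], IterationStats]:
    """One DDM iteration: binarize ``row``.

    Positive and negative modes are pairwise combined; a (p, n) candidate is
    elementary — and kept — iff no other current mode's *binary* support is
    contained in ``bits(p) | bits(n)`` (the combinatorial adjacency test over
    the processed constraints, witnesses drawn from the full current ray set
    including the negative tree).  Negative modes are then discarded
    (irreversibility).
    """
    pos = [m for m in modes if m.numeric.get(row, ZERO) > 0]
    neg = [m for m in modes if m.numeric.get(row, ZERO) < 0]
    zero = [m for m in modes if m.numeric.get(row, ZERO) == 0]

    kept: list[IntermediateMode] = []
    for p in pos:
        for n in neg:
            union = p.bits | n.bits
            adjacent = True
            for w in modes:
                if w is p or w is n:
                    continue
                if w.bits & union == w.bits:
                    adjacent = False
                    break
            if adjacent:
                kept.append(_combine(p, n, row))

    survivors: list[IntermediateMode] = []
    for m in pos:
        numeric = dict(m.numeric)
        numeric.pop(row)
        survivors.append(IntermediateMode(m.bits | (1 << row), numeric, m.generation))
    for m in zero:
        numeric = dict(m.numeric)
        numeric.pop(row, None)
        survivors.append(IntermediateMode(m.bits, numeric, m.generation))
    survivors.extend(kept)
    stats = IterationStats(row=row, n_pos=len(pos), n_zero=len(zero), n_neg=len(neg),
                           candidates_generated=len(pos) * len(neg),
                           candidates_kept=len(kept))
    return survivors, stats


# ---------------------------------------------------------------------------
# full enumeration
# ---------------------------------------------------------------------------

def _run_tableau(basis: KernelBasis,
                 step_hook: Callable | None = None) -> tuple[list[IntermediateMode], EnumerationStats]:
    """Iterate the tableau to full binary form.

    ``step_hook(modes, row, stats_entry)``, if given, is called *before*
    combination with the pivot row and may prune ``modes`` in place (used by
    the thermodynamic pipeline); it returns an optionally filtered mode list.
    """
    modes = init_tableau(basis)
    stats = EnumerationStats()
    unprocessed = set(range(basis.dim, basis.n_rows))
    while unprocessed and modes:
        row = select_next_row(modes, unprocessed)
        entry = IterationStats(row=row, n_pos=0, n_zero=0, n_neg=0,
                               candidates_generated=0, candidates_kept=0)
        if step_hook is not None:
            modes = step_hook(modes, row, entry)
        modes, it = process_row(modes, row)
        it.lp_calls, it.cache_hits, it.pruned = entry.lp_calls, entry.cache_hits, entry.pruned
        stats.iterations.append(it)
        unprocessed.discard(row)
    return modes, stats


def finalize_fluxes(support: Iterable[int], model: MetabolicModel) -> EFM:
    """Flux values of an EFM from its support.

    The nullspace of S restricted to the support columns must be
    1-dimensional with a strictly positive generator; the flux is normalized
    so its smallest positive entry is 1.
    """
    support = sorted(set(support))
    sub = columns(model.S, support)
    basis = nullspace(sub, len(support))
    if len(basis) != 1:
        raise EnumerationError(
            f"support {support} has nullspace dimension {len(basis)}, expected 1")
    gen = basis[0]
    if all(v <= 0 for v in gen):
        gen = [-v for v in gen]
    if any(v <= 0 for v in gen):
        raise EnumerationError(f"support {support} has no strictly positive generator")
    smallest = min(gen)
    gen = [v / smallest for v in gen]
    flux = [ZERO] * model.n_reactions
    for j, v in zip(support, gen):
        flux[j] = v
    return EFM(flux=tuple(flux), support=frozenset(support))


def modes_to_supports(modes: list[IntermediateMode], basis: KernelBasis) -> list[frozenset[int]]:
    """Map fully binary modes back to original reaction index supports."""
    out = []
    for m in modes:
        if m.numeric:
            raise EnumerationError("mode still has numeric entries after completion")
        out.append(frozenset(basis.row_order[i]
                             for i in range(basis.n_rows) if m.bits >> i & 1))
    return out


def enumerate_efms(model: MetabolicModel,
                   basis: KernelBasis | None = None) -> tuple[list[EFM], EnumerationStats]:
    """All elementary flux modes of an irreversible model.

    Deterministic: fixed row-selection tie-breaking and canonical output order
    (sorted by support).
    """
    if any(model.reversible):
        raise ValueError("enumerate_efms expects an irreversible (post-split) model")
    if basis is None:
        basis = kernel(model)
    if basis.dim == 0:
        return [], EnumerationStats()
    modes, stats = _run_tableau(basis)
    supports = modes_to_supports(modes, basis)
    supports = sorted(set(supports), key=lambda s: tuple(sorted(s)))
    efms = [finalize_fluxes(s, model) for s in supports if s]
    return efms, stats


def remove_futile_2cycles(efms: list[EFM], model: MetabolicModel,
                          split_map: SplitMap) -> list[EFM]:
    """Drop EFMs whose support is exactly one forward/backward split pair."""
    pairs = set(split_map.pair_index_sets(model))
    return [e for e in efms if frozenset(e.support) not in pairs]
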