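"""Metabolic model input, validation and structural transforms.

A model is a stoichiometric matrix S (internal metabolites x reactions) over
exact rationals, with per-reaction reversibility and exchange annotations.
External metabolites (boundary species) do not get a row in S — they are kept
as annotations on the exchange reactions that touch them, which is what the
condition-specific sub-model construction needs.

Supported input formats: an SBML core subset (read through cobra) and a
plain-text TSV dialect with columns ``reaction_id``, ``equation``,
``is_exchange`` where equations look like ``A + 2 B -> C`` (``<=>`` marks a
reversible reaction and either side may be empty).  Metabolites that appear
only in exchange reactions are treated as external.
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from ._exact import ZERO, Matrix, as_fraction, nullspace, rank, rref


class ModelFormatError(ValueError):
    """Raised when an input file cannot be parsed into a valid model."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


@dataclass
class MetabolicModel:
    """Stoichiometric model over internal metabolites.

    S is row-major: ``S[i][j]`` is the coefficient of metabolite i in
    reaction j (negative = consumed).  ``ext_stoich[j]`` maps external
    metabolite ids to their coefficients in reaction j; these rows are not
    part of S.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: Matrix
    reversible: list[bool]
    exchange: list[bool]
    ext_stoich: list[dict[str, Fraction]] = field(default_factory=list)

    def __post_init__(self):
        if not self.ext_stoich:
            self.ext_stoich = [{} for _ in self.reaction_ids]

    # -- basic accessors -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def column(self, j: int) -> list[Fraction]:
        return [row[j] for row in self.S]

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def to_float_array(self) -> np.ndarray:
        return np.array([[float(v) for v in row] for row in self.S], dtype=float) \
            if self.S else np.zeros((0, self.n_reactions))

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            list(self.metabolite_ids),
            list(self.reaction_ids),
            [list(r) for r in self.S],
            list(self.reversible),
            list(self.exchange),
            [dict(d) for d in self.ext_stoich],
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(repr((self.metabolite_ids, self.reaction_ids, self.S,
                       self.reversible, self.exchange)).encode())
        return h.hexdigest()[:12]

    # -- validation ------------------------------------------------------
    def validate(self) -> "MetabolicModel":
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            dup = sorted({r for r in self.reaction_ids if self.reaction_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            dup = sorted({m for m in self.metabolite_ids if self.metabolite_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        r = self.n_reactions
        for row in self.S:
            if len(row) != r:
                raise ModelValidationError("ragged stoichiometric matrix")
        # drop metabolites that touch no reaction (invariant: every internal
        # metabolite participates in >=1 reaction after validation)
        keep = [i for i, row in enumerate(self.S) if any(v != 0 for v in row)]
        if len(keep) != self.n_metabolites:
            self.metabolite_ids = [self.metabolite_ids[i] for i in keep]
            self.S = [self.S[i] for i in keep]
        return self

    # -- exchange annotations --------------------------------------------
    def exchange_nutrient(self, j: int) -> str | None:
        """The transported species of exchange reaction j.

        The external metabolite if one is annotated, otherwise the single
        internal metabolite of a bare ``-> A`` style boundary reaction.
        """
        if not self.exchange[j]:
            return None
        if self.ext_stoich[j]:
            return next(iter(self.ext_stoich[j]))
        nz = [i for i, row in enumerate(self.S) if row[j] != 0]
        return self.metabolite_ids[nz[0]] if len(nz) == 1 else None

    def is_uptake(self, j: int) -> bool:
        """True if the forward direction of exchange j imports its nutrient."""
        if self.ext_stoich[j]:
            coef = next(iter(self.ext_stoich[j].values()))
            return coef < 0  # external species consumed -> import
        col = self.column(j)
        return sum(col) > 0  # net production of internal mass -> import


@dataclass
class SplitMap:
    """Bookkeeping of reversible-reaction splitting (order preserved)."""

    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def backward_ids(self) -> set[str]:
        return {b for _, b in self.pairs.values()}

    def pair_index_sets(self, model: MetabolicModel) -> list[frozenset[int]]:
        """Index pairs {fwd, bwd} in a given (split) model."""
        out = []
        for f, b in self.pairs.values():
            if f in model.reaction_ids and b in model.reaction_ids:
                out.append(frozenset({model.reaction_index(f), model.reaction_index(b)}))
        return out


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?(\S+)$")


def _parse_side(text: str) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ModelFormatError(f"empty term in equation side {text!r}")
        m = _TERM.match(term)
        if m is None:
            raise ModelFormatError(f"cannot parse term {term!r}")
        coef = as_fraction(m.group(1)) if m.group(1) else Fraction(1)
        name = m.group(2)
        out[name] = out.get(name, ZERO) + coef
    return out


def _parse_equation(eq: str) -> tuple[dict[str, Fraction], bool]:
    """Return (net stoichiometry, reversible)."""
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>", 1)
        reversible = True
    elif "->" in eq:
        lhs, rhs = eq.split("->", 1)
        reversible = False
    else:
        raise ModelFormatError(f"equation {eq!r} has no '->' or '<=>' arrow")
    stoich: dict[str, Fraction] = {}
    for name, c in _parse_side(lhs).items():
        stoich[name] = stoich.get(name, ZERO) - c
    for name, c in _parse_side(rhs).items():
        stoich[name] = stoich.get(name, ZERO) + c
    return {k: v for k, v in stoich.items() if v != 0}, reversible


_TRUE = {"1", "true", "yes", "y"}


def _read_table(path: Path) -> MetabolicModel:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"reaction_id", "equation", "is_exchange"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ModelFormatError(
                f"model table needs columns {sorted(required)}, got {reader.fieldnames}")
        rows = list(reader)
    rids, stoichs, revs, exch = [], [], [], []
    for row in rows:
        rid = row["reaction_id"].strip()
        if not rid:
            raise ModelFormatError("empty reaction_id")
        stoich, reversible = _parse_equation(row["equation"])
        rids.append(rid)
        stoichs.append(stoich)
        revs.append(reversible)
        exch.append(row["is_exchange"].strip().lower() in _TRUE)
    if len(set(rids)) != len(rids):
        dup = sorted({r for r in rids if rids.count(r) > 1})
        raise ModelValidationError(f"duplicate reaction ids: {dup}")
    # metabolites used only by exchange reactions are external
    used_internal: set[str] = set()
    for st, ex in zip(stoichs, exch):
        if not ex:
            used_internal.update(st)
    # internal metabolites in first-appearance order
    order: list[str] = []
    for st in stoichs:
        for m in st:
            if m in used_internal and m not in order:
                order.append(m)
    mids = order
    midx = {m: i for i, m in enumerate(mids)}
    S: Matrix = [[ZERO] * len(rids) for _ in mids]
    ext: list[dict[str, Fraction]] = []
    for j, st in enumerate(stoichs):
        e = {}
        for m, c in st.items():
            if m in midx:
                S[midx[m]][j] = c
            else:
                e[m] = c
        ext.append(e)
    return MetabolicModel(mids, rids, S, revs, exch, ext).validate()


def _sbml_reaction_ids(path: Path) -> set[str]:
    """Reaction ids literally present in the file (cobra adds boundary
    exchanges for species with boundaryCondition; those are not ours)."""
    import gzip

    from lxml import etree

    if str(path).endswith(".gz"):
        with gzip.open(path) as fh:
            tree = etree.parse(fh)
    else:
        tree = etree.parse(str(path))
    return {r.get("id") for r in tree.iter("{*}reaction") if r.get("id")}


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
        declared = _sbml_reaction_ids(path)
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise ModelFormatError(f"SBML parse failure for {path}: {exc}") from exc
    # cobra strips the SBML "R_" id prefix; match either form
    added = [r for r in cm.reactions
             if r.id not in declared and "R_" + r.id not in declared]
    if added:
        cm.remove_reactions(added)
    external = {m.id for m in cm.metabolites
                if (m.compartment or "").lower() in {"external", "extra_organism", "b"}}
    mids = [m.id for m in cm.metabolites if m.id not in external]
    midx = {m: i for i, m in enumerate(mids)}
    rids = [r.id for r in cm.reactions]
    S: Matrix = [[ZERO] * len(rids) for _ in mids]
    revs, exch, ext = [], [], []
    boundary_ids = {r.id for r in cm.boundary}
    for j, r in enumerate(cm.reactions):
        e: dict[str, Fraction] = {}
        for met, coef in r.metabolites.items():
            c = as_fraction(float(coef))
            if met.id in midx:
                S[midx[met.id]][j] = c
            else:
                e[met.id] = c
        ext.append(e)
        revs.append(bool(r.reversibility))
        exch.append(r.id in boundary_ids or bool(e))
    return MetabolicModel(mids, rids, S, revs, exch, ext).validate()


def read_model(path, fmt: str | None = None) -> MetabolicModel:
    """Read a model from SBML or the TSV table dialect.

    ``fmt`` is ``"sbml"`` or ``"table"``; by default it is inferred from the
    file extension (.xml/.sbml -> sbml, everything else -> table).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        name = path.name.lower().removesuffix(".gz")
        fmt = "sbml" if name.endswith((".xml", ".sbml")) else "table"
    if fmt == "sbml":
        return _read_sbml(path)
    if fmt == "table":
        return _read_table(path)
    raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def split_reversible(model: MetabolicModel) -> tuple[MetabolicModel, SplitMap]:
    """Split every reversible reaction into forward + backward columns.

    The backward column is the exact negation of the forward one and is
    appended directly after it; both are irreversible in the result.
    """
    mids = list(model.metabolite_ids)
    rids, revs, exch, ext = [], [], [], []
    cols: list[list[Fraction]] = []
    pairs: dict[str, tuple[str, str]] = {}
    for j, rid in enumerate(model.reaction_ids):
        col = model.column(j)
        rids.append(rid)
        cols.append(col)
        revs.append(False)
        exch.append(model.exchange[j])
        ext.append(dict(model.ext_stoich[j]))
        if model.reversible[j]:
            bid = rid + "_rev"
            if bid in model.reaction_ids:
                raise ModelValidationError(f"cannot split {rid}: id {bid} already used")
            rids.append(bid)
            cols.append([-v for v in col])
            revs.append(False)
            exch.append(model.exchange[j])
            ext.append({k: -v for k, v in model.ext_stoich[j].items()})
            pairs[rid] = (rid, bid)
    S = [[cols[j][i] for j in range(len(cols))] for i in range(len(mids))]
    return MetabolicModel(mids, rids, S, revs, exch, ext).validate(), SplitMap(pairs)


def merge_split_fluxes(flux: dict[str, Fraction], split_map: SplitMap) -> dict[str, Fraction]:
    """Collapse forward/backward flux pairs into one signed flux per original id."""
    out = dict(flux)
    for rid, (f, b) in split_map.pairs.items():
        out[rid] = out.pop(f, ZERO) - out.pop(b, ZERO)
    return out


def build_condition_model(model: MetabolicModel, medium: set[str]) -> MetabolicModel:
    """Condition-specific sub-model: keep uptake only for medium nutrients.

    Uptake reactions (or the uptake direction of reversible exchanges) for
    nutrients outside ``medium`` are removed; secretion is always retained.
    """
    nutrients = {model.exchange_nutrient(j) for j in range(model.n_reactions)
                 if model.exchange[j]}
    nutrients.discard(None)
    unknown = set(medium) - nutrients
    if unknown:
        raise ValueError(
            f"unknown medium nutrients {sorted(unknown)}; "
            f"exchangeable nutrients are {sorted(nutrients)}")
    out = model.copy()
    keep = []
    for j in range(out.n_reactions):
        nut = out.exchange_nutrient(j)
        if not out.exchange[j] or nut is None or nut in medium:
            keep.append(j)
            continue
        if out.reversible[j]:
            # disable the uptake direction only: orient the column so that the
            # (now irreversible) forward direction secretes
            if out.is_uptake(j):
                for row in out.S:
                    row[j] = -row[j]
                out.ext_stoich[j] = {k: -v for k, v in out.ext_stoich[j].items()}
            out.reversible[j] = False
            keep.append(j)
        elif out.is_uptake(j):
            continue  # irreversible uptake of an absent nutrient: drop
        else:
            keep.append(j)  # secretion retained
    out.reaction_ids = [out.reaction_ids[j] for j in keep]
    out.S = [[row[j] for j in keep] for row in out.S]
    out.reversible = [out.reversible[j] for j in keep]
    out.exchange = [out.exchange[j] for j in keep]
    out.ext_stoich = [out.ext_stoich[j] for j in keep]
    return out.validate()


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------

@dataclass
class CompressedModel:
    """Result of structural compression of an irreversible model.

    ``reaction_map`` sends each compressed reaction id to the original
    reactions it aggregates, with exact rational multipliers;
    ``duplicate_classes`` records removed duplicate columns (kept id ->
    [(removed id, scale)] with column_removed = scale * column_kept).
    """

    model: MetabolicModel
    reaction_map: dict[str, list[tuple[str, Fraction]]]
    removed_reactions: list[tuple[str, str]]
    duplicate_classes: dict[str, list[tuple[str, Fraction]]] = field(default_factory=dict)

    def expand_support(self, support_ids: set[str] | frozenset[str]) -> frozenset[str]:
        """Original reactions active when the given compressed reactions are."""
        out: set[str] = set()
        for rid in support_ids:
            out.update(orig for orig, _ in self.reaction_map[rid])
        return frozenset(out)

    def decompress_flux(self, flux: dict[str, Fraction]) -> dict[str, Fraction]:
        out: dict[str, Fraction] = {}
        for rid, v in flux.items():
            for orig, mult in self.reaction_map[rid]:
                out[orig] = out.get(orig, ZERO) + v * mult
        return {k: v for k, v in out.items() if v != 0}


def _blocked_reactions(model: MetabolicModel) -> set[int]:
    """Reactions that can carry no nonnegative steady-state flux."""
    from scipy.optimize import linprog

    r = model.n_reactions
    blocked: set[int] = set()
    basis = nullspace(model.S, r)
    for j in range(r):
        if all(v[j] == 0 for v in basis):
            blocked.add(j)  # zero in every kernel vector: structurally blocked
    A = model.to_float_array()
    for j in range(r):
        if j in blocked:
            continue
        c = np.zeros(r)
        c[j] = -1.0
        res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]),
                      bounds=[(0.0, 1.0)] * r, method="highs")
        if res.status != 0 or -res.fun < 1e-9:
            blocked.add(j)  # sign-blocked: only reversible use possible
    return blocked


def compress(model: MetabolicModel) -> CompressedModel:
    """Structurally compress an irreversible model.

    Removes blocked reactions, merges uniquely coupled reaction pairs
    (a metabolite with exactly one producer and one consumer forces a fixed
    flux ratio), and collapses positively proportional duplicate columns.
    The reaction map makes decompression exact.
    """
    if any(model.reversible):
        raise ValueError("compress expects an irreversible (post-split) model")
    cur = model.copy()
    rmap: dict[str, list[tuple[str, Fraction]]] = {
        rid: [(rid, Fraction(1))] for rid in cur.reaction_ids}
    removed: list[tuple[str, str]] = []

    def drop_reactions(idx: set[int], reason: str):
        for j in sorted(idx):
            removed.append((cur.reaction_ids[j], reason))
            rmap.pop(cur.reaction_ids[j], None)
        keep = [j for j in range(cur.n_reactions) if j not in idx]
        cur.reaction_ids = [cur.reaction_ids[j] for j in keep]
        cur.S = [[row[j] for j in keep] for row in cur.S]
        cur.reversible = [cur.reversible[j] for j in keep]
        cur.exchange = [cur.exchange[j] for j in keep]
        cur.ext_stoich = [cur.ext_stoich[j] for j in keep]

    def drop_zero_rows():
        keep = [i for i, row in enumerate(cur.S) if any(v != 0 for v in row)]
        cur.metabolite_ids = [cur.metabolite_ids[i] for i in keep]
        cur.S = [cur.S[i] for i in keep]

    changed = True
    while changed:
        changed = False
        blocked = _blocked_reactions(cur)
        if blocked:
            drop_reactions(blocked, "blocked")
            drop_zero_rows()
            changed = True
            continue
        # unique producer / unique consumer merge
        for i in range(cur.n_metabolites):
            prod = [j for j in range(cur.n_reactions) if cur.S[i][j] > 0]
            cons = [j for j in range(cur.n_reactions) if cur.S[i][j] < 0]
            if len(prod) == 1 and len(cons) == 1 and prod[0] != cons[0]:
                p, c = prod[0], cons[0]
                a, b = cur.S[i][p], -cur.S[i][c]  # both positive
                # new column = b*col_p + a*col_c (metabolite i cancels)
                for row in cur.S:
                    row[p] = b * row[p] + a * row[c]
                new_ext = {}
                for k, v in cur.ext_stoich[p].items():
                    new_ext[k] = new_ext.get(k, ZERO) + b * v
                for k, v in cur.ext_stoich[c].items():
                    new_ext[k] = new_ext.get(k, ZERO) + a * v
                cur.ext_stoich[p] = {k: v for k, v in new_ext.items() if v != 0}
                cur.exchange[p] = cur.exchange[p] or cur.exchange[c]
                pid, cid = cur.reaction_ids[p], cur.reaction_ids[c]
                rmap[pid] = ([(o, b * mlt) for o, mlt in rmap[pid]]
                             + [(o, a * mlt) for o, mlt in rmap[cid]])
                removed.append((cid, f"merged into {pid}"))
                rmap.pop(cid)
                keep = [j for j in range(cur.n_reactions) if j != c]
                cur.reaction_ids = [cur.reaction_ids[j] for j in keep]
                cur.S = [[row[j] for j in keep] for row in cur.S]
                cur.reversible = [cur.reversible[j] for j in keep]
                cur.exchange = [cur.exchange[j] for j in keep]
                cur.ext_stoich = [cur.ext_stoich[j] for j in keep]
                drop_zero_rows()
                changed = True
                break

    # duplicate columns (equal up to a positive scale); zero columns excluded
    dup_classes: dict[str, list[tuple[str, Fraction]]] = {}
    to_drop: set[int] = set()
    for j in range(cur.n_reactions):
        if j in to_drop:
            continue
        cj = cur.column(j)
        if all(v == 0 for v in cj):
            continue
        for k in range(j + 1, cur.n_reactions):
            if k in to_drop:
                continue
            ck = cur.column(k)
            pivot = next((i for i, v in enumerate(cj) if v != 0))
            if ck[pivot] == 0:
                continue
            scale = ck[pivot] / cj[pivot]
            if scale > 0 and all(ck[i] == scale * cj[i] for i in range(len(cj))):
                dup_classes.setdefault(cur.reaction_ids[j], []).append(
                    (cur.reaction_ids[k], scale))
                to_drop.add(k)
    if to_drop:
        # move duplicates' maps out before dropping (they stay decompressible)
        dup_maps = {cur.reaction_ids[k]: rmap[cur.reaction_ids[k]] for k in to_drop}
        drop_reactions(to_drop, "duplicate")
        rmap.update(dup_maps)  # retained for duplicate expansion
    cur.validate()
    comp = CompressedModel(cur, rmap, removed, dup_classes)
    # restrict reaction_map to surviving + duplicate-class reactions
    surviving = set(cur.reaction_ids) | {rid for cls in dup_classes.values()
                                         for rid, _ in cls}
    comp.reaction_map = {k: v for k, v in rmap.items() if k in surviving}
    return comp


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

@dataclass
class KernelBasis:
    """Nullspace basis with the identity block leading.

    ``matrix`` has one row per reaction in the permuted order ``row_order``
    (original reaction indices); the first ``dim`` rows form an identity.
    """

    matrix: Matrix
    row_order: list[int]

    @property
    def dim(self) -> int:
        return len(self.matrix[0]) if self.matrix and self.matrix[0] else 0

    @property
    def n_rows(self) -> int:
        return len(self.matrix)


def kernel(model: MetabolicModel) -> KernelBasis:
    """Exact rational kernel of S, row-permuted so an identity block leads.

    Free (non-pivot) columns of the RREF of S index the identity rows; this is
    the starting tableau convention of the binary null-space algorithm.
    """
    r = model.n_reactions
    if r == 0:
        return KernelBasis([], [])
    if not model.S:
        R, pivots = [], []
    else:
        R, pivots = rref(model.S)
    free = [c for c in range(r) if c not in pivots]
    k = len(free)
    order = free + list(pivots)
    K: Matrix = []
    for pos, orig in enumerate(order):
        if pos < k:
            K.append([Fraction(1) if j == pos else ZERO for j in range(k)])
        else:
            i = pivots.index(orig)
            K.append([-R[i][free[j]] for j in range(k)])
    if k == 0:
        K = [[] for _ in order]
    return KernelBasis(K, order)


def matrix_rank(model: MetabolicModel) -> int:
    """Exact rank of the stoichiometric matrix."""
    return rank(model.S)
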