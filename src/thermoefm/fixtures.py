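"""Synthetic models, thermodynamic fixtures and independent oracles.

Everything the test suite needs without external downloads: seeded random
stoichiometric models with guaranteed nontrivial kernels, a brute-force EFM
oracle (exhaustive support enumeration with exact nullspace checks), a
grid-search falsifier for the NET LP, and an inverse generator that
rejection-samples thermodynamic data until prescribed reaction patterns are
(in)feasible — the construction behind the glycolysis/gluconeogenesis motif,
where three consecutive reactions are pairwise feasible in both directions
but jointly feasible in only one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._exact import ZERO, columns, nullspace, rank
from .efm_engine import EFM, finalize_fluxes
from .model_io import MetabolicModel
from .thermo import MetaboliteThermo, ThermoData, net_feasible, reaction_constraint

MAX_ORACLE_REACTIONS = 18  # 2^r support subsets must stay desk-scale


@dataclass
class FixtureSpec:
    """Parameters of a random model draw."""

    m: int = 4
    r: int = 8
    density: float = 0.5
    n_reversible: int = 0
    seed: int = 0
    planted_infeasible: list[frozenset[int]] = field(default_factory=list)
    planted_feasible: list[frozenset[int]] = field(default_factory=list)


def gen_random_model(spec: FixtureSpec) -> MetabolicModel:
    """Seeded random model with a nontrivial nullspace.

    Coefficients are drawn from {-2,-1,1,2}; the first column is an uptake
    exchange (+1 into metabolite 0) and the last a secretion exchange (-1 out
    of the last metabolite), so every fixture has a boundary.  Reversibility
    flags are assigned to the first ``n_reversible`` interior reactions.
    """
    if spec.r > MAX_ORACLE_REACTIONS:
        raise ValueError(f"r must be <= {MAX_ORACLE_REACTIONS} for oracle tractability")
    if spec.r < 3 or spec.m < 2:
        raise ValueError("need at least 2 metabolites and 3 reactions")
    rng = np.random.default_rng(spec.seed)
    values = [-2, -1, 1, 2]
    for _ in range(100):
        S = [[ZERO] * spec.r for _ in range(spec.m)]
        S[0][0] = Fraction(1)  # uptake
        S[spec.m - 1][spec.r - 1] = Fraction(-1)  # secretion
        for j in range(1, spec.r - 1):
            for i in range(spec.m):
                if rng.random() < spec.density:
                    S[i][j] = Fraction(int(rng.choice(values)))
            if all(S[i][j] == 0 for i in range(spec.m)):
                S[int(rng.integers(spec.m))][j] = Fraction(int(rng.choice(values)))
        ok_rows = all(any(row[j] != 0 for j in range(spec.r)) for row in S)
        if not ok_rows:
            continue
        if rank(S) >= spec.r:
            continue
        mids = [f"M{i}" for i in range(spec.m)]
        rids = [f"R{j}" for j in range(spec.r)]
        reversible = [False] * spec.r
        for j in range(1, min(1 + spec.n_reversible, spec.r - 1)):
            reversible[j] = True
        exchange = [False] * spec.r
        exchange[0] = exchange[spec.r - 1] = True
        ext = [{} for _ in rids]
        ext[0] = {"M0_ext": Fraction(-1)}
        ext[spec.r - 1] = {f"M{spec.m - 1}_ext": Fraction(1)}
        return MetabolicModel(mids, rids, S, reversible, exchange, ext).validate()
    raise RuntimeError("could not generate a model with nontrivial nullspace in 100 attempts")


# ---------------------------------------------------------------------------
# brute-force EFM oracle
# ---------------------------------------------------------------------------

def brute_force_efms(model: MetabolicModel) -> list[EFM]:
    """All EFMs by exhaustive support enumeration (exact arithmetic).

    A support T qualifies iff the nullspace of S restricted to T is
    1-dimensional with a strictly positive generator on T, and no smaller
    accepted support is contained in T.  Independent of the double
    description engine by construction.
    """
    r = model.n_reactions
    if r > MAX_ORACLE_REACTIONS:
        raise ValueError(f"oracle limited to r <= {MAX_ORACLE_REACTIONS}")
    if any(model.reversible):
        raise ValueError("oracle expects an irreversible (post-split) model")
    accepted: list[frozenset[int]] = []
    efms: list[EFM] = []
    idx = list(range(r))
    for size in range(1, r + 1):
        for combo in itertools.combinations(idx, size):
            T = frozenset(combo)
            if any(a < T for a in accepted):
                continue
            basis = nullspace(columns(model.S, combo), size)
            if len(basis) != 1:
                continue
            gen = basis[0]
            if all(v <= 0 for v in gen):
                gen = [-v for v in gen]
            if any(v <= 0 for v in gen):
                continue
            accepted.append(T)
            efms.append(finalize_fluxes(T, model))
    efms.sort(key=lambda e: tuple(sorted(e.support)))
    return efms


# ---------------------------------------------------------------------------
# grid-search NET falsifier
# ---------------------------------------------------------------------------

def grid_net_oracle(pattern, model: MetabolicModel, thermo: ThermoData,
                    points_per_dim: int = 11) -> bool:
    """Exhaustive grid check of simultaneous strict drG negativity.

    True iff some grid point in log-concentration space satisfies every
    constraint strictly.  One-sided by design: an LP-infeasible pattern must
    yield False at every resolution; an LP-feasible one may need a finer
    grid.  Limited to 4 free metabolite variables.
    """
    cons = {}
    for i in sorted(frozenset(pattern)):
        c = reaction_constraint(i, model, thermo)
        if c is not None:
            cons[i] = c
    if not cons:
        return True
    mets = sorted({m for c in cons.values() for m in c.coeffs})
    if len(mets) > 4:
        raise ValueError("grid oracle limited to <= 4 free metabolites")
    import math
    axes = []
    for m in mets:
        lo, hi = thermo.bounds(model.metabolite_ids[m])
        axes.append(np.linspace(math.log(lo / thermo.c0), math.log(hi / thermo.c0),
                                points_per_dim))
    mpos = {m: k for k, m in enumerate(mets)}
    for point in itertools.product(*axes):
        ok = True
        for c in cons.values():
            drg = c.const + sum(v * point[mpos[m]] for m, v in c.coeffs.items())
            if not drg < -thermo.epsilon:
                ok = False
                break
        if ok:
            return True
    return False


# ---------------------------------------------------------------------------
# inverse thermo-fixture generator
# ---------------------------------------------------------------------------

def gen_thermo_fixture(model: MetabolicModel,
                       planted_infeasible=(), planted_feasible=(),
                       seed: int = 0, max_tries: int = 10000,
                       **thermo_kwargs) -> ThermoData:
    """Rejection-sample thermodynamic data with prescribed (in)feasibilities.

    Draws formation energies and concentration bounds until every planted
    infeasible pattern is LP-infeasible with all its proper subsets feasible,
    and every planted feasible pattern is feasible.  Seeded and reproducible.
    """
    planted_infeasible = [frozenset(p) for p in planted_infeasible]
    planted_feasible = [frozenset(p) for p in planted_feasible]
    for p in planted_feasible:
        for q in planted_infeasible:
            if q <= p:
                raise ValueError(
                    f"planted feasible pattern {sorted(p)} contains planted "
                    f"infeasible pattern {sorted(q)}")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        entries = {}
        for mid in model.metabolite_ids:
            dfg = float(rng.uniform(-60.0, 20.0))
            lo_exp = float(rng.uniform(-6.0, -3.5))
            width = float(rng.uniform(0.4, 2.0))
            entries[mid] = MetaboliteThermo(dfg, 10.0 ** lo_exp,
                                            10.0 ** (lo_exp + width))
        thermo = ThermoData(entries, **thermo_kwargs)
        ok = True
        for p in planted_infeasible:
            if net_feasible(p, model, thermo).feasible:
                ok = False
                break
            for k in range(1, len(p)):
                for sub in itertools.combinations(sorted(p), k):
                    if not net_feasible(frozenset(sub), model, thermo).feasible:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            for p in planted_feasible:
                if not net_feasible(p, model, thermo).feasible:
                    ok = False
                    break
        if ok:
            return thermo
    raise RuntimeError(
        f"no thermodynamic fixture found in {max_tries} draws; "
        "loosen the planted patterns")


# ---------------------------------------------------------------------------
# named toy models
# ---------------------------------------------------------------------------

def chain_model(n: int = 3) -> MetabolicModel:
    """Linear chain: uptake -> M0 -> M1 -> ... -> secretion (n+? reactions).

    ``n`` interior conversions give n+2 reactions and n+1 metabolites; the
    whole network carries exactly one EFM.
    """
    mids = [f"M{i}" for i in range(n + 1)]
    rids = ["R_up"] + [f"R{i}" for i in range(1, n + 1)] + ["R_sec"]
    r = len(rids)
    S = [[ZERO] * r for _ in mids]
    S[0][0] = Fraction(1)
    for j in range(1, n + 1):
        S[j - 1][j] = Fraction(-1)
        S[j][j] = Fraction(1)
    S[n][r - 1] = Fraction(-1)
    exchange = [False] * r
    exchange[0] = exchange[r - 1] = True
    ext = [{} for _ in rids]
    ext[0] = {"M0_ext": Fraction(-1)}
    ext[r - 1] = {f"M{n}_ext": Fraction(1)}
    return MetabolicModel(mids, rids, S, [False] * r, exchange, ext).validate()


def diamond_model() -> MetabolicModel:
    """Uptake of A, two parallel routes A->B, and secretion of B: 2 EFMs."""
    mids = ["A", "B"]
    rids = ["R_up", "R_left", "R_right", "R_sec"]
    S = [
        [Fraction(1), Fraction(-1), Fraction(-1), ZERO],
        [ZERO, Fraction(1), Fraction(1), Fraction(-1)],
    ]
    exchange = [True, False, False, True]
    ext = [{"A_ext": Fraction(-1)}, {}, {}, {"B_ext": Fraction(1)}]
    return MetabolicModel(mids, rids, S, [False] * 4, exchange, ext).validate()


def directional_chain_motif():
    """Hand-constructed pathway-context motif on a reversible 3-step chain.

    All formation energies are zero; the feasibility geometry is set purely
    by concentration windows on the chain metabolites M0..M3 (log-bounds
    [-5,-4.5], [-6,-2], [-6,-2], [-4.4,-3.5]).  Summing the three forward
    constraints forces ln c_M3 <= ln c_M0, impossible since the M3 window
    lies strictly above the M0 window — the forward triple is infeasible
    while each proper subset, and the entire backward triple, is feasible.

    Returns (split_model, forward_triple, backward_triple, thermo).
    """
    import math

    from .thermo import MetaboliteThermo, ThermoData

    model = chain_model(3)
    for j in (1, 2, 3):
        model.reversible[j] = True
    from .model_io import split_reversible
    split, _ = split_reversible(model)
    fwd = frozenset(split.reaction_index(f"R{i}") for i in (1, 2, 3))
    bwd = frozenset(split.reaction_index(f"R{i}_rev") for i in (1, 2, 3))
    bounds = {"M0": (-5.0, -4.5), "M1": (-6.0, -2.0),
              "M2": (-6.0, -2.0), "M3": (-4.4, -3.5)}
    thermo = ThermoData({mid: MetaboliteThermo(0.0, math.exp(lo), math.exp(hi))
                         for mid, (lo, hi) in bounds.items()})
    return split, fwd, bwd, thermo


def reversible_pair_model() -> MetabolicModel:
    """Uptake -> A <-> B -> secretion; the split model has a futile 2-cycle."""
    mids = ["A", "B"]
    rids = ["R_up", "R_ab", "R_sec"]
    S = [
        [Fraction(1), Fraction(-1), ZERO],
        [ZERO, Fraction(1), Fraction(-1)],
    ]
    exchange = [True, False, True]
    ext = [{"A_ext": Fraction(-1)}, {}, {"B_ext": Fraction(1)}]
    return MetabolicModel(mids, rids, S, [False, True, False], exchange, ext).validate()
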