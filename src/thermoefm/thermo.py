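"""Network-embedded thermodynamics (NET) over metabolite concentration ranges.

The second law constrains every reaction that carries flux to a negative Gibbs
reaction energy,

    drG_i = sum_j S_ji * (dfG'0_j + R T ln(c_j / c0)) < 0 ,

with dfG'0 the transformed standard Gibbs energy of formation (pH- and
ionic-strength-corrected) and c_j bounded by measured (or conservative
default) concentration ranges.  Whether a whole set of reactions — the support
of a flux mode — can satisfy all of these simultaneously is a linear
feasibility problem in x_j = ln(c_j/c0).  No objective is needed: any feasible
point certifies the pattern.

Conventions used throughout:

* water and protons carry no concentration variable (their activity is fixed;
  pH enters through the Legendre transform of dfG0),
* reactions touching an uncharacterized metabolite, and exchange/boundary
  reactions, are skipped — missing data can only reduce pruning, never create
  a false infeasibility,
* strict negativity is approximated by ``<= -epsilon`` (default epsilon 0);
  the forward+backward pair of a split reversible reaction, whose summed
  constraints force drG = 0, is special-cased infeasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import MetabolicModel

R_GAS = 8.314e-3  # kJ / (mol K)
DEFAULT_T = 310.15  # K (37 C)
# extended Debye-Hueckel constants, Alberty convention
DH_ALPHA = 2.91482  # kJ mol^-1 M^-1/2
DH_B = 1.6  # M^-1/2

DEFAULT_EXCLUDED = frozenset({"h", "h+", "h2o", "water", "proton"})


class LPSolverError(RuntimeError):
    """LP solver failed for a reason other than proven infeasibility."""


class _LPStats:
    """Process-wide count of actual LP solver invocations (diagnostics)."""

    calls = 0


LP_STATS = _LPStats()


def transform_dfg0(dfg0: float, n_h: float, z: float, ph: float,
                   ionic_strength: float, temperature: float = DEFAULT_T) -> float:
    """Legendre transform of a standard formation energy to pH/ionic-strength
    corrected form (kJ/mol).

    dfG'0 = dfG0 + n_H R T ln(10) pH - alpha (z^2 - n_H) sqrt(I)/(1 + B sqrt(I))
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be nonnegative")
    sqrt_i = math.sqrt(ionic_strength)
    ph_term = n_h * R_GAS * temperature * math.log(10.0) * ph
    dh_term = DH_ALPHA * (z * z - n_h) * sqrt_i / (1.0 + DH_B * sqrt_i)
    return dfg0 + ph_term - dh_term


@dataclass
class MetaboliteThermo:
    dfg0_prime: float | None = None  # kJ/mol, None = uncharacterized
    c_min: float | None = None  # mol/L
    c_max: float | None = None


@dataclass
class ThermoData:
    """Per-metabolite thermodynamic data plus global conditions."""

    entries: dict[str, MetaboliteThermo] = field(default_factory=dict)
    temperature: float = DEFAULT_T  # K
    ph: float = 7.0
    ionic_strength: float = 0.15  # mol/L, applied only to raw dfG0 input
    epsilon: float = 0.0  # kJ/mol feasibility margin
    c0: float = 1.0  # standard concentration, mol/L
    default_c_min: float = 1e-9  # conservative bounds for unmeasured metabolites
    default_c_max: float = 0.1
    excluded: frozenset[str] = DEFAULT_EXCLUDED

    def __post_init__(self):
        self.excluded = frozenset(s.lower() for s in self.excluded)
        for mid, e in self.entries.items():
            lo, hi = self.bounds(mid)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid concentration bounds for {mid}: ({lo}, {hi})")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")

    @property
    def rt(self) -> float:
        return R_GAS * self.temperature

    def is_excluded(self, met_id: str) -> bool:
        """Water/protons etc.: fixed activity, no concentration variable.

        Matching strips a trailing compartment suffix (``h_c`` -> ``h``).
        """
        low = met_id.lower()
        if low in self.excluded:
            return True
        base = low.rsplit("_", 1)[0] if "_" in low else low
        return base in self.excluded

    def dfg0_prime(self, met_id: str) -> float | None:
        e = self.entries.get(met_id)
        return e.dfg0_prime if e else None

    def bounds(self, met_id: str) -> tuple[float, float]:
        e = self.entries.get(met_id)
        lo = e.c_min if e and e.c_min is not None else self.default_c_min
        hi = e.c_max if e and e.c_max is not None else self.default_c_max
        return lo, hi

    def copy(self) -> "ThermoData":
        return ThermoData(
            {k: MetaboliteThermo(v.dfg0_prime, v.c_min, v.c_max)
             for k, v in self.entries.items()},
            self.temperature, self.ph, self.ionic_strength, self.epsilon,
            self.c0, self.default_c_min, self.default_c_max, self.excluded)

    def has_data(self) -> bool:
        return any(e.dfg0_prime is not None for e in self.entries.values())


def empty_thermo(**kwargs) -> ThermoData:
    """ThermoData with no characterized metabolites (no constraint is ever emitted)."""
    return ThermoData({}, **kwargs)


def load_thermo(path, **global_kwargs) -> ThermoData:
    """Read a thermodynamics TSV.

    Transformed dialect: ``metabolite_id, dfG0_prime_kJ_mol, c_min_M, c_max_M``
    (energy may be empty = uncharacterized).  Raw dialect:
    ``metabolite_id, dfG0_kJ_mol, n_H, charge`` plus optional bound columns;
    the pH/ionic-strength transform is applied with the global conditions.
    """
    df = pd.read_csv(Path(path), sep="\t")
    cols = set(df.columns)
    td = ThermoData({}, **global_kwargs)
    entries: dict[str, MetaboliteThermo] = {}
    if "dfG0_prime_kJ_mol" in cols:
        for _, row in df.iterrows():
            g = row["dfG0_prime_kJ_mol"]
            entries[str(row["metabolite_id"])] = MetaboliteThermo(
                None if pd.isna(g) else float(g),
                None if "c_min_M" not in cols or pd.isna(row.get("c_min_M")) else float(row["c_min_M"]),
                None if "c_max_M" not in cols or pd.isna(row.get("c_max_M")) else float(row["c_max_M"]),
            )
    elif "dfG0_kJ_mol" in cols:
        for _, row in df.iterrows():
            g = row["dfG0_kJ_mol"]
            if pd.isna(g):
                gp = None
            else:
                gp = transform_dfg0(float(g), float(row["n_H"]), float(row["charge"]),
                                    td.ph, td.ionic_strength, td.temperature)
            entries[str(row["metabolite_id"])] = MetaboliteThermo(
                gp,
                None if "c_min_M" not in cols or pd.isna(row.get("c_min_M")) else float(row["c_min_M"]),
                None if "c_max_M" not in cols or pd.isna(row.get("c_max_M")) else float(row["c_max_M"]),
            )
    else:
        raise ValueError(
            "thermo table needs either dfG0_prime_kJ_mol or dfG0_kJ_mol/n_H/charge columns")
    td.entries = entries
    td.__post_init__()
    return td


# ---------------------------------------------------------------------------
# patterns and results
# ---------------------------------------------------------------------------

SupportPattern = frozenset  # of reaction indices in a (post-split) model


@dataclass
class NetResult:
    feasible: bool
    witness: dict[str, float] | None  # metabolite id -> ln(c/c0)
    checked_reactions: frozenset[int]
    skipped_reactions: frozenset[int]


@dataclass(frozen=True)
class InfeasiblePattern:
    reactions: frozenset[int]
    minimal: bool = False


# ---------------------------------------------------------------------------
# constraint construction
# ---------------------------------------------------------------------------

@dataclass
class _Constraint:
    const: float  # sum_j S_ji dfG'0_j  (kJ/mol)
    coeffs: dict[int, float]  # metabolite row index -> R T S_ji


def reaction_constraint(reaction: int, model: MetabolicModel,
                        thermo: ThermoData) -> _Constraint | None:
    """The drG <= -eps constraint of one reaction, or None if uncharacterized.

    Exchange reactions are always uncharacterized: their reaction energy
    involves the unmodelled boundary compartment.
    """
    if model.exchange[reaction]:
        return None
    const = 0.0
    coeffs: dict[int, float] = {}
    rt = thermo.rt
    any_nonzero = False
    for i, mid in enumerate(model.metabolite_ids):
        s = model.S[i][reaction]
        if s == 0:
            continue
        any_nonzero = True
        if thermo.is_excluded(mid):
            g = thermo.dfg0_prime(mid)
            if g is not None:
                const += float(s) * g
            continue
        g = thermo.dfg0_prime(mid)
        if g is None:
            return None
        const += float(s) * g
        coeffs[i] = coeffs.get(i, 0.0) + float(s) * rt
    if not any_nonzero:
        return _Constraint(0.0, {})
    return _Constraint(const, coeffs)


def _characterized_split(pattern, model, thermo):
    checked, skipped, constraints = [], [], {}
    for i in sorted(pattern):
        con = reaction_constraint(i, model, thermo)
        if con is None:
            skipped.append(i)
        else:
            checked.append(i)
            constraints[i] = con
    return checked, skipped, constraints


def _has_antiparallel_pair(checked: list[int], model: MetabolicModel) -> bool:
    """Detect a forward/backward pair (exactly opposite columns) in the pattern."""
    cols = {i: model.column(i) for i in checked}
    for a in range(len(checked)):
        for b in range(a + 1, len(checked)):
            ca, cb = cols[checked[a]], cols[checked[b]]
            if any(v != 0 for v in ca) and all(x == -y for x, y in zip(ca, cb)):
                return True
    return False


def _log_bounds(met_idx: int, model: MetabolicModel, thermo: ThermoData) -> tuple[float, float]:
    lo, hi = thermo.bounds(model.metabolite_ids[met_idx])
    return math.log(lo / thermo.c0), math.log(hi / thermo.c0)


def net_feasible(pattern, model: MetabolicModel, thermo: ThermoData,
                 epsilon: float | None = None) -> NetResult:
    """LP feasibility of simultaneous negative drG for a reaction pattern.

    Variables are x_j = ln(c_j/c0) for the internal, non-excluded,
    characterized metabolites appearing in the checked constraints, box-bounded
    by the concentration ranges.  Feasibility comes from the solver's
    certificate; any feasible point is returned as a witness.
    """
    eps = thermo.epsilon if epsilon is None else epsilon
    pattern = frozenset(pattern)
    checked, skipped, cons = _characterized_split(pattern, model, thermo)
    if not checked:
        return NetResult(True, {}, frozenset(), frozenset(skipped))
    if _has_antiparallel_pair(checked, model):
        # summed constraints force drG = 0, contradicting strict negativity
        return NetResult(False, None, frozenset(checked), frozenset(skipped))
    mets = sorted({m for c in cons.values() for m in c.coeffs})
    mpos = {m: k for k, m in enumerate(mets)}
    n = len(mets)
    a_ub, b_ub = [], []
    for i in checked:
        row = [0.0] * n
        for m, v in cons[i].coeffs.items():
            row[mpos[m]] = v
        a_ub.append(row)
        b_ub.append(-eps - cons[i].const)
    bounds = [_log_bounds(m, model, thermo) for m in mets]
    LP_STATS.calls += 1
    res = linprog(np.zeros(n), A_ub=np.array(a_ub), b_ub=np.array(b_ub),
                  bounds=bounds, method="highs")
    if res.status == 0:
        witness = {model.metabolite_ids[m]: float(res.x[mpos[m]]) for m in mets}
        return NetResult(True, witness, frozenset(checked), frozenset(skipped))
    if res.status == 2:
        return NetResult(False, None, frozenset(checked), frozenset(skipped))
    raise LPSolverError(f"LP solver status {res.status}: {res.message}")


def minimal_infeasible_pattern(pattern, model: MetabolicModel,
                               thermo: ThermoData) -> InfeasiblePattern:
    """Shrink an infeasible pattern to a minimal one by greedy deletion.

    Iterates reactions in index order and drops each whose removal keeps the
    remainder infeasible; the result is minimal (every proper subset feasible)
    after at most |pattern| LP calls.
    """
    if net_feasible(pattern, model, thermo).feasible:
        raise ValueError("minimal_infeasible_pattern requires an infeasible input pattern")
    current = set(pattern)
    for i in sorted(pattern):
        trial = current - {i}
        if trial and not net_feasible(trial, model, thermo).feasible:
            current = trial
    return InfeasiblePattern(frozenset(current), minimal=True)


def isolated_drg_range(reaction: int, model: MetabolicModel,
                       thermo: ThermoData) -> tuple[float, float] | None:
    """Closed-form drG range of one reaction over the concentration box.

    The extremes sit at box corners: substrates at c_max (minimum) or c_min
    (maximum), products vice versa.  Returns None for uncharacterized
    reactions.
    """
    con = reaction_constraint(reaction, model, thermo)
    if con is None:
        return None
    lo = hi = con.const
    for m, v in con.coeffs.items():
        xlo, xhi = _log_bounds(m, model, thermo)
        lo += v * (xlo if v > 0 else xhi)
        hi += v * (xhi if v > 0 else xlo)
    return lo, hi


def drg_range_in_context(reaction: int, pattern, model: MetabolicModel,
                         thermo: ThermoData) -> tuple[float, float] | None:
    """drG range of one reaction under the NET constraints of its pattern.

    Minimizes/maximizes drG_reaction subject to drG <= -eps for the *other*
    characterized pattern members plus the concentration box; the result is
    always contained in the isolated range.  Returns None if the reaction is
    uncharacterized, or if the context constraints are themselves infeasible
    (empty range).
    """
    target = reaction_constraint(reaction, model, thermo)
    if target is None:
        return None
    others = frozenset(pattern) - {reaction}
    checked, _, cons = _characterized_split(others, model, thermo)
    mets = sorted(set(target.coeffs)
                  | {m for c in cons.values() for m in c.coeffs})
    mpos = {m: k for k, m in enumerate(mets)}
    n = len(mets)
    a_ub, b_ub = [], []
    for i in checked:
        row = [0.0] * n
        for m, v in cons[i].coeffs.items():
            row[mpos[m]] = v
        a_ub.append(row)
        b_ub.append(-thermo.epsilon - cons[i].const)
    bounds = [_log_bounds(m, model, thermo) for m in mets]
    obj = np.zeros(n)
    for m, v in target.coeffs.items():
        obj[mpos[m]] = v
    kw = dict(A_ub=np.array(a_ub) if a_ub else None,
              b_ub=np.array(b_ub) if b_ub else None,
              bounds=bounds, method="highs")
    LP_STATS.calls += 2
    lo_res = linprog(obj, **kw)
    if lo_res.status == 2:
        return None
    hi_res = linprog(-obj, **kw)
    if lo_res.status != 0 or hi_res.status != 0:
        raise LPSolverError(f"LP solver status {lo_res.status}/{hi_res.status}")
    return target.const + float(lo_res.fun), target.const - float(hi_res.fun)


def pattern_cache_check(pattern, cache) -> bool:
    """True iff the pattern is a superset of a cached infeasible pattern.

    Infeasibility is monotone under adding reactions, so a positive answer
    certifies infeasibility without an LP call.
    """
    pattern = frozenset(pattern)
    for p in cache:
        reactions = p.reactions if isinstance(p, InfeasiblePattern) else frozenset(p)
        if reactions <= pattern:
            return True
    return False
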