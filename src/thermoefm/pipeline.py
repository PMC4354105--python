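"""The integrated enumeration pipeline: thermodynamic pruning inside the DDM.

Workflow: split reversible reactions, (optionally) compress, build the kernel
tableau, then iterate the binary null-space algorithm.  At the start of each
iteration every mode with nonzero numeric value at the pivot row is checked
for thermodynamic feasibility on its *inherited* support — the binarized bits,
which every descendant provably retains — and removed at birth if infeasible.
A final feasibility pass over the full supports catches infeasibilities that
arose in positions never re-examined.  The returned EFM set equals the plain
enumeration post-hoc filtered by the NET LP; the interleaved version just
never materializes the infeasible part of the search tree.

Feasibility answers are cached in both monotone directions (a superset of an
infeasible pattern is infeasible; a subset of a feasible one is feasible),
keyed on the characterized part of the support, so repeated checks along a
descent line cost no LPs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

import numpy as np
import pandas as pd

from ._exact import ZERO, as_fraction
from .efm_engine import (EFM, EnumerationError, EnumerationStats, IterationStats,
                         finalize_fluxes, init_tableau, modes_to_supports,
                         process_row, remove_futile_2cycles, select_next_row)
from .model_io import (CompressedModel, MetabolicModel, SplitMap, compress,
                       kernel, merge_split_fluxes, split_reversible)
from .thermo import (LP_STATS, InfeasiblePattern, ThermoData,
                     minimal_infeasible_pattern, net_feasible,
                     reaction_constraint)

CHECK_MODES = ("off", "binary_only", "binary_plus_pivot")


@dataclass
class TefmaOptions:
    """Knobs of the integrated run.

    ``check_mode``: ``off`` (plain enumeration), ``binary_only`` (prune on
    inherited bits only — provably safe for all offspring) or
    ``binary_plus_pivot`` (additionally re-check retained positive modes with
    the freshly binarized pivot, after combination).  ``epsilon`` overrides
    the thermo table's feasibility margin when set.
    """

    check_mode: str = "binary_only"
    epsilon: float | None = None
    use_pattern_cache: bool = True
    collect_minimal_patterns: bool = False
    final_check: bool = True
    compress: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.check_mode not in CHECK_MODES:
            raise ValueError(f"check_mode must be one of {CHECK_MODES}")


@dataclass
class TefmaResult:
    """EFMs (thermodynamically feasible when data were given) plus diagnostics.

    EFMs live on the split (irreversible) model; ``merge_split_fluxes`` turns
    their fluxes into signed values on the original reactions.
    """

    efms: list[EFM]
    split_model: MetabolicModel
    split_map: SplitMap
    patterns: list[InfeasiblePattern]
    stats: EnumerationStats
    options: TefmaOptions

    def support_sets(self) -> set[frozenset[int]]:
        return {e.support for e in self.efms}

    def support_id_sets(self) -> set[frozenset[str]]:
        return {e.support_ids(self.split_model) for e in self.efms}


class _FeasibilityChecker:
    """Cached NET feasibility over supports of the split model."""

    def __init__(self, split_model: MetabolicModel, thermo: ThermoData,
                 options: TefmaOptions):
        self.model = split_model
        if options.epsilon is not None and options.epsilon != thermo.epsilon:
            thermo = thermo.copy()
            thermo.epsilon = options.epsilon
        self.thermo = thermo
        self.options = options
        self._constraints = {
            i: con for i in range(split_model.n_reactions)
            if (con := reaction_constraint(i, split_model, thermo)) is not None}
        self.characterized = frozenset(self._constraints)
        self.infeasible_cache: list[frozenset[int]] = []
        self.feasible_cache: list[frozenset[int]] = []
        self.minimal_patterns: list[InfeasiblePattern] = []
        self.lp_calls = 0
        self.minimization_lp_calls = 0
        self.cache_hits = 0

    def is_feasible(self, support: frozenset[int]) -> bool:
        eff = support & self.characterized
        if not eff:
            return True
        if self.options.use_pattern_cache:
            for p in self.infeasible_cache:
                if p <= eff:
                    self.cache_hits += 1
                    return False
            for p in self.feasible_cache:
                if eff <= p:
                    self.cache_hits += 1
                    return True
        before = LP_STATS.calls
        res = net_feasible(eff, self.model, self.thermo)
        self.lp_calls += LP_STATS.calls - before
        if res.feasible:
            self.feasible_cache.append(self._extend_witness(eff, res.witness))
            return True
        pattern = eff
        if self.options.collect_minimal_patterns:
            before = LP_STATS.calls
            minimal = minimal_infeasible_pattern(eff, self.model, self.thermo)
            self.minimization_lp_calls += LP_STATS.calls - before
            pattern = minimal.reactions
            if all(pattern != p.reactions for p in self.minimal_patterns):
                self.minimal_patterns.append(minimal)
        self.infeasible_cache.append(pattern)
        return False

    def _extend_witness(self, eff: frozenset[int],
                        witness: dict[str, float]) -> frozenset[int]:
        """All characterized reactions satisfied at one concrete metabolome.

        The LP witness fixes the metabolites it constrained; everything else
        is pinned at the midpoint of its log-concentration range.  Every
        reaction with negative drG at this single point is simultaneously
        feasible, so the whole satisfied set — a superset of ``eff`` — can be
        cached as one feasible pattern (witness reuse).
        """
        import math

        x: dict[int, float] = {}
        mids = self.model.metabolite_ids
        for i, mid in enumerate(mids):
            if mid in witness:
                x[i] = witness[mid]
            else:
                lo, hi = self.thermo.bounds(mid)
                x[i] = 0.5 * (math.log(lo / self.thermo.c0)
                              + math.log(hi / self.thermo.c0))
        satisfied = set(eff)
        for i, con in self._constraints.items():
            if i in satisfied:
                continue
            drg = con.const + sum(v * x[m] for m, v in con.coeffs.items())
            if drg <= -self.thermo.epsilon - 1e-9:
                satisfied.add(i)
        return frozenset(satisfied)


def tefma_enumerate(model: MetabolicModel, thermo: ThermoData | None = None,
                    options: TefmaOptions | None = None,
                    iteration_log: Callable[[dict], None] | None = None) -> TefmaResult:
    """Enumerate (thermodynamically feasible) EFMs of a metabolic model.

    ``model`` may contain reversible reactions; splitting, compression,
    futile-2-cycle removal, decompression and flux computation are handled
    here.  With ``thermo=None`` (or ``check_mode='off'``) this is a plain
    enumeration.
    """
    options = options or TefmaOptions()
    if thermo is not None:
        unmatched = [mid for mid in thermo.entries if mid not in model.metabolite_ids]
        if unmatched:
            warnings.warn(
                f"thermo entries match no model metabolite: {sorted(unmatched)}",
                stacklevel=2)

    split_model, split_map = split_reversible(model)
    comp: CompressedModel | None = None
    if options.compress:
        comp = compress(split_model)
        work = comp.model
    else:
        work = split_model

    checker = None
    if thermo is not None and options.check_mode != "off":
        checker = _FeasibilityChecker(split_model, thermo, options)

    basis = kernel(work)
    stats = EnumerationStats()
    efms: list[EFM] = []
    if basis.dim > 0:
        # tableau row -> set of split-model reaction indices guaranteed active.
        # For a reaction with removed duplicate columns only the intersection
        # over representatives is guaranteed: decompression may substitute any
        # member of the class.
        split_idx = {rid: j for j, rid in enumerate(split_model.reaction_ids)}
        row_support: list[frozenset[int]] = []
        for pos in range(basis.n_rows):
            rid = work.reaction_ids[basis.row_order[pos]]
            if comp is not None:
                variants = [frozenset(split_idx[o] for o, _ in comp.reaction_map[rid])]
                for other, _ in comp.duplicate_classes.get(rid, []):
                    variants.append(frozenset(split_idx[o]
                                              for o, _ in comp.reaction_map[other]))
                row_support.append(frozenset.intersection(*variants))
            else:
                row_support.append(frozenset({split_idx[rid]}))

        def bits_support(bits: int) -> frozenset[int]:
            out: set[int] = set()
            for i in range(basis.n_rows):
                if bits >> i & 1:
                    out |= row_support[i]
            return frozenset(out)

        modes = init_tableau(basis)
        unprocessed = set(range(basis.dim, basis.n_rows))
        while unprocessed and modes:
            row = select_next_row(modes, unprocessed)
            pruned = 0
            lp0 = checker.lp_calls if checker else 0
            ch0 = checker.cache_hits if checker else 0
            if checker is not None:
                # check only when pruning can pay for itself: it costs up to
                # pos+neg LPs and can save up to pos*neg combinations, so tiny
                # iterations are left to the final pass instead
                n_pos = sum(1 for m in modes if m.numeric.get(row, ZERO) > 0)
                n_neg = sum(1 for m in modes if m.numeric.get(row, ZERO) < 0)
                if n_pos * n_neg > n_pos + n_neg:
                    keep = []
                    for m in modes:
                        if m.numeric.get(row, ZERO) != 0 and \
                                not checker.is_feasible(bits_support(m.bits)):
                            pruned += 1
                            continue
                        keep.append(m)
                    modes = keep
            modes, it = process_row(modes, row)
            if checker is not None and options.check_mode == "binary_plus_pivot":
                keep = []
                for m in modes:
                    if m.bits >> row & 1 and not checker.is_feasible(bits_support(m.bits)):
                        pruned += 1
                        continue
                    keep.append(m)
                modes = keep
            it.pruned = pruned
            if checker is not None:
                it.lp_calls = checker.lp_calls - lp0
                it.cache_hits = checker.cache_hits - ch0
            stats.iterations.append(it)
            unprocessed.discard(row)
            if iteration_log is not None:
                iteration_log({"pivot_reaction": work.reaction_ids[basis.row_order[it.row]],
                               "pos": it.n_pos, "zero": it.n_zero, "neg": it.n_neg,
                               "candidates": it.candidates_generated,
                               "kept": it.candidates_kept, "lp_calls": it.lp_calls,
                               "cache_hits": it.cache_hits, "pruned": it.pruned})

        final_modes = [m for m in modes if m.bits]
        lp0 = checker.lp_calls if checker else 0
        if checker is not None and options.final_check:
            # final pass, stage 1: the guaranteed-active support of each
            # fully binary mode.  This also eliminates the non-elementary
            # artifacts of pruning: a candidate kept only because its
            # adjacency witness was pruned inherits that witness's
            # infeasible bits, so it cannot pass this check.
            kept_modes = []
            for m in final_modes:
                if checker.is_feasible(bits_support(m.bits)):
                    kept_modes.append(m)
                else:
                    stats.final_pruned += 1
            final_modes = kept_modes
        work_supports = sorted({s for s in modes_to_supports(final_modes, basis) if s},
                               key=lambda s: tuple(sorted(s)))
        efms = _decompress(work_supports, work, comp, split_model,
                           tolerate_degenerate=checker is not None)
        if checker is not None and options.final_check:
            # stage 2: every decompressed expansion on its actual support
            # (duplicate substitution can change the support; usually a
            # cache hit)
            kept = []
            for e in efms:
                if checker.is_feasible(e.support):
                    kept.append(e)
                else:
                    stats.final_pruned += 1
            efms = kept
        if checker is not None:
            stats.final_lp_calls = checker.lp_calls - lp0

    efms = remove_futile_2cycles(efms, split_model, split_map)
    efms.sort(key=lambda e: tuple(sorted(e.support)))
    patterns = checker.minimal_patterns if checker else []
    return TefmaResult(efms, split_model, split_map, patterns, stats, options)


def _decompress(work_supports, work: MetabolicModel, comp: CompressedModel | None,
                split_model: MetabolicModel,
                tolerate_degenerate: bool = False) -> list[EFM]:
    """Expand compressed EFM supports to split-model EFMs.

    Merged reactions distribute their flux over their members with the stored
    rational multipliers; duplicate classes expand combinatorially, one EFM
    per representative choice.  With ``tolerate_degenerate`` (pruned runs
    without a final check), supports failing the 1-D nullspace test are
    silently dropped — they are pruning artifacts, provably infeasible.
    """
    import itertools

    split_idx = {rid: j for j, rid in enumerate(split_model.reaction_ids)}
    out: list[EFM] = []
    for s in work_supports:
        try:
            base = finalize_fluxes(s, work)
        except EnumerationError:
            if tolerate_degenerate:
                continue
            raise
        active = [work.reaction_ids[j] for j in sorted(s)]
        if comp is None:
            out.append(_flux_to_efm({rid: base.flux[work.reaction_index(rid)]
                                     for rid in active}, split_idx))
            continue
        choices = []
        for rid in active:
            reps = [(rid, Fraction(1))]
            for other, scale in comp.duplicate_classes.get(rid, []):
                reps.append((other, scale))
            choices.append((rid, reps))
        for combo in itertools.product(*(reps for _, reps in choices)):
            flux: dict[str, Fraction] = {}
            for (rid, _), (rep, scale) in zip(choices, combo):
                v = base.flux[work.reaction_index(rid)] / scale
                for orig, mult in comp.reaction_map[rep]:
                    flux[orig] = flux.get(orig, ZERO) + v * mult
            out.append(_flux_to_efm(flux, split_idx))
    return out


def _flux_to_efm(flux: dict[str, Fraction], split_idx) -> EFM:
    vec = [ZERO] * len(split_idx)
    for rid, v in flux.items():
        if v != 0:
            vec[split_idx[rid]] = v
    positive = [v for v in vec if v > 0]
    if not positive or any(v < 0 for v in vec):
        raise EnumerationError("decompressed flux is not nonnegative")
    smallest = min(positive)
    vec = [v / smallest for v in vec]
    return EFM(flux=tuple(vec), support=frozenset(j for j, v in enumerate(vec) if v != 0))


def safe_support(mode, pivot: int, check_mode: str,
                 bits_support: Callable[[int], frozenset[int]]) -> frozenset[int]:
    """The support on which a mode may be pruned without touching offspring.

    ``binary_only``: the inherited bits — active in every descendant.
    ``binary_plus_pivot``: bits plus the pivot, valid only for retained
    positive modes *after* combination (they parent no further offspring in
    the iteration).
    """
    if check_mode == "binary_only":
        return bits_support(mode.bits)
    if check_mode == "binary_plus_pivot":
        return bits_support(mode.bits | (1 << pivot))
    raise ValueError(f"no safe support for check_mode {check_mode!r}")


# ---------------------------------------------------------------------------
# EFM files
# ---------------------------------------------------------------------------

def write_efms_tsv(path, result: TefmaResult, original_model: MetabolicModel) -> None:
    """Signed flux table: one EFM per row, columns = original reaction ids.

    Split pairs are merged back into signed values; the header records the
    model hash, options and counts.
    """
    rids = list(original_model.reaction_ids)
    with open(path, "w") as fh:
        fh.write(f"# model_hash={original_model.content_hash()} "
                 f"check_mode={result.options.check_mode} "
                 f"n_efms={len(result.efms)}\n")
        fh.write("\t".join(rids) + "\n")
        for e in result.efms:
            flux = {rid: e.flux[j] for j, rid in enumerate(result.split_model.reaction_ids)}
            merged = merge_split_fluxes(flux, result.split_map)
            fh.write("\t".join(str(merged.get(rid, ZERO)) for rid in rids) + "\n")


def write_supports(path, result: TefmaResult) -> None:
    """Compact support-list format: one line of reaction ids per EFM."""
    with open(path, "w") as fh:
        fh.write(f"# model_hash={result.split_model.content_hash()} "
                 f"check_mode={result.options.check_mode} "
                 f"n_efms={len(result.efms)}\n")
        for e in result.efms:
            fh.write(" ".join(sorted(e.support_ids(result.split_model))) + "\n")


def read_efms_tsv(path) -> tuple[list[str], list[dict[str, Fraction]]]:
    """Read a signed EFM table back: (reaction ids, one flux dict per EFM)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith("#")]
    if not lines:
        return [], []
    rids = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        vals = [as_fraction(tok) for tok in ln.split("\t")]
        if len(vals) != len(rids):
            raise ValueError("EFM row length does not match header")
        rows.append({rid: v for rid, v in zip(rids, vals) if v != 0})
    return rids, rows


@dataclass
class EfmCheckRecord:
    index: int
    feasible: bool | None  # None on per-record error
    error: str | None = None


@dataclass
class EfmCheckReport:
    records: list[EfmCheckRecord]

    @property
    def n_feasible(self) -> int:
        return sum(1 for r in self.records if r.feasible)

    @property
    def n_infeasible(self) -> int:
        return sum(1 for r in self.records if r.feasible is False)

    @property
    def n_errors(self) -> int:
        return sum(1 for r in self.records if r.feasible is None)


def check_efm_file(path, model: MetabolicModel, thermo: ThermoData) -> EfmCheckReport:
    """Post-hoc NET feasibility of every EFM in a signed flux table.

    Each row is mapped back onto the split model (sign decides the half of a
    split pair), validated as an elementary mode (1-dimensional restricted
    nullspace) and run through the feasibility LP.  Per-record failures are
    reported, not raised.
    """
    split_model, split_map = split_reversible(model)
    split_idx = {rid: j for j, rid in enumerate(split_model.reaction_ids)}
    _, rows = read_efms_tsv(path)
    records = []
    for k, flux in enumerate(rows):
        support: set[int] = set()
        try:
            for rid, v in flux.items():
                if rid in split_map.pairs:
                    f, b = split_map.pairs[rid]
                    support.add(split_idx[f] if v > 0 else split_idx[b])
                elif rid in split_idx:
                    if v < 0:
                        raise EnumerationError(
                            f"negative flux on irreversible reaction {rid}")
                    support.add(split_idx[rid])
                else:
                    raise EnumerationError(f"unknown reaction id {rid}")
            finalize_fluxes(support, split_model)  # 1-D consistency check
        except EnumerationError as exc:
            records.append(EfmCheckRecord(k, None, str(exc)))
            continue
        res = net_feasible(frozenset(support), split_model, thermo)
        records.append(EfmCheckRecord(k, res.feasible))
    return EfmCheckReport(records)


# ---------------------------------------------------------------------------
# stability analysis
# ---------------------------------------------------------------------------

def _perturb_concentrations(thermo: ThermoData, delta: float,
                            rng: np.random.Generator) -> ThermoData:
    out = thermo.copy()
    for mid, e in out.entries.items():
        base_lo = e.c_min if e.c_min is not None else out.default_c_min
        base_hi = e.c_max if e.c_max is not None else out.default_c_max
        mean = 0.5 * (base_lo + base_hi)
        lo = base_lo * float(rng.uniform(1 - delta, 1 + delta))
        hi = base_hi * float(rng.uniform(1 - delta, 1 + delta))
        # the perturbed bounds must still bracket the mean concentration
        e.c_min = min(lo, mean)
        e.c_max = max(hi, mean)
    return out


def _perturb_dfg(thermo: ThermoData, delta: float,
                 rng: np.random.Generator) -> ThermoData:
    out = thermo.copy()
    for e in out.entries.values():
        if e.dfg0_prime is not None:
            e.dfg0_prime += float(rng.uniform(-delta, delta))
    return out


def stability_analysis(model: MetabolicModel, thermo: ThermoData, kind: str,
                       magnitudes, n_reps: int, seed: int,
                       options: TefmaOptions | None = None) -> pd.DataFrame:
    """Robustness of the feasible EFM set against input perturbations.

    ``kind='concentration'``: every explicit concentration bound is scaled by
    an independent uniform factor in [1-delta, 1+delta] (delta relative, e.g.
    0.05 for +-5%), then clamped so the bounds still bracket the unperturbed
    midpoint.  ``kind='dfg'``: every formation energy is shifted by an
    independent uniform draw in [-delta, +delta] kJ/mol.  Each of ``n_reps``
    replicates reruns the full enumeration; the run is bit-reproducible for a
    fixed root seed (one derived stream per replicate).
    """
    if kind not in ("concentration", "dfg"):
        raise ValueError("kind must be 'concentration' or 'dfg'")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    magnitudes = list(magnitudes)
    if any(m < 0 for m in magnitudes):
        raise ValueError("magnitudes must be nonnegative")
    options = options or TefmaOptions()
    base = tefma_enumerate(model, thermo, options)
    base_sets = base.support_sets()
    rows = []
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(magnitudes) * n_reps)
    k = 0
    for delta in magnitudes:
        for rep in range(n_reps):
            rng = np.random.default_rng(streams[k])
            k += 1
            perturbed = (_perturb_concentrations(thermo, delta, rng)
                         if kind == "concentration" else _perturb_dfg(thermo, delta, rng))
            res = tefma_enumerate(model, perturbed, options)
            rows.append({"magnitude": delta, "rep": rep,
                         "feasible_count": len(res.efms),
                         "set_identical": res.support_sets() == base_sets})
    return pd.DataFrame(rows)


def iteration_log_writer(fh):
    """JSON-lines iteration logger for ``tefma_enumerate(iteration_log=...)``."""
    def log(record: dict):
        fh.write(json.dumps(record) + "\n")
    return log
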