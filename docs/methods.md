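# Methods

## Model representation

A metabolic model is the stoichiometric matrix **S** (m internal metabolites ×
r reactions) with exact rational coefficients, per-reaction reversibility
flags, and exchange annotations.  External (boundary) metabolites get no row
in **S**; their coefficients are kept as annotations on the exchange reactions
so that condition-specific sub-models can be built (uptake of a nutrient
absent from the growth medium is removed; if the transport is reversible only
its uptake orientation is disabled, secretion is always retained).

SBML input goes through cobra; the reader keeps only reactions literally
declared in the file (cobra synthesizes exchange reactions for
boundary-condition species, which would distort dimensions), treats species in
a compartment named `external`/`b` and boundary-condition species as external,
and converts coefficients to exact rationals via their decimal representation.
For SBML with flux-bound (fbc) information, reversibility follows the bounds
as cobra exposes them; for plain L2 files it is the `reversible` attribute.
The TSV dialect (`reaction_id`, `equation`, `is_exchange`) treats metabolites
that appear only in exchange reactions as external.

All structural transforms are exact.  Floating point enters only in the LP
layer (below) and in blocked-reaction detection.

## Enumeration: binary null-space double description

Reversible reactions are split into irreversible forward/backward halves (the
backward column an exact negation).  The kernel of **S** is computed by
rational Gauss–Jordan elimination and row-permuted so that the free columns —
one per kernel dimension — form a leading identity block.  Each kernel column
is an intermediate mode with one *binary* (processed) coordinate set and the
remaining coordinates numeric.

One row (reaction) is processed per iteration, chosen as the unprocessed row
minimizing |pos|·|neg| with smallest-index tie-breaking, which makes runs
deterministic; the final EFM set is independent of the order (tested by
permutation).  Modes positive at the row keep it as an activity bit; negative
modes are discarded; each positive/negative pair (p, n) is combined into
|n_row|·p + p_row·n — the row cancels exactly — and gcd-normalized.

A candidate is kept iff it passes the combinatorial adjacency test: no *other*
current mode (including the negative side) has a binary support contained in
`bits(p) | bits(n)`.  Elementarity of an extreme ray is a zero-set condition
over the inequality-constrained coordinates only, which at any intermediate
stage are exactly the processed (binary) coordinates; the numeric part of a
mode is unconstrained and must not enter the test.  An earlier variant of this
test that compared full supports (bits plus numeric nonzeros) against only the
surviving modes was found to admit non-elementary candidates on random
12-reaction networks and was replaced; the engine is validated against a
brute-force oracle (exhaustive support enumeration with exact nullspace
checks) on 80 random networks across four size classes.

Enumeration is preceded by structural compression: removal of blocked
reactions (zero row in the kernel, or LP-certified zero maximal flux), merging
of uniquely coupled pairs (a metabolite with exactly one producer and one
consumer fixes their flux ratio; the merged column carries exact multipliers),
and removal of duplicate columns (equal up to a positive scale).  Duplicate
classes are remembered and re-expanded at decompression — one EFM per
representative choice, scaled by the stored ratio — which keeps the
compressed/uncompressed EFM sets exactly equal (tested against the oracle).
Futile 2-cycles (the forward+backward pair of one split reaction) are removed
in post-processing, and each EFM's flux values are recomputed from its support
(the nullspace of **S** restricted to the support must be one-dimensional with
a strictly positive generator; the smallest positive entry is normalized
to 1).

## Thermodynamic feasibility (NET)

Reaction i with flux must satisfy ΔrG_i < 0 with

ΔrG_i = Σ_j S_ji ΔfG'°_j + RT Σ_j S_ji x_j,  x_j = ln(c_j/c°).

Whether all members of a reaction pattern can satisfy this simultaneously,
with x_j box-bounded by the concentration ranges, is a linear feasibility
problem solved with HiGHS (scipy); infeasibility is taken from the solver's
certificate, and any feasible point is returned as a witness (no objective is
optimized).  Strict negativity is encoded as ≤ −ε with ε = 0 by default
(configurable); the forward+backward pair of a split reaction — whose summed
constraints force ΔrG = 0 — is special-cased infeasible, since ΔrG = 0 means
no net flux in either direction.

Conventions:

* Water and protons (configurable list, matched after stripping a compartment
  suffix) carry no concentration variable: their activity is fixed, and pH
  enters through the Legendre transform of the formation energies
  (ΔfG'° = ΔfG° + n_H·RT·ln(10)·pH − 2.91482·(z² − n_H)·√I/(1 + 1.6·√I),
  the extended Debye–Hückel form with the Alberty convention constants; the
  coefficient is treated as fixed rather than temperature-dependent).
* A reaction is *characterized* iff every non-excluded internal metabolite it
  touches has a formation energy.  Uncharacterized reactions, and all
  exchange/boundary reactions (their ΔrG would involve the unmodelled
  extracellular compartment), are skipped entirely: missing data can only
  reduce pruning, never create a false infeasibility.
* Unmeasured metabolites default to very conservative concentration bounds,
  10⁻⁹–0.1 M, configurable globally and per metabolite.
* Defaults: T = 310.15 K, pH 7, ionic strength 0.15 M (used only when raw
  ΔfG° tables are transformed), c° = 1 M, R = 8.314·10⁻³ kJ/(mol·K).

Isolated ΔrG ranges are closed-form (box corners: substrates at c_max for the
minimum, products at c_min, and vice versa).  Context ranges minimize and
maximize ΔrG_i subject to the other pattern members' constraints; the context
interval is always contained in the isolated one.  Minimal infeasible patterns
come from greedy deletion in index order (at most |pattern| LP calls); the
result is infeasible with every proper subset feasible.

Infeasibility is monotone under adding reactions and feasibility under
removing them.  The pipeline exploits both: verified infeasible patterns are
cached and matched by subset test before any LP, and after every feasible LP
all characterized reactions are evaluated at one concrete metabolome (the LP
witness, with unconstrained metabolites at their log-midpoint) and the whole
satisfied set is cached as a single feasible pattern (witness reuse).  Cache
answers never differ from LP answers (tested), so caching changes LP counts
only.

## Interleaved pruning

At the start of an iteration, modes with nonzero numeric value at the pivot
row are checked on their *inherited* support — the binary bits, which every
descendant provably retains (for compressed reactions with duplicate classes,
only the intersection of the representatives' original reactions is
guaranteed) — and removed immediately if infeasible.  Two check variants
exist: `binary_only` (bits only), and `binary_plus_pivot`, which additionally
re-checks retained positive modes with the freshly binarized pivot included
(safe, because at that point they no longer parent offspring within the
iteration).  Checks are only issued when |pos|·|neg| > |pos| + |neg|, i.e.
when pruning can save more pairwise combinations than it costs in checks;
everything the loop skips is decided in the final pass.

Pruning can remove a mode that would have served as an adjacency witness, so
a later candidate may be kept that is not elementary — but any such candidate
inherits the pruned witness's bits and is therefore itself infeasible on its
inherited support.  The final pass exploits this: it first checks every fully
binary mode on its guaranteed support (eliminating those artifacts before any
flux computation), then decompresses and checks each expanded EFM on its
actual support.  The returned set equals the plain enumeration post-hoc
filtered by the feasibility LP — the package's central correctness identity,
asserted for both check variants on every test fixture.  With an
uncharacterized metabolome or `check_mode="off"` the pipeline is bitwise
identical to plain enumeration and solves zero LPs.

LP economy — total LPs not exceeding the number of candidate modes the
matched plain run generates — is a *scale* property: it holds on networks
where enumeration does real combinatorial work (the acceptance check uses
8-metabolite, 16-reaction fixtures with 5 reversible reactions, median ~2000
candidates) but is unattainable on fixtures that compress to near-trivial
enumerations (a model with one EFM and zero candidates still needs one LP to
classify that EFM).  Runs generating zero candidates are therefore excluded
from the comparison as vacuous.

## Stability protocol

Robustness of the feasible set is probed by rerunning the full pipeline under
random input perturbations: every explicit concentration bound scaled by an
independent uniform factor in [1−δ, 1+δ] (then clamped so the bounds still
bracket the unperturbed arithmetic midpoint, which stands in for the measured
mean concentration), or every formation energy shifted by an independent
uniform draw in [−δ, +δ] kJ/mol.  One root seed spawns an independent stream
per replicate, making runs bit-reproducible.  The output table records, per
replicate, the feasible-EFM count and whether the support set is identical to
the unperturbed run.

## Synthetic study conditions

The fixture module generates everything the tests need: seeded random models
(coefficients in {−2, −1, 1, 2}, guaranteed nontrivial kernel, one uptake and
one secretion exchange by construction, capped at 18 reactions so the
exhaustive oracle stays tractable), a brute-force EFM oracle, a grid-search
falsifier for the feasibility LP (one-sided: an LP-infeasible pattern must
have no strictly satisfying grid point; used to guard against solver
misconfiguration, since a grid cannot prove infeasibility of a continuous
set), and an inverse generator that rejection-samples formation energies
(uniform −60…20 kJ/mol) and concentration windows (log-uniform lower bound
10⁻⁶–10⁻³·⁵ M, 0.4–2 decades wide) until prescribed patterns are infeasible
with all proper subsets feasible and prescribed others feasible.  A
deterministic variant of the pathway-context motif is also provided: a
reversible 3-step chain with zero formation energies whose concentration
windows are placed so the forward triple is infeasible (the telescoped
constraint forces ln c_end ≤ ln c_start while the end window lies strictly
above the start window) with every proper subset, and the entire backward
triple, feasible.

These fixtures emulate the *structure* of real inputs — sparse stoichiometry,
reversibility, exchanges, partially characterized metabolomes — but not their
biochemistry: no mass conservation across elements, no cofactor coupling, no
realistic energy scales beyond the motif.  Passing tests therefore certify
the algorithms (completeness, the pruning identity, monotonicity,
reproducibility), not biological conclusions about any particular organism.

## Numerical choices and limitations

* Exact rational arithmetic everywhere except the LP layer; "is this entry
  zero" is decided exactly, so the adjacency test needs no tolerance.  A
  price: coefficients can grow, mitigated by gcd normalization after every
  combination.
* LP feasibility tolerance is HiGHS's default (~10⁻⁹ primal); witnesses are
  asserted to satisfy constraints within 10⁻⁶ kJ/mol in tests.
* ε = 0 means a pattern achieving ΔrG = 0 exactly on some reaction counts as
  feasible (except the special-cased antiparallel pairs); set ε > 0 for a
  strict margin.
* Problem sizes: the test and acceptance suites run networks up to 8
  metabolites × 21 post-split reactions, chosen so exhaustive oracles and
  hundreds of LP-verified trials complete in seconds; the implementation
  itself has no hard size limit but is a clarity-first rational-arithmetic
  code, not a performance-parity replacement for compiled enumerators.
* Multi-compartment transport thermodynamics, Gibbs energy estimation from
  structure, regulatory constraints and flux prediction are out of scope.
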