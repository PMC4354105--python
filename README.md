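# thermoefm

Elementary flux mode enumeration with network-embedded thermodynamic pruning.

## The problem

Elementary flux modes (EFMs) are the support-minimal steady-state pathways of a
metabolic network: nonnegative flux vectors *v* with **S** *v* = 0 (for the
stoichiometric matrix **S** over internal metabolites, after splitting every
reversible reaction into irreversible halves) such that no proper subset of the
active reactions can still carry steady-state flux.  Every steady-state flux
distribution is a nonnegative combination of EFMs, so the EFM set characterizes
the full metabolic capability of an organism — but its size explodes
combinatorially with network size, and many topologically valid EFMs are
biologically impossible: they would require some reaction to run against its
Gibbs energy gradient given physiological metabolite concentrations.

`thermoefm` enumerates EFMs with the binary null-space variant of the double
description method and, when a metabolome is supplied, interleaves
network-embedded thermodynamic (NET) feasibility checks into the enumeration
itself.  A reaction *i* carrying flux must satisfy

```
ΔrG_i = Σ_j S_ji (ΔfG'°_j + RT ln(c_j / c°)) < 0,
```

and whether all reactions of a candidate pathway can satisfy this
*simultaneously*, with each concentration c_j inside its measured (or
conservative default) range, is a linear feasibility program in
x_j = ln(c_j/c°).  Because activity bits in the enumeration are inherited by
all descendants, a mode whose inherited support is already infeasible can be
discarded at birth — without ever losing a feasible EFM.  The result is exactly
the thermodynamically feasible subset of the full EFM set, computed without
materializing the infeasible part of the search tree.

The package is for systems-biology researchers doing constraint-based
modelling who want condition-specific EFM sets (metabolome-filtered), minimal
infeasible reaction patterns (reaction sets that can never carry simultaneous
flux, e.g. a gluconeogenic chain under glycolytic conditions), and
ΔrG ranges of reactions in pathway context.

## Worked example

A toy upper-glycolysis module where both glycolytic and gluconeogenic
directions are individually reversible, written in the package's TSV dialect:

`model.tsv`
```
reaction_id	equation	is_exchange
EX_glc	glc_e -> g6p	1
EX_pyr_up	pyr_e -> pyr	1
PGI	g6p <=> f6p	0
LOWER	f6p <=> 2 pyr	0
EX_pyr_out	pyr ->	1
EX_g6p_out	g6p ->	1
```

`thermo.tsv` (transformed formation energies, kJ/mol, and concentration
windows, M)
```
metabolite_id	dfG0_prime_kJ_mol	c_min_M	c_max_M
g6p	-1318.9	1e-4	5e-3
f6p	-1315.7	1e-5	1e-3
pyr	-660.0	1e-4	1e-2
```

Plain enumeration finds four EFMs (columns are the original reactions; signed
values mean the reverse half of a split reaction carries the flux):

```
$ thermoefm enumerate model.tsv -o plain.tsv
4 EFMs (candidates=6 kept=4 lp_calls=0 pruned=0)

$ cat plain.tsv
# model_hash=5c150eeae94e check_mode=off n_efms=4
EX_glc	EX_pyr_up	PGI	LOWER	EX_pyr_out	EX_g6p_out
1	0	1	1	2	0
1	0	0	0	0	1
0	2	-1	-1	0	1
0	1	0	0	1	0
```

Row 1 is glycolysis (glucose in, two pyruvate out), row 3 is gluconeogenesis
(two pyruvate in, running PGI and LOWER backwards).  With the metabolome, the
pruned run drops exactly the gluconeogenic mode and reports why:

```
$ thermoefm tefma model.tsv thermo.tsv -o pruned.tsv --collect-patterns
3 EFMs (candidates=6 kept=4 lp_calls=2 pruned=3)
pattern	PGI PGI_rev
pattern	LOWER LOWER_rev
pattern	LOWER_rev PGI_rev
```

Each reported pattern is a *minimal infeasible flux pattern*: the two
futile 2-cycles, and — the interesting one — `{PGI_rev, LOWER_rev}`.  Either
backward reaction is feasible on its own within the concentration windows, but
together they would need f6p below ~2·10⁻⁵ M (to drive LOWER backwards at the
maximal pyruvate level) *and* g6p below the f6p level times e^1.24, which its
own lower bound forbids — the gluconeogenic chain is blocked only in network
context.  The post-hoc route confirms the same verdict:

```
$ thermoefm check plain.tsv model.tsv thermo.tsv
0	feasible
1	feasible
2	infeasible
3	feasible
# feasible=3 infeasible=1 errors=0
```

The same operations are available as a library
(`thermoefm.tefma_enumerate`, `net_feasible`, `minimal_infeasible_pattern`,
`drg_range_in_context`, `stability_analysis`, ...); see `docs/methods.md` for
the model and algorithm details.

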