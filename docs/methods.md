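# Methods

## Replicore pedigree model

A replicore is tracked as a complete binary tree: each node is one DNA
molecule, each replication event produces a leading-strand and a
lagging-strand daughter. Mutations follow the infinite-sites convention —
every event is an opaque, globally unique integer label, so a genotype is a
set of labels, back-mutation cannot occur, and genotype identity is set
equality. There is no fitness, drift or randomness in this module: the model
isolates what the replication rule alone implies.

Per replication event, `d` new mutations are introduced (default `d = 2`).
In **disparity** mode all `d` go to the lagging daughter; in **parity** mode
each daughter receives `d/2` (so `d` must be even). This keeps total
mutational input identical between modes, which is the comparison the model
is built to make; it is why the default parity tree gives every genome
exactly `g` mutations at generation `g` while the disparity tree gives the
binomial census `C(g, k)` genomes with `2k` mutations.

Determinism is exact: event labels 1, 2, 3, … are allocated depth-first,
leading daughter before lagging daughter, so two runs with equal parameters
produce equal trees. Which physical daughter "is" the lagging strand in
successive generations is not modelled — only which daughter receives the
new mutations matters for every census and persistence statement the module
makes. The node budget (default depth ≤ 20, ~10⁶ nodes) is a plain memory
guard.

Newick export writes branch lengths as the number of new mutations on each
edge (0 on disparity leading edges) and labels nodes `n<id>_<count>`;
serialization goes through dendropy.

## Quasi-species engine

The population lives on a binary alphabet of length `L`, reduced to Hamming
error classes 0..L from the master sequence; the reduction is exact because
the single-peak landscape (master fitness σ > 1, all other classes 1) is
permutation-invariant. Replication copies each base with error probability
μ, except that a fraction `p` of replication events use an error-free
polymerase:

    M = p·I + (1 − p)·B(μ),
    B[j, i] = Σ_k  Bin(k; i, μ) · Bin(j − i + k; L − i, μ)

where `k` counts errors that revert an incorrect position and the second
factor counts fresh errors among the `L − i` correct positions. Both
directions of mutation are therefore exact; the familiar no-backmutation
closed form

    x₀ = max(0, (σ·Q_eff − 1)/(σ − 1)),   Q_eff = p + (1 − p)(1 − μ)^L

is kept only as an independent test oracle (agreement within 0.02 absolute
for L ≥ 50). Per-event mixing (each replication independently error-free
with probability p) is the minimal reading of a two-polymerase mixture and
is what yields that closed form.

Dynamics are the discrete-generation normalized update
x ← M(f ⊙ x)/‖·‖₁ rather than the continuous-time ODE; the fixed points
coincide up to time parameterization and the discrete map is easier to test.
The stationary state is computed as the dominant (Perron) eigenvector of
`M·diag(f)` by a dense eigensolve, then verified — and if necessary polished
by power iteration — to be a fixed point of the update map within `tol`
(default 10⁻¹², sup-norm). The direct solve is preferred because near the
threshold the spectral gap closes and naive power iteration stalls.

The error threshold is defined **operationally**: the strict phase
transition exists only at L → ∞, so `mu_critical` is the per-base rate at
which the stationary master-class frequency crosses ε (default 10⁻³),
located by bisection to a μ-tolerance of 10⁻⁵. Both ε and the tolerance are
parameters. Consequences used in the tests: at p = 0 the threshold solves
σ(1 − μ)^L = 1, so μ_c·L → ln σ for large L (≈ 1 for σ = e, the "one
mutation per genome per replication" rule); for σ·p > 1 the master frequency
is bounded below by (σp − 1)/(σ − 1) for every μ, so no threshold exists in
μ ∈ [0, 0.5]. A μ below 10⁻¹² is treated as exactly zero when building the
matrix (the per-genome flip probability is < L·10⁻¹²; this also avoids a
scipy instability for subnormal binomial parameters).

Defaults σ ∈ {2, e, 10} and L ∈ {50, 100} for the phase tables are package
choices of convenient desk-scale values; σ = e is singled out because it
makes the classical genome-wide threshold exactly 1.

## Strand-asymmetric genetic algorithm

Genomes are binary inclusion vectors for a 0/1 knapsack instance (weights
and values uniform integers on [1, 100], capacity 50% of total weight by
default, all seeded). Fitness is the selected value if the weight fits, else
0 — a cliff rather than a graded penalty, which makes "no feasible genome"
well-defined; a run is declared extinct after 10 consecutive generations
with feasible fraction 0. Each generation every genome produces two
daughters through independent per-bit flip channels `mu_leading` and
`mu_lagging`; truncation selection keeps the top half of the 2N daughters
(stable sort, ties broken by parent index then leading-before-lagging, so
runs are bit-reproducible given seeds). The founder population is the empty
knapsack (feasible, fitness 0) unless explicit founders are supplied. No
crossover or sexual reproduction is modelled.

The "total mutation rate" of a run is defined as the per-bit rate averaged
over the two daughters, (mu_leading + mu_lagging)/2, so parity at 4% means
(0.04, 0.04) and pure disparity at 4% means (0, 0.08); this interpretation
is recorded in run metadata and is configurable by setting the two channel
rates directly. The key mechanism is quasi-elitism: with `mu_leading = 0`
the best genome's faithful daughter always survives truncation, so best
fitness is monotone non-decreasing in every run — diversity generation with
a "guarantee of principal".

An exact dynamic program over capacity (budgeted at 10⁷ table cells) serves
as the optimality oracle; the tests additionally check it against exhaustive
subset enumeration for n ≤ 15. Default comparison conditions — n = 20 items,
N = 200, 500 generations, 20 matched seeds, average rate 4% — are desk-scale
choices at which disparity reaches the DP optimum in ≥80% of seeds and
matches or beats parity's final best in ≥80% of matched seeds; the contrast
in final best fitness widens at an 8% average rate, where parity keeps
destroying its best solutions. The historical thresholds reported for this
kind of experiment (parity extinct at 2.32%, disparity adapting at 8%)
depend on instance size, population size and selection details that are not
pinned down here; only the qualitative ordering is asserted or tested.

## Load arithmetic

`genetic_load(U) = 1 − exp(−U)` (computed as `−expm1(−U)` for accuracy at
small U), with the multiplicativity identity
L(a + b) = 1 − (1 − L(a))(1 − L(b)) holding exactly. The budget helpers are
plain products. The human per-site mutation rate is taken as 10⁻⁹ per site
per year — the only reading consistent with the standard 60–75
mutations/generation window for a 3×10⁹ bp genome and 20–25-year
generations. Display rounding is two decimals (0.89 for U = 2.2); both
published human deleterious-mutation estimates (2.2 and 3.2) are accepted
inputs, neither privileged.

## What the synthetic inputs do and do not show

All inputs are generated internally: pedigrees are deterministic, knapsack
instances are seeded uniform-random, quasi-species runs are closed-form
dynamics. Passing tests therefore demonstrate the *model's* internal claims
— persistence of genotypes under disparity replication, threshold shift and
disappearance under a fidelity mixture, monotone best fitness with a
faithful copy channel — not that real genomes behave this way. In
particular, real replication has correlated errors, finite sites,
back-mutation at the sequence level, selection within pedigrees, and
recombination, none of which are modelled; the GA's truncation selection and
infeasibility cliff are modelling choices, and the quasi-species engine is
deterministic (infinite-population), so stochastic loss of the master class
in small populations is out of scope.

## Numerical choices and limitations

- Stationary-solve tolerance 10⁻¹² (sup-norm), bisection tolerance 10⁻⁵ on
  μ, threshold criterion ε = 10⁻³; all configurable.
- Error-class matrices are dense (L + 1)²; L is capped at 1000.
- Pedigree genotypes share structure (leading daughters alias the parental
  set), but memory still grows as 2^g; depth is capped at 20 by default.
- The GA holds N constant by cycling survivors when the keep-fraction
  yields fewer than N; with the default keep-fraction 0.5 this never
  triggers.
- `ThresholdResult.exists = False` means no crossing in μ ∈ [0, 0.5]
  specifically; the search range upper bound is fixed at 0.5 because beyond
  it a binary-alphabet "copy" is anticorrelated with its template.
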