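# Methods

`phagestab` analyses how amino-acid substitutions alter two thermodynamic
phenotypes of an oligomeric viral coat protein — folding stability of the
monomer and binding stability of the pentameric subunit — and how the
substitutions fixed by selection differ from the pool of substitutions
that mutation can reach. The reference system is the φX174 coat protein F
(426 mature residues; the initiator methionine is cleaved, and residue 1
is the second translated codon). This note records the models, the
parameters that matter, and the numerical decisions taken where the
problem itself leaves choices open.

## Quantities and conventions

Both phenotypes are expressed as ΔΔG in kcal/mol relative to the
reference sequence, positive = destabilizing. For a pentamer of
`n = 5` monomers the binding free energy of one complex is

    ΔG_bind = ΔG_interaction − n·ΔG_fold

so that for a substitution, ΔΔG_fold is the difference of monomer folding
energies and ΔΔG_bind the difference of the binding energies above
(`stats.ddg_bind_from_cycle`). ΔΔG values for real data come from
structure-based calculations supplied as a tab-separated table (columns
`site, aa.from, aa.to, within.1.DNA.change, wild.phg.sub, lab.exp.sub,
ddG.fold, ddG.bind`); this package validates, analyses, and round-trips
that dialect but does not compute the energies itself.

## Mutational accessibility

A substitution is *accessible* when some single-base change of the
reference codon encodes it. Enumeration uses the standard genetic code
(hard-coded once, cross-checked against Biopython in the tests);
synonymous changes and changes creating stop codons are excluded, and
multiple mutational routes to one amino acid collapse to a single
substitution. For an L-residue protein the accessible set is therefore at
most 9L of the 19L possible substitutions; for a random coding sequence
the genetic code yields roughly 0.31·19L ≈ 5.9 per site. Only direct
single-nucleotide paths are considered — no codon-usage or
transition/transversion weighting, and no two-step paths through a stop
codon.

## Stability zones and the randomization test

A *stability zone* is a closed interval on ΔΔG around zero, by default
[−2, +2] kcal/mol with [−3.5, +3.5] as a robustness zone. Closed
membership is used because observed substitutions sit exactly at typical
zone edges in real data and an open convention would be unstable to
rounding.

The null hypothesis that observed substitutions are a random draw from
the accessible pool is tested by resampling: each of `reps` (default
10,000) replicates draws |observed| substitutions without replacement
from the pool and counts zone membership by ΔΔG_fold alone, ΔΔG_bind
alone, and jointly. The two-sided p-value is twice the proportion of
replicates with a simulated count ≥ the real count, capped at 1; ties
count toward the tail, zero exceedances are reported as `p < 2/reps`
rather than 0, and an optional (k+1)/(reps+1) correction is available
behind a flag (default off). A single seeded generator drives all
replicates, so results are exactly reproducible. The marginal counts are
hypergeometric, which the tests exploit: calibration checks allow for the
discreteness (point masses) of that distribution.

## Selection-surface estimation

The observation model: the probability that a substitution with a given
(ΔΔG_fold, ΔΔG_bind) appears among the observed set is proportional to
the density of accessible substitutions at that point multiplied by a
*selection function*, a bivariate normal with parameters
(μ_fold, μ_bind, σ_fold, σ_bind, ρ) truncated to the square
[−3, +3]² kcal/mol. The accessible density is an empirical histogram of
the pool on a 0.25-kcal/mol grid of that square (24×24 = 576 cells,
half-open cells, the boundary +3 belonging to the last cell). Selection
cell probabilities are the bivariate-normal density at cell centers,
renormalized to sum to 1 over the square — without renormalization scores
are not comparable across σ.

Fitting is an exhaustive scan over a parameter lattice: μ ∈ [−1, 1] step
0.1, σ ∈ [0.25, 1.5] step 0.0625, ρ ∈ [−0.9, 0.9] step 0.1 (ρ = ±1 is a
singular covariance, so the endpoints are pulled in). The scan is
vectorized per (σ_fold, σ_bind, ρ) triple over all μ pairs and cells; the
full ~3.7M-combination lattice evaluates in well under a minute on one
CPU, and a documented coarse lattice (μ step 0.25; σ ∈ {0.5, 0.75, 1.0,
1.25}; ρ ∈ {−0.5, 0, 0.5}) is used by the test suite and as the CLI
default. Ties break to the first maximum in lexicographic order
(μ_fold, μ_bind, σ_fold, σ_bind, ρ).

Two scores are implemented:

* `normalization="joint"` (default): the exact log-likelihood of the
  observation model. Because observation probability is *proportional*
  to acc(c)·sel(c), the per-cell probability is
  acc(c)·sel(c) / Σ_c acc(c)·sel(c), and the scan maximizes the
  weighted sum of its logs.
* `normalization="selection"`: the raw score Σ_i w_i·log(acc(c_i)·sel(c_i))
  with sel normalized over the square on its own. This is the historical
  grid procedure and is kept for comparability, but it is a
  pseudo-likelihood: its normalizer ignores how the accessible density
  reweights the sampling, so with an asymmetric pool (the realistic
  case — the pool mean is positive on both axes) its argmax is pulled
  toward the pool mean. In simulations at full scale (n = 200 draws under
  μ = (−0.5, 0.5), σ = 0.75, ρ = 0) the joint likelihood recovers μ
  within one coarse-lattice step in 20/20 seeds, usually exactly, while
  the raw score recovers in roughly half the seeds with an asymptotic
  offset of about +0.25 kcal/mol on the fold axis. The joint form is
  therefore the default.

Observations may carry integer weights (the number of distinct
experiments a substitution appeared in); weighting is linear in the
score. Observations outside the ±3 square are clamped to the nearest
boundary cell and counted in `n_clamped`; accessible cells with zero mass
that contain an observation are floored at 1/(2·|pool|) so one stray
point cannot send every score to −∞. Both policies are recorded in the
fit result and the run manifest.

## Observed substitutions and trajectories

Wild-phage substitutions are called by comparing aligned, gap-free
homologous protein sequences against their column-wise consensus (most
frequent residue; ties error by default, with an optional
first-in-alphabet policy recorded in output metadata). Laboratory
adaptations live in a YAML registry: each experiment is a rooted tree of
segments with substitution lists (compact `A123T` notation), a
temperature class (high ≥ 42 °C, normal ≤ 37 °C, otherwise variable), and
a flag for whether the line began with the reference ancestor.

Cumulative trajectories sum ΔΔG_fold and ΔΔG_bind along root-to-segment
paths starting at (0, 0); within a segment only the sum is defined, so no
per-substitution ordering is assumed. The *individual effect radius* —
the largest √(ΔΔG_fold² + ΔΔG_bind²) over single observed substitutions —
is the reference circle against which cumulative departures are judged.
Experiment weights count distinct experiments (not segments) per
substitution, after optional temperature/ancestor filters.

## Synthetic data

The generator exists so that every stage is testable end-to-end without
the structure-based energy calculations. It emulates:

* **pool geometry** — a complete 19·L table whose accessible flags come
  from a simulated coding sequence (ATG + L random sense codons) run
  through the real enumeration, so accessibility has genuine genetic-code
  structure rather than random flags;
* **effect distributions** — ΔΔG_fold and ΔΔG_bind drawn independently
  per axis from two-component normal mixtures (narrow near-zero core
  plus a long destabilizing tail; fold wider than bind), then shifted so
  the realized destabilizing fractions among accessible substitutions
  equal their targets — defaults 0.73 (fold) and 0.70 (bind), the
  majority-destabilizing pattern of the real pool. The shift is an
  empirical-quantile placement, exact to one rank. Mixture shapes are
  illustrative, not fitted;
* **observed sets** — accessible substitutions sampled without
  replacement with probability proportional to a known truncated
  bivariate-normal selection density, i.e. exactly the generative model
  the surface fit assumes; optional 1 + Poisson(0.6) integer weights;
* **experiment registries** — linear chains or complete binary trees of
  segments, temperature classes drawn from the 12/13/4
  high/normal/variable composition of the emulated corpus.

What it does **not** emulate: spatial correlation of effects along the
structure (interface vs core residues), any fold–bind correlation,
energy-function error structure, or codon-usage bias. Tests passing on
synthetic data therefore validate the statistical machinery and its
contracts, not the structural biology of any particular protein.

## Problem sizes and determinism

Default analyses use L = 426 pools (≈2,500 accessible of 8,094 possible),
10,000 randomization replicates, and the coarse lattice for routine fits
(the full lattice remains a single flag away). The test suite and the
reproduction script run the same sizes, with L = 100 for the end-to-end
pipeline fixture and n = 200 observation draws for parameter recovery.
All randomness flows from one top-level seed; per-stage seeds are spawned
deterministically from it, and repeated runs with the same seed produce
byte-identical numeric outputs.

## Known limitations

* The selection surface is assumed unimodal Gaussian on the truncated
  square; ridge-like or multimodal selection can only be approximated.
* The accessible-density grid treats cell masses as piecewise-constant;
  observations are scored by their cell, so sub-cell structure is lost.
* Consensus ancestral calling is majority-rule only — no phylogenetic
  reconstruction, no gap handling.
* Zone membership and truncation bounds are fixed conventions; results
  near the boundaries depend on the closed-interval choice, which is why
  the robustness zone is re-run by default.
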