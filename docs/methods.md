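# Methods

## Coordinates, variants, masking

All positions are 1-based on the 16,569-bp rCRS grid; the molecule is
circular, the control region wrapping the origin (16,024–16,569 ∪ 1–576)
and the coding region spanning 577–16,023. Equal-length sequences are
compared positionally; unequal lengths go through a global affine-gap
alignment (match 1, mismatch −1, gap open −8, gap extend −1 — conventional
values, configurable) before variant extraction, and a sample whose
alignment identity falls below 95% is rejected as a probable
non-mitogenome. Indels in homopolymer tracts are normalised to the 3′-most
equivalent placement, following forensic mtDNA nomenclature; `N` bases
never generate variants.

The default site mask removes the classically unreliable indels at 309,
315, 515–522 and 16,193 (indel calls only — substitutions at those
positions survive), all variants at the hypervariable hotspots 16,182,
16,183 and 16,519, and the allele-specific entries 16182C/16183C.
Masking is idempotent and order-independent; removals are counted, never
silent.

A position is called heteroplasmic when each observed allele's frequency
lies in the 31–70% band. The endpoints are treated as inclusive — the rule
is usually quoted as "between 31 and 70%" with inclusivity unspecified, and
a deterministic convention is required.

## Haplogroup classification and parsimony trees

Classification scores every node of a motif tree by the cumulative expected
derived substitutions along its root path (back-mutation tokens, marked
`!`, erase the expectation at their position): score = matched − missing,
maximised with ties broken by depth and then label. Only substitutions
participate; profiles should be masked first.

Tree building is greedy shared-variant agglomeration: the variant carried
by the largest number of unplaced haplotypes (ties: lowest position)
founds a child clade, with every variant sharing exactly that carrier set
riding the same edge; haplotypes sharing nothing with the rest hang off as
tips with their private mutations, and identical haplotypes collapse onto
one tip. On homoplasy-free data this recovers the perfect phylogeny, whose
score it provably attains (each variant appears on exactly one edge); with
homoplasy a recurrent mutation simply occurs on more than one edge, counted
once per edge. The exhaustive oracle enumerates all rooted binary
topologies ((2n−3)!! of them, refused above 8 haplotypes) and scores each
with Fitch parsimony, the root state fixed to the ancestral haplotype by
attaching it as a pseudo-leaf; the suite requires the greedy score to match
the oracle minimum on ≥95% of homoplasy-free instances and never to beat
it. Homoplasy weighting is deliberately uniform: the historical desktop
tools in this field do not document their weighting, so unweighted counting
is the reproducible choice.

A candidate internal node is proposed as a new haplogroup only when it
subtends at least five samples (counting multiplicity) and at least two
distinct haplotypes and its defining edge is not a control-region mutation
alone. Multiplicity counts toward the five-sample rule but identical
sequences count as one haplotype.

## ρ dating

ρ = (1/n) Σ n_j m_j and σ² = (1/n²) Σ n_j² m_j over the clade's edges. The
σ formula is the genealogy-weighted Poisson heuristic: treating each edge's
mutation count as Poisson(m_j), the variance of ρ is Σ (n_j/n)² m_j. On a
star genealogy this reduces to σ² = ρ/n, which the suite checks to 1e-9.
The 95% CI is ρ ± 1.96σ (z configurable; the multiplier convention behind
published ρ intervals is not always stated, so it is explicit here),
truncated at zero before clock conversion.

Conversion to years multiplies whole-genome substitutions by 3,624
years each. A purifying-selection correction is supported as a pluggable
two-column table (substitutions → years), strictly increasing, linearly
interpolated, anchored at (0,0) and extrapolated with the final slope; the
default is the uncorrected linear clock, because the published calculator's
coefficients are not part of this package's inputs.

## Likelihood machinery and ML dating

The pruning likelihood supports JC69/K80/HKY85/TN93 with arbitrary base
frequencies (empirical by default for HKY/TN93), an invariant-sites class,
and discrete-gamma rate heterogeneity with equal-probability categories and
within-category mean rates (32 categories default; 6 mirrors the "G6"
convention). The generator is normalised to mean rate 1 so heights are
expected substitutions per site; with +I the variable-class rates are
rescaled by 1/(1−p_inv) to keep the overall mean at 1. Partition
log-likelihoods (coding/control by default on full-length alignments) add.
Alignment columns are compressed to site patterns; masked positions can be
excluded from the likelihood. Correctness is pinned to JC69 closed forms,
to brute-force summation over all ancestral states on 4-tip trees, and to
tip-order invariance.

Clock fitting maximises the likelihood over node heights on the fixed MP
topology by coordinate-wise bounded scalar optimisation (each height within
[max child height, parent height], root capped at 10 substitutions/site),
sweeping to relative tolerance 1e-6 with a bounded-Brent refinement step so
wide root bounds do not limit precision, and seeded random restarts.
Non-convergence is flagged on the result, never silent. The ML age CI is
the profile likelihood on the clade-root height (1.92 log-unit drop,
nuisance heights re-optimised at each pinned value); when no bracket is
found a curvature-based normal interval is returned and flagged. BIC model
selection jointly optimises heights and free model parameters
(Nelder-Mead over log/logit-transformed rates, shape, p_inv) and counts
free parameters as model parameters plus free node heights.

## Synthetic data

The generator is the package's ground-truth instrument. Genealogies follow
the single-population coalescent for haploid (female effective) size N —
constant, exponential-growth (N(t) = N₀e^{−gt} backward in time, waiting
times by inverting the integrated rate) or piecewise-constant — with a
generation time of 25 years tying coalescent units to the clock (the
generation time is a free parameter of the analysis, not an output).
A star genealogy gives the instantaneous-expansion limit in which ρ dating
is exactly calibrated. Mutations fall per branch as
Poisson(branch years / 3,624), positions drawn proportionally to per-site
rates with the three masked hotspots upweighted ×20 (so masking
demonstrably improves dating), target alleles drawn from the substitution
model's jump probabilities; recurrent and back mutations arise naturally
and masked sites stay eligible so the mask can be tested. The default
sequence-evolution model is TN93 with transition/transversion
exchangeability 20 and human-mtDNA-like base frequencies.

The shipped reference is a synthetic 16,569-bp sequence with realistic base
composition on the rCRS coordinate grid — a stand-in, clearly labelled as
such; real rCRS-aligned data drop in unchanged. What the simulations do
not emulate: NUMT contamination, sequencing error, length heteroplasmy,
site-specific selection, and the real rCRS site pattern — so passing tests
validate the estimators' statistical behaviour, not the handling of every
artefact of real data.

The route scenario is a constructed sample table following the study
composition for the Sahul region — 635 New Guinea, 16 Bismarcks/Solomons
and 65 Australia samples, ~7% and ~3% intrusive lineages respectively, and
a 36/64 northern/southern founder split in Australia — with route
assignments taken from the published haplogroup lists (M25, M27, M28,
M29′Q, P, R14 northern; M42a, M42c, R12, S, O, M14, M15, M16, N13
southern; E, M7c3c, M73a2 intrusive; Q intrusive in Australia only, some
N13/S2 lineages intrusive in New Guinea). The counting machinery is thereby
exercised end to end against constructed truth; per-sample curated
assignments from a real panel would slot into the same tables.

## Problem sizes and numerical choices

The validation suite runs at sizes chosen to keep the statistics meaningful
on one CPU: 5,000 coalescent replicates for the E[TMRCA] closed-form check,
200 replicates each for the ρ-path oracle, the parsimony-oracle comparison
(≤6 haplotypes, 12 segregating sites) and the end-to-end ρ-CI coverage
(50-tip star clades at 60 ka), 50 replicates for BIC model recovery (3-tip
clades, 300 sites), and 12 replicates of 8-tip clades for ML age recovery.
The end-to-end coverage of the nominal 95% interval is accepted at
0.95 ± 0.05; the Wald-type interval's true coverage at these mutation
counts is ≈0.94, inside that band.

Ties are broken deterministically everywhere (lowest position, then
alleles, then lexicographic sample id); all simulation entry points take a
seed, and the pipeline serialises its config, seed and per-stage counts so
a rerun is byte-identical.

## Known limitations

- The greedy tree builder is not guaranteed minimal under heavy homoplasy;
  the exhaustive oracle bounds it only at small n.
- ML profile CIs re-optimise nuisance heights by coordinate descent; on
  large trees this is the slowest step, and the curvature fallback (always
  flagged) is a normal approximation.
- Bayesian dating (skyline tree priors, relaxed clocks) is out of scope;
  the consensus operation accepts any interval list, so externally
  computed Bayesian intervals can be intersected with ρ and ML ones.
- Route attribution is an input heuristic by design: the package counts,
  it does not infer routes from sequence data.
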