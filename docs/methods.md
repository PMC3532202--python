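# Methods

This note documents the models, algorithms, numerical choices and design
decisions behind `kdrphylo`, and what the synthetic-data tests do and do
not demonstrate about real data.

## The scientific question

Target-site pyrethroid resistance in the house fly is caused by point
mutations in the voltage-sensitive sodium channel gene (*Vssc*): L1014F
(*kdr*), L1014H (*kdr-his*) and M918T+L1014F (*super-kdr*). The intron
immediately downstream of codon 1014 (three bases after the mutation site)
is hypervariable and close to selectively neutral, so it records the
genealogy of the chromosomal background each resistance mutation arose on.
Under a single evolutionary origin of resistance, all resistant haplotypes
should be monophyletic in the intron phylogeny; under recurrent mutation
they should be scattered among susceptible lineages. The package tests
single-origin monophyly with a parametric bootstrap and counts the minimum
number of independent origins by parsimony.

## Haplotype classification

Sequences are classified from fragment-local coordinates
(`FragmentLayout`): the codon-1014 and optional codon-918 offsets plus the
half-open intron interval. Codons are translated under the standard
genetic code; IUPAC-ambiguous codons translate only if every resolution
agrees, otherwise the deduced amino acid is `?` and the allele class is
`other` — unresolvable heterozygotes are reported, never guessed.
Haplotype identity is the triple (aligned intron string, codon-918 state,
codon-1014 state); names are the class prefix plus a discovery-order
integer, and the catalog is an explicit input/output so numbering is
stable across batches. Intron-identity groups are computed on the aligned
slice with gap characters retained, because identity is defined
post-alignment.

## Substitution models and likelihood

Four reversible families (JC69, K80, HKY85, GTR), each optionally with
discrete-gamma rate heterogeneity (Yang's mean-rate discretization,
4 equal-weight categories by default; shape α > 0). Rate matrices are
scaled to one expected substitution per site per unit branch length.
Transition probabilities come from the spectral decomposition of the
π-symmetrized rate matrix; tiny negative entries from round-off are
clipped and rows renormalized.

Site likelihoods use Felsenstein's pruning algorithm over unique site
patterns (mask-aware pattern compression), with per-pattern scaling
factors shared across gamma categories to prevent underflow. Gaps and
IUPAC ambiguities are missing data (partial likelihood 1 over compatible
states). The engine caches a conditional-likelihood vector per *directed*
edge, which makes single-branch re-optimization and NNI scoring O(1)
vector operations.

Branch lengths are optimized per edge by a safeguarded Newton iteration
using analytic first and second derivatives of the edge log-likelihood,
bounded to [1e-8, 10] substitutions/site; steps are accepted only if the
log likelihood improves, and a smoothing pass visits every edge in an
Euler-tour order that keeps all cached vectors exact, so passes are
monotone in lnL. Convergence: passes repeat until the per-pass gain falls
below a tolerance (1e-2 during topology search, 1e-8 for the final polish
of a search winner).

Base frequencies are estimated empirically from the alignment with a +1
pseudocount rather than by maximum likelihood — a standard, documented
approximation. Exchangeabilities (κ or the five free GTR rates) and α are
maximized by Nelder-Mead in log space, alternating with branch-length
smoothing (two outer rounds).

Model selection minimizes BIC = −2 lnL + k ln(n) on a fixed
neighbour-joining starting topology (JC-corrected distances, scikit-bio
NJ). k counts substitution parameters (0/1/4/8 for JC/K80/HKY/GTR, +1 for
Γ) plus all 2n−3 branch lengths; n is the number of *included* sites.
Ties break toward fewer parameters. The candidate set is the 4 families ×
{no Γ, +Γ(4)} — eight models spanning the complexity axis.

## Tree search

Each search replicate starts from a random-addition tree: taxa are added
in random order, each attached to the edge that minimizes an
added-changes estimate from directed Fitch state sets (ties broken at
random). Hill climbing then repeatedly scores all NNI rearrangements —
each candidate evaluated from four cached directed vectors with only the
central branch re-optimized — applies the best improving move, and
re-smooths branch lengths; it stops when no move gains more than 1e-5 lnL
units. The best replicate is polished tightly; exact lnL ties break
toward the lexicographically smallest canonical Newick string, making
searches deterministic given a seed.

A monophyly constraint is enforced by rejection, which is provably sound
for a single constraint: starting trees are built so the constrained taxa
stay monophyletic at every addition step, and because an NNI changes
exactly one bipartition (the central edge's), a candidate move is legal
iff the constraint bipartition survives it. Model parameters are held
fixed during topology search (estimated once on the starting topology,
re-estimated afterwards as needed) — the usual speed/accuracy compromise.

Bootstrap support resamples included columns with replacement, re-runs the
search per replicate (2 starting trees by default), and reports the
percentage of replicates containing each bipartition of the focal tree.
Display trees are midpoint rooted — for visualization and origin counting
only, never for likelihood (re-rooting leaves the likelihood of a
reversible model unchanged) — and show only supports above 50%.

## The parametric bootstrap (SOWH-style) monophyly test

Observed statistic: δ = lnL(best unconstrained tree) − lnL(best
constrained tree). The two heuristic searches are *coupled*: if the
constrained search happens to beat the unconstrained one, the
unconstrained search is restarted from the constrained tree (a point of
its own space), so δ ≥ 0 by construction rather than by hope.

Null distribution: model parameters are re-fitted on the constrained
topology, `n_reps` alignments of the same (included) length are simulated
on that tree, and both searches are re-run on each replicate with the
same effort as on the observed data — equal effort keeps observed and
null statistics exchangeable, which is what calibrates the test. The
p-value is the proportion of replicate δᵢ ≥ δ_observed, ties counting
against rejection (conservative Monte-Carlo convention); when the count
is zero the result is reported as the bound "p < 1/n_reps", and the
(r+1)/(n+1)-corrected p is stored alongside. Replicates are scored with
the generating model (fitted once on the observed data's constrained
tree) rather than re-fitted per replicate; a `refit_model` switch exists,
and the single-fit default is what the type-I calibration below
validates.

## Origin counting

Two summaries per resistance class on a rooted display tree:

* **Maximal clades** — subtrees whose tips all carry the class and whose
  parent clade does not; singletons count.
* **Minimum gains** — binarize tips to focal vs rest, add a stem lineage
  above the root fixed to the non-focal state (susceptibility assumed
  ancestral), and run a Sankoff dynamic program minimizing
  (total changes, gains) lexicographically; the reported gain count is
  from that optimum, with the free-root minimum-change count
  (gains + losses) reported alongside. The stem-lineage construction is
  what makes "all tips resistant" cost exactly one gain.

Because midpoint rooting is a display convention, clade counts are also
swept over every possible root placement and reported as a (min, max)
range.

Sequential evolution of *super-kdr* from *kdr* is summarized by pairing
each *super-kdr* haplotype with the *kdr* haplotypes in its
intron-identity group; unpaired *super-kdr* haplotypes are flagged.

## Synthetic data: what it emulates and what it does not

`simulate_rooted_tree` draws a Yule (pure-birth) genealogy (DendroPy) and
rescales branch lengths to a target height — the default 0.15
substitutions/site gives intron divergences of a few percent to ~15%,
typical of a fast intron within a species. Yule rather than coalescent:
the package tests inference machinery, not house-fly demography; a
coalescent option is noted as future work.

`plant_origins` samples origin branches subject to the nesting rules
(kdr and kdr-his origins mutually non-nested; each super-kdr origin
strictly inside a kdr origin subtree) and resamples until the realized
number of maximal clades per class equals the request and at least one
susceptible tip remains, so planted truth always agrees with the origins
module by construction — that agreement is itself a tested invariant.

`simulate_vssc_alignment` builds the default 350-column fragment: a
250-column intron (evolving at the full rate under the generating model —
AT-rich HKY85, π = (0.35, 0.15, 0.15, 0.35), κ = 3), surrounding exon at
a 0.1× rate multiplier, and codons 918/1014 overwritten deterministically
from the tip's class (TTA→TTT for F, →CAT for H, ATG→ACG for T918; no
synonymous variation by default so classification truth is unambiguous).
A configurable 10% of intron columns is flagged alignment-ambiguous
column-wise; the "strict" matrix excludes them, the "full" matrix keeps
everything.

Not emulated: recombination within the fragment, selection on the intron,
sequencing error, heterozygote phasing, alignment error beyond column
masking, and population structure. Passing tests therefore demonstrate
the correctness and calibration of the *inference machinery* under the
assumed model, not robustness to those real-data complications.

## Statistical validation and problem sizes

The acceptance suite (`tests/test_acceptance.py`) fixes these desk-scale
study conditions, chosen to complete on a single core in minutes:

* likelihood vs exhaustive interior-state enumeration: trees of 2–5 tips,
  30 sites, JC/HKY/GTR+Γ, agreement to 1e-8;
* two-sequence JC69 ML distance vs −(3/4)ln(1 − 4p̂/3) at
  p̂ ∈ {0.05, 0.10, 0.20}, to 1e-6;
* heuristic search vs exhaustive topology scoring: 20 data sets of 4–6
  taxa × 500 sites, optimum reached (1e-6) in ≥ 95%;
* δ ≥ 0 on 100 random scenarios (10 taxa × 250 sites, 1–3 origins);
* type-I error: 100 single-origin null runs (12 taxa × 300 sites,
  n_reps = 20, one search start per search on both observed and null
  data), empirical rejection rate at α = 0.05 inside [0.01, 0.12];
* power: 20 three-origin runs (16 taxa × 350 sites, tree height 0.3,
  n_reps = 20, two search starts), bound "p < 1/20" in ≥ 90%;
* origin counting vs exhaustive labelings/clade scans on trees of ≤ 8
  tips, plus the 15-haplotype intron-sharing fixture (8 groups, 3
  super-kdr/kdr pairings);
* classification round trip: 100% class recovery on the default presets;
* parameter recovery: κ and α within 15% relative error in ≥ 90% of 20
  replicates (HKY+Γ truth, 16 taxa × 5000 sites).

`scripts/acceptance.py` re-runs the pipeline end to end (32-taxon
multiple-origins preset with 3 search replicates, 20×1 bootstrap, 30
SOWH replicates; 64-taxon classification preset; 12-taxon single-origin
control) and writes every headline quantity it computes as JSON.

## Known limitations

* NNI-only rearrangements can be trapped by local optima that SPR/TBR
  would escape; random-addition replicates mitigate but do not eliminate
  this, which is why per-dataset search effort is configurable and the
  SOWH test couples its paired searches.
* Empirical (not ML) base frequencies and the fixed-topology model
  selection slightly understate lnL differences between frequency-rich
  models.
* The intron-identity pairing statistic requires literally identical
  aligned introns; under the simulation model such identity is rare, so
  synthetic runs typically report zero pairings — the statistic is
  meaningful for real data where resistance mutations are recent.
* Likelihood values on real data depend on the particular sequence set
  and hand alignment analysed; the package validates the method itself,
  and its acceptance quantities are defined on synthetic data.
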