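# Methods

## Scope and data model

The package analyses a protein-coding gene family along five axes: gene
structure, sequence conservation, pairwise substitution rates, tree-wide
branch models, and duplication/fate history.  All codon-level machinery
works on the 61 sense codons of the standard nuclear genetic code; stop
codons are excluded from the state space, terminal stops are trimmed at
ingestion, and an internal stop is a hard error unless the record is
explicitly flagged as a pseudogene.  Genomic coordinates are 1-based
inclusive (GFF3 convention); ambiguity symbols count as gaps for masking
purposes.

Codon alignments are built by back-translation: each unaligned CDS is
threaded through its gapped row of the protein alignment, one codon per
residue, with translation verified position by position.  Gap handling
offers two policies — complete deletion (drop every column containing a
gap or ambiguous cell; the default for likelihood fitting, matching the
usual treatment in codon-model software) and pairwise deletion (per-pair
comparable column sets; the default for pairwise rate estimation, which
keeps per-pair information that complete deletion would discard).  The
two policies give non-comparable likelihoods, so every report embeds the
policy used.

## Gene structure

Introns are gaps between consecutive intervals of the protein-coding
region: CDS features when annotated, otherwise exons clipped to the CDS
span (introns lying wholly in UTRs are thereby excluded — the natural
reading of "introns within the protein-coding region").  Minus-strand
genes are re-sorted into genomic order before gap arithmetic, so strand
never changes a count.  Classification is an exact-match rule, default
{class I: 16, class II: 2}, anything else `unknown`.

## Conservation statistics

Percent identity defaults to matches over positions where *both*
sequences are ungapped.  That choice matters: between-class identities
in two-domain families are only meaningful on comparable positions, and
the alternative denominators (full alignment length, shorter sequence)
are provided for sensitivity analysis only.  Within- vs between-class
distributions are compared with a two-sided independent-sample t-test
(Welch by default, pooled optional).  Pairwise identities are not
independent observations, so this p-value is approximate; a
label-permutation alternative is available but off by default, since the
t-test is the procedure in standard use.  Catalytic-site conservation is
*absolute*: a reference residue (mapped through the reference row's gaps
to its alignment column) counts as conserved in a class only if every
member of that class carries it.

## Pairwise dN/dS

NG86 counts fractional synonymous sites per codon position as
(synonymous one-step neighbours)/(viable one-step neighbours), with
mutations to stop codons excluded from the viable set, so S + N = 3L
exactly.  Codons differing at several positions are resolved by
averaging over all minimal mutational pathways that avoid stops, equally
weighted; proportions are corrected with the one-parameter formula
d = −3/4 ln(1 − 4p/3).  ω is flagged `undefined_dS0` when dS = 0 (never
reported as infinity) and `saturated` when p ≥ 3/4; pairs with dS > 3
are additionally excluded from scatter reports.

The YN00-style estimator keeps this counting skeleton but weights both
site fractions and pathways by target-codon frequency and κ.  Pathway
weights are κ^(transitions) × the symmetrized product of target
frequencies over the two reading directions, which makes the estimate
exactly invariant to swapping the sequences.  κ defaults to the K80
estimate at positions fourfold-degenerate in both codons (falling back
to 2.0, flagged, when data are too sparse); codon frequencies default to
F3x4 computed from the pair.  Two deliberate design choices differ from
the PAML yn00 program: pathway weights exclude ω (including the quantity
being estimated in its own counting weights adds circularity for little
gain at family-typical divergences), and the distance correction keeps
the one-parameter NG86 form rather than an HKY-based one.  Together
these make the estimator collapse *exactly* onto NG86 in the
equal-frequency κ=1 limit — a property the test suite checks to 1e-6 —
at the cost of slightly under-using the transition/transversion
structure in the correction step.  The κ/ω update loop runs to a fixed
point; because ω does not feed back into the weights, convergence is
immediate and the loop exists to surface non-convergence flags on
pathological inputs.

The domain comparison computes, per unordered sequence pair, ω
restricted to the TPS and TPP column blocks (pairwise deletion within
each block), flags undefined entries rather than dropping them, and
applies a paired two-sided t-test to (ω_TPP − ω_TPS) over pairs with
both estimates defined.

## Branch models

The GY94 rate matrix assigns `q_ij = π_j κ^[ts] ω^[nonsyn]` to
single-nucleotide codon changes and 0 otherwise, satisfies detailed
balance, and is normalized so branch lengths are expected substitutions
per codon.  Equilibrium frequencies come from the alignment (equal,
F1x4, F3x4, or empirical codon frequencies; default F3x4, floored at
1e-6 and renormalized).  Transition matrices are computed by
eigendecomposition in the π^1/2-symmetrized basis, which also yields
Q·P(t) cheaply for gradients.

Likelihoods use Felsenstein pruning over site patterns with per-node
rescaling.  Branch-length derivatives are analytic: a pre-order pass
propagates "outer" partials with their own log-scales, so the gradient
is exact under scaling; κ and ω derivatives use forward differences.
Trees are derooted (basal bifurcations collapsed) before fitting so the
2n−3 free edges are identifiable; by reversibility the likelihood is
invariant to the virtual root, which the tests verify directly.

The one-ratio model shares ω across the tree; the two-ratio model gives
a designated foreground clade — all edges whose child-side leaves lie in
the clade, including the stem edge — its own ω.  Fits maximize over κ,
the ω values and all branch lengths with bounded L-BFGS-B (ω ∈ [1e-6,
50], κ ∈ [1e-3, 100], t ∈ [0, 50]), multi-start with seeded lognormal
perturbations (default 3 starts for standalone fits).  In the LRT suite
the two-ratio fit is warm-started from the one-ratio optimum: this
guarantees lnL₁ ≥ lnL₀ up to optimizer noise, speeds convergence, and
empirically calibrates the null distribution of 2Δℓ to χ²(1).  Branch
lengths are re-optimized under each model, the statistic is clipped at 0
when the alternative lands marginally below the null, and df = 1 for
every two-ratio vs one-ratio comparison (one extra ω).  Nesting is
verified by a digest of the alignment content and tree bipartitions, so
rerooted copies of the same problem still compare.

## Family-level analyses

JTT pairwise distances maximize Σ log(π_a P_ab(t)) over t ∈ [0, 10]
under the Jones–Taylor–Thornton empirical amino-acid model on
both-ungapped columns.  Neighbor-joining is deterministic (Q-criterion
ties break toward the lowest index pair) with negative branch estimates
floored at zero; bootstrap support is column resampling with a seeded
generator, scored as the percentage of replicate trees containing each
split of the point estimate.

"Recently duplicated pair" is operationalized as a same-species cherry;
polytomies containing candidate leaves are reported unresolved rather
than auto-paired.  The minimum ancestral-gene count at the monocot–dicot
split finds maximal single-side clades, merges sister clades of opposite
sides into one orthologous group, and counts groups; pruning a whole
group reduces the count by exactly one.  Mechanism calls: tandem when
two genes share a chromosome within 100 kb (configurable; there is no
universal threshold, and known tandem pairs are typically adjacent),
otherwise the kind of any matching paralogous-block entry
(whole-genome-duplication block or segmental), otherwise unknown —
missing coordinates are never an error.  Fate calls over conditions
assayed in both genes: both expressed everywhere → shared; exactly one
silent everywhere → nonfunctionalization candidate; one broad and the
other a strict nonempty subset → subfunctionalization candidate;
anything else (including both silent) → divergent.  External evidence
such as EST hits is carried as flagged annotation, never mixed into
assay calls.

## Synthetic data and study conditions

The simulator evolves codon states down a fixed tree: root states drawn
from π, each edge applying exp(Q·t) with its branch class's ω; domain
blocks are contiguous column ranges with their own ω (TPS block first,
matching the N-terminal TPS / C-terminal TPP architecture).  Gene-model
fixtures use exon lengths 60–300 nt (total a multiple of 3), intron
lengths 80–2000 nt, and both strands.  Expression fixtures realize each
prescribed fate pattern and then flip calls independently with the noise
probability.  Every generator is a pure function of spec + seed.

The standard verification experiments (in `tpsevol.studies`, driven by
both the test suite and `scripts/acceptance.py`) use: a balanced 8-taxon
tree of root-to-tip depth 0.5 (total depth 1.0 substitutions/codon) —
small enough to fit quickly, deep enough to be identifiable; 300 codons
and 200 replicates for the LRT null calibration (rejection at the χ²(1)
5% cutoff expected in [0.02, 0.09]); 500 codons and 20 replicates for
the ω = 0.065 vs 0.35 clade-contrast recovery (medians within ±30%,
correct ordering in ≥95%); and a 20-taxon tree of depth 0.4 with
500 + 300 codon domain blocks at ω 0.08/0.14 for the paired-test power
study (50 replicates, p < 0.01 expected in ≥90%).  Generating codon
frequencies are uneven F3x4-style products with mild GC structure rather
than uniform, so frequency estimation is genuinely exercised.

What the generator does *not* emulate: indels and alignment error,
recombination, rate variation among sites within a domain block,
selection on silent sites, and base-composition heterogeneity across
lineages.  Passing tests therefore demonstrate correctness of the
estimators under their own model assumptions and the stated study
conditions — not robustness to model violation in real data.

## Numerical choices and degenerate inputs

Eigendecomposition tolerances: transition-matrix rows sum to 1 within
1e-10, small negative entries are clipped at 0.  Optimizer: L-BFGS-B
with ftol 1e-12 and projected-gradient tolerance 1e-7; non-convergence
after all starts returns the best iterate with `converged=False` and a
warning rather than raising.  Identity with no comparable positions,
empty alignments after masking, unmapped class labels, mismatched
tree/alignment ids, and non-nested LRT inputs all raise typed errors.
Zero-variance t-test inputs with equal means return t = 0, p = 1.  A
degenerate frequency vector (all mass on one codon) fails rate-matrix
normalization explicitly.

## Known limitations

Pairwise ML estimation (codeml runmode −2), site and branch-site models,
and ML topology search are out of scope; topologies are supplied or
built by NJ.  The YN00-style estimator's one-parameter correction mildly
underestimates distances at high divergence relative to HKY-corrected
variants; saturated pairs are flagged rather than rescued.  The
ancestral-lineage merge rule reproduces the minimum-count reasoning for
clean trees but does not perform full gene-tree/species-tree
reconciliation.  The expression-fate rules are deliberately strict
(absolute definitions of "broad" and "shared"); under call noise their
recovery is bounded by the exact enumeration computed in the test suite
(~74% at 5% noise with 6 conditions), which is why fate calls on noisy
real data should be read as candidates, not conclusions.
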