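# Methods

`dupsel` infers selection histories of duplicated genes from in-frame codon
alignments, a phylogeny, and within-species haplotype samples, and maps the
resulting evidence to duplicate-gene retention modes. This note records the
models, the numerical choices, and what the synthetic-data generators do and
do not emulate.

## Codon counting primitives

Synonymous/nonsynonymous arithmetic follows the Nei–Gojobori conventions.
Between two codons, all orderings of the differing positions are enumerated
as minimal mutational pathways; pathways crossing a stop codon are
discarded and the per-pathway synonymous/nonsynonymous step counts averaged
over the survivors, so the two counts always sum to the Hamming distance.
When every pathway crosses a stop (possible for a few three-difference
pairs) the counts fall back to averaging all pathways with stop steps
scored as nonsynonymous, and a warning flag is set; this keeps counts
total-preserving. Site denominators count, per codon position, the fraction
of the three possible single-base changes that are synonymous, with changes
to stops scored as nonsynonymous so each codon contributes exactly three
sites. For a two-sequence comparison the denominators average the two
per-sequence totals.

A known artifact of pathway counting is that codon pairs encoding the same
amino acid but reachable only through multi-step paths (e.g. CGT/AGA, both
arginine) receive fractional nonsynonymous counts even under purely
synonymous evolution; the protein-level identity, not the pathway split,
is the exact invariant. Columns containing gaps or ambiguity codes are
excluded from all counts. The standard genetic code is the default; any
code table can be injected.

## Codon substitution models

The substitution process is the Goldman–Yang codon model: instantaneous
rates are zero for multi-position changes and stop targets and otherwise
proportional to the target codon frequency, multiplied by the
transition/transversion ratio κ for transitions and by ω for
nonsynonymous changes. Codon frequencies default to F3×4 computed from the
alignment with a pseudocount of 0.5 per nucleotide per position (so small
alignments never produce structurally zero frequencies); `equal` and `F61`
modes are available.

Two model families are implemented:

- **M0**: one ω shared by all sites and branches.
- **Branch-site Model A**: four site classes with proportions
  (p0, p1, p2a, p2b), the class-2 mass split proportionally to p0:p1.
  Background branches see ω0 (class 0/2a) or 1 (class 1/2b); designated
  foreground branches see ω2 on classes 2a/2b. The alternative model
  estimates ω2 ≥ 1; the null fixes ω2 = 1.

Rate matrices are normalized so that branch lengths are expected
substitutions per codon; for the branch-site mixture the normalization uses
the background-class mixture rate, which is identical between the
alternative and null models (so the LRT compares like with like). The
likelihood is computed by Felsenstein pruning over the 61 sense-codon
states with site-pattern compression and per-node rescaling; columns with
gaps or ambiguity in any tree tip are dropped. Because the model is
reversible, the likelihood is invariant to root placement; the engine
exploits this by rerooting at the foreground branch's parent so the four
site classes share the two background prunings. Transition matrices come
from one symmetric eigendecomposition per distinct ω (in the π-symmetrized
basis), reused across branch lengths and rate scalings.

## Fitting and the branch-site test

Maximization is bounded quasi-Newton (L-BFGS-B) on transformed parameters:
log κ, logit ω0, log(ω2 − 1), class-proportion logits, log branch lengths;
the lnL convergence tolerance is 1e-8. `fit` uses three starts by default
(one heuristic, the rest seeded perturbations); exact lnL ties keep the
earliest start. The branch-site test estimates branch lengths once under
M0 and holds them fixed in the constrained null/alternative fits, which
are warm-started (the alternative from the null's MLE), with one
additional cold start each. This is a deliberate trade: it makes
200-replicate calibration studies tractable and, because both constrained
models share the same branch lengths, it biases the LRT statistic slightly
downward (conservative). Fully free branch lengths remain available
through `fit`.

The LRT statistic 2(lnL_alt − lnL_null) is clipped at zero and referred to
χ² with one degree of freedom. The asymptotically correct null is a 50:50
mixture of a point mass at zero and χ²₁; the χ²₁ convention is the
conservative choice and is the default (the mixture is available via
`null_distribution_p(..., convention="mixture")`). Scans over a branch set
share the M0 fit and adjust raw p-values jointly with Holm–Bonferroni.
A "branch" in a test may be a set of branches marked jointly — e.g. a
daughter-gene lineage (stem plus descendant branches) after a duplication.

Site-class posteriors are naive empirical Bayes at the MLEs: per site,
P(class | data) ∝ p_c L_c(site). No hyperprior integration over parameter
uncertainty is performed; posteriors are therefore anticonservative near
boundary estimates and should be read as descriptive.

## Ancestral reconstruction

Marginal reconstruction reroots the tree at the target internal node
(valid under reversibility) and combines the incident subtree partials
with the stationary prior; for branch-site fits the posterior marginalizes
over site classes at their estimated proportions. The MAP codon is
reported per site with its posterior; exact ties break to the
lexicographically smallest codon and are flagged. Columns dropped from the
likelihood are emitted as gaps. Joint (pathwise) reconstruction is not
implemented; downstream MK counting consumes marginal MAP sequences.
Rooted binary inputs are first converted to a canonical unrooted form
(basal bifurcation collapsed) so that the fake root edge is never double
counted; a node that coincides with the collapsed root maps to the same
point of the unrooted tree.

A reconstruction suite fits several constrained models (e.g. M0, the
branch-site alternative and null at a key branch) and reconstructs the
same node under each; members whose fits fail to converge stay in the
suite flagged.

## McDonald–Kreitman framework

Polymorphism: per codon column, the distinct alleles are connected by a
minimum-total-change spanning tree (Hamming weights, deterministic
lexicographic tie-breaks) and pathway counts are summed over its edges.
Divergence: only columns fixed within the sample are compared with the
reference (the classic MKT convention; segregating columns count as
polymorphism only). Divergence counts are Jukes–Cantor corrected per
class — d = −(3/4)·ln(1 − 4p/3) applied to p = count/sites with NG site
denominators averaged between the sample consensus and the reference —
while polymorphism counts are left uncorrected. Saturation (p ≥ 0.75)
raises an error naming the class.

The test reports NI = (Pn/Ps)/(Dn/Ds) and the Pearson χ² of the 2×2 table
without continuity correction (the uncorrected statistic reproduces the
published GSS table values; a Yates-corrected one does not), with the χ²₁
upper tail as p-value. NI is flagged undefined when Ps, Ds or Dn is zero
rather than reported as 0/∞. Against a reconstruction suite, each member
serves as the reference and the report carries per-cell min–max ranges
with NI as "≤ max" and χ² as "≥ min" (p at that minimum) — a conservative
bound convention. Pairwise gene comparisons pool the two samples'
polymorphism cells and count divergence at columns fixed in both samples.

Rounding in reports: NI to 2 decimals, χ² to 1, p to 3; JSON artifacts
keep full precision. When recomputing published table statistics from
rounded printed counts, the last decimal of χ² can differ (e.g. the first
pairwise GSS row recomputes to 18.8 where 19.0 was printed); the package
asserts only the rows that reproduce exactly.

## Retention classification

The classifier is a pure decision table over per-daughter selection
evidence (adjusted p ≤ α, default α = 0.05) and user-supplied function
states: NF when exactly one daughter is under positive selection and the
quiet copy retains the ancestral function; EAC when both are positive and
one function is ancestral; CN when both are positive and both functions
novel; everything else — including any unknown annotation — degrades to
SF-or-ambiguous with explicit caveats. A failed positive-selection test is
reported as "no evidence of positive selection", never as affirmative
purifying selection, and functions are annotations (they come from assays),
never inferred from sequence.

## Synthetic data

`simulate_alignment` draws each site's class from the class proportions,
draws root codons from π, and propagates states down the tree with
class- and branch-appropriate transition matrices under the same rate
normalization the likelihood engine uses, returning tips plus the true
per-site classes. `simulate_population_sample` overlays Poisson-distributed
single-base polymorphisms on a base haplotype at separate synonymous and
nonsynonymous intensities (per codon), assigning each derived allele to a
uniform nonempty proper subset of haplotypes; `simulate_divergent_reference`
applies fixed substitutions to the base the same way. Changes creating
stop codons are rejected (and, for rare double-mutant combinations within
a haplotype, skipped for that carrier). There is no coalescent genealogy,
recombination, demography, or codon-usage evolution: the generators
reproduce the count structure the tests consume, so calibration results
say nothing about linkage or frequency-spectrum effects in real data.

The scenario presets place a duplication on a six-taxon tree: two
daughter-gene clades (stems 0.3 with two descendants at 0.25 each) and an
outgroup pair. Selection presets put ω2 = 4 on ~10% of sites (p0 = 0.72,
p1 = 0.18, ω0 = 0.2, κ = 2) along a daughter lineage — the stem and its
descendant branches marked jointly, reflecting episodic selection that
continues in the daughter gene after duplication. Branch lengths were
chosen so a daughter lineage carries enough substitutions for the
branch-site test to be well powered while individual branches stay far
from saturation. With these presets (300 codons) the test's type-I error
under ω2 = 1 is well below nominal (the χ²₁ convention is conservative)
and power against the ω2 = 4 regime is above 80%.

Calibration study sizes (200 null replicates, 100 power replicates, 20
M0-recovery fits, 100 MK replicates at 400 codons with 24 haplotypes) are
the package's standing acceptance conditions and run in roughly a quarter
hour on a single core.

## Known limitations

- Branch lengths fixed at M0 estimates in the branch-site LRT (see above);
  power is mildly reduced relative to fully free fits.
- Naive empirical-Bayes site posteriors ignore parameter uncertainty.
- The MK counting convention is NG-style and isolated in `dupsel.codon`;
  alternative conventions (e.g. transition-weighted) can be swapped in
  behind the same interface.
- The population simulator's uniform allele-frequency assignment is not a
  coalescent frequency spectrum; rare-variant-driven biases of the MKT
  cannot be studied with it.
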