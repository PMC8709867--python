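# Methods

This note records the models, conventions, and numerical choices behind
`genedecay`, and what the synthetic-data tests do and do not establish.

## Gene models and disruption scanning

A gene is an ordered list of coding exons.  Exon *k*'s **phase** is the
number of its 5'-terminal bases that complete a codon begun in exon *k−1*
(exon 1 has phase 0; phase(k+1) = (3 − cumulative length mod 3) mod 3).
Mutation records use exon-local, 1-based coordinates on the coding strand.
Insertions are anchored "after base p", with p = 0 meaning before the first
base.  Codon-anchored records resolve through the phase: substitutions and
deletions to the codon's first base, an insertion "at codon position n" to
the gap after codon *n* (so "between the 11th and 12th codon" is codon
position 11).  This matches how comparative pseudogene catalogs are written.

Scanning aligns each observed exon to its reference exon globally with
affine gaps (match +1, mismatch −1, a gap of length L costs 4 + L).  Gap
placement in repetitive context is inherently ambiguous, so every indel —
detected or catalogued — is **left-normalized** (shifted to its leftmost
equivalent placement) before comparison; contiguous mismatch runs merge into
one substitution record.  Two limits are worth knowing: an inserted string
that happens to copy its flanking context cannot be distinguished from a
shifted copy by any aligner; and two indels separated by only 1–2 matching
bases can tie with a single larger edit under any affine scheme.  The
round-trip guarantee (scan ∘ apply = identity) therefore holds for
well-separated edits, which is what real decay catalogs contain.  Exons
aligning at < 50% identity are flagged unalignable and excluded from
mutation calling.

Premature stops are called by translating the full spliced observed sequence
in frame 0 — indels upstream shift the frame downstream automatically, which
is exactly the biology.  A destroyed terminal stop is recorded as stop-loss
but does not by itself mark the gene disrupted.  **Status rules**: disrupted
iff ≥ 1 premature stop, or terminal cumulative frame offset ≢ 0 (mod 3), or
start codon lost; missing iff no sequence was supplied.  Exons shorter than
3 bases after edits still contribute their bases to the spliced frame.

## Loss events and branch labels

Mutation identity across species is equality of (exon, kind, resolved
position, length, alt) after left-normalization, extended by containment:
a record of the same kind and anchor whose edit contains another's counts as
the shared mutation plus a private extension (this is what keeps a lineage
that later extended a shared 2-base insertion to 5 bases inside the shared
event).  Species are grouped transitively; each group's event attaches to
the stem branch of its MRCA (terminal branch for singletons).  Sharing
across a non-monophyletic set is flagged homoplastic but never split,
following the one-origin, no-reversal (Dollo) assumption, which is
hard-coded.  Labeling sets event branches *mixed*, their descendants
*pseudogenic*, everything else *functional*; two events nested on one
root-to-leaf path are an error because a lineage cannot lose a gene twice.

Species with relaxed-selection or expression evidence but an intact ORF are
deliberately *not* events; the fixtures carry them as `putative_losses`.

Gene-order comparison is adjacency-level only: a reference adjacency is
retained iff the two genes are adjacent in the query, in either order, on
the same chromosome.  Maximal retained runs are located in the query, and
runs on a different chromosome than the run holding the first reference gene
are reported as moved segments.  No rearrangement-mechanism inference is
attempted.

## Codon model

MG94×HKY on the 61 sense codons: q_ij = 0 unless codons differ at exactly
one position, otherwise proportional to the target codon frequency π_j,
times κ for transitions and ω for nonsynonymous changes.  Matrices are
normalized to unit expected rate, so branch lengths are expected
substitutions per codon (codeml's convention).  π is F3x4 by default (equal
and F1x4 selectable), estimated with a one-count pseudocount per nucleotide
and position so no sense codon gets zero mass.  Stop codons inside
pseudogenic rows are recoded as missing data, keeping the state space at 61;
gaps and ambiguities are missing (all-ones partials).

Likelihoods use Felsenstein pruning over compressed site patterns with
per-site rescaling.  The reversible structure gives a symmetric
eigendecomposition per category (eigenvalues clipped at 0 to kill positive
round-off), so all branch transition matrices cost two matrix products each.

**Fitting.**  Bounded L-BFGS-B on log-parameters, started from the best
point of a κ ∈ {1, 2, 5} × ω ∈ {0.1, 0.5, 1.5} grid, restart budget 5,
tolerance 1e-6 on the log-likelihood.  Two branch-length modes:

* `free` — one length per branch (codeml-like).
* `clock` (default for dating) — a single synonymous rate μ (substitutions
  per codon per MY) shared by all branches; a branch in category ω gets
  length μ·T·(S + ωN)/S, where S and N are the synonymous and nonsynonymous
  flux potentials at ω = 1.  This encodes the biological premise behind the
  dating method — selection changes dN, not dS — and cuts the parameter
  count to (μ, κ, one ω per category), which is what makes the
  simulation-based calibration affordable.

The relaxation LRT compares one shared ω against a separate foreground ω
(df = 1, χ²₁ p-values; the 50:50 boundary mixture is available but off by
default, since the foreground ω is interior under the null).  An auxiliary
test of foreground ω fixed at 1 against free is reported alongside.

Likelihood invariance is tested under leaf relabeling; re-rooting invariance
is not tested because the tree container enforces ultrametricity and
re-rooting a clock tree along a branch breaks it.

## Dating

With functional dN/dS ω_f (< 1), mixed-branch dN/dS ω_m, branch duration T,
and synonymous-rate ratio r = s_p/s_f, equating nonsynonymous accumulation
across the two portions under ω_p = 1 gives

    t_p = T (ω_m − ω_f) / ( r (1 − ω_m) + (ω_m − ω_f) ),

the 1ds model being r = 1 and the 2ds model using
r̂ = (mean dS/MY on fully pseudogenic branches)/(same on functional
branches), defaulting to 1 when no pseudogenic branches exist.  ω_m outside
[ω_f, 1] is clamped to the interval and flagged (sampling noise routinely
pushes ω_m past 1 on short branches; the mixture premise caps it).
Inactivation age = child-node age + t_p, because the pseudogenic portion is
the most recent part of the branch.  Reported ranges are the min/max over
the two models only; an optional seeded site bootstrap provides intervals
when asked for.  ω_f ≥ 1 is an error: dating is undefined without purifying
selection in the functional class.

## Trait association

The retention model is a two-state Markov process on the tree whose
stationary probability at tip *i* is logit⁻¹(β₀ + β₁ x_i) and whose total
switching intensity is α per unit of normalized patristic distance, so tip
correlation decays as exp(−α d̂_ij).  Two estimators:

* `mple`: maximizes Bernoulli log-likelihood + ½ logdet(X' A^{1/2} R⁻¹
  A^{1/2} X), with A = diag(p(1−p)) and R = exp(−α D̂).  On a star tree
  (R = I) this is exactly Firth-penalized logistic regression, so estimates
  stay finite under separation.
* `ig10`: damped quasi-score iterations solving X' A^{1/2} R⁻¹ A^{−1/2}
  (y − p) = 0.

α is profiled on a 13-point log grid over [1e-4, 1e4] and refined, using a
REML-flavoured Gaussian pseudo-likelihood of standardized residuals (the
logdet(X'V⁻¹X) term stops an equicorrelation component from re-absorbing
what the intercept explains); boundary hits are flagged.  On an exact star
phylogeny the exchangeable correlation is confounded with the intercept, and
the identified limit α = ∞ (independence) is used directly.  p-values for
β₁: parametric bootstrap (default 499 replicates, seeded) of the
*studentized* slope under the fitted intercept-only null — studentizing
matters because near-separation replicates otherwise fatten the null tail —
with α held at its null estimate across replicates; a Wald p-value is
reported as cross-check.

A caveat the simulations make explicit: under strong phylogenetic inertia
(small α), tip retention tracks ancestrally smoothed trait values, and the
marginal tip-level slope is attenuated for *any* estimator — consistency of
β̂₁ is a property of the fast-switching regime, and the recovery test runs
there.

Ancestral continuous states are the BM generalized-least-squares solution of
the edge-weight (1/branch-length) Laplacian — each internal node the
weighted average of its neighbours — which keeps every estimate inside the
convex hull of the tip values.  The Brownian rate comes from independent
contrasts; per-node variances from the inverse internal-block Laplacian.
Fiber components (white/pink/red) are estimated independently and
renormalized to sum to 100 (an isometric log-ratio treatment was considered
and left out: the renormalized componentwise estimates are what the standard
pie-chart figures show).  Zero-length branches are perturbed by 1e-8 with a
warning.

## Synthetic data: the stated world

The simulator evolves codons site-independently along the tree with a
synonymous molecular clock of **0.005 synonymous substitutions per codon per
MY** (vertebrate nuclear genes run at roughly 1–3 per-site substitutions per
thousand sites per MY; this default keeps 50–100 MY trees informative
without saturation), κ = 2.5, equal codon frequencies, functional ω = 0.15.
Substitutions are simulated exactly (per-site Gillespie), and realized
synonymous/nonsynonymous counts per branch are recorded as ground truth.  At
a loss point the lineage switches to neutral nucleotide-level HKY with the
same total rate as the ω = 1 codon process — stop codons can now arise and
are retained in emitted sequences — and indels start accruing at 0.002
events per codon site per MY (geometric lengths, p = 0.5; none before loss:
catalogued indels are post-loss decay).  Deleted codon sites appear as
missing data in the reference-frame alignment; insertions appear only in
emitted sequences.  Trait tables use reflected Brownian motion on [0, 100]
for white fiber (root 40, tip SD ≈ 20), the remainder split 60:40
pink:red with noise, and retention from the two-state model above with
default α = 3 (moderate inertia — enough signal to matter, rarely a
constant-retention draw at n ≈ 20).

The fixtures are *engineered*, not real, sequences: four-exon references
built from T-free filler codons (no stop can arise from filler in any
frame) with the catalogued target codons placed at their printed coordinates
(exon-2 phase 2 for the bird/felid references, which is what makes the
printed chicken, quail and cheetah coordinates mutually consistent), and TAA
triplets planted on the shifted-frame codon boundaries of each disrupted
species so that every described consequence — which exons gain premature
stops — is realized and programmatically verified at build time.  What a
green fixture test establishes is that scanning, coordinate arithmetic and
event clustering reproduce the catalogued biology; it says nothing about
alignment quality on diverged real sequences.

Simulated alignments likewise idealize: no rate variation among sites or
lineages, no codon-usage bias, no alignment error, and the labeled-chain
dating tests start from the true tree.  The end-to-end recovery numbers
(median |error| ≈ 1.5 MY on a 30 MY mixed branch at 300 codons) are
therefore a best case; real data add alignment and tree uncertainty.

## Pipeline

`pipeline.run()` executes scan → events → labeling → (ω fitting → dating,
when an alignment is supplied) → trait association, writes TSV/JSON
artifacts without timestamps (reruns are byte-identical), records the seed
and all option defaults in the report, and surfaces numerical warnings
(ω_m clamps, α boundary hits) in the report rather than only in logs.
Events without a fitted ω_m are reported "undatable" rather than dropped.

## Known limitations

* Event assignment is parsimony, not probabilistic; convergent identical
  indels across clades are flagged homoplastic, not resolved.
* The clock fit assumes equal synonymous rates across lineages; lineage rate
  variation biases 1ds dates (the 2ds option absorbs only a
  functional-vs-pseudogenic rate difference).
* The codon model has no site-heterogeneity (no gamma rates, no branch-site
  classes) and no RELAX-style selection-intensity parameter.
* The regression supports one predictor plus intercept, matching its use;
  compositional predictors should be reduced to one component first.
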