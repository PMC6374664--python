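# Methods

This note documents the models, conventions and numerical choices
behind `driftdiet`, in the order data flows through the package.

## Sequence processing

**Screening.** Unique primer-trimmed sequences are screened on three
rules: trimmed length above 175 bp (longer than the expected V9
amplicon), any single-base run of ≥ 8 bp (a homopolymer signature of
sequencing error), and dataset-wide singletons. A sequence violating
several rules is counted once, under the first rule in that order, so
per-rule rejection counts sum to the total removed.

**OTU clustering.** Sequences are clustered greedily in descending
abundance order (ties broken lexicographically): each sequence joins
the first existing centroid within 2 edit operations, else founds a new
OTU. Edit distance is Levenshtein (substitutions and indels counted
equally, computed with `edlib`), since a "≤ 2 bp difference" criterion
does not distinguish the two for near-identical amplicons. The
procedure is deterministic; on data where true groups are well
separated (> 5 edits) and variants sit within 2 edits of their
most-abundant centroid it provably coincides with single-linkage
connected components, which the tests verify against an exhaustive
union-find oracle.

**ESU assignment.** An OTU is assigned to the ESU of its best-identity
reference when identity ≥ 0.95, where identity = 1 − edits/OTU length
and the alignment must cover the whole OTU (end-gaps free only on the
reference side; `edlib` infix mode). Ties on identity go to the
most-abundant reference's ESU, then lexicographically — an arbitrary
but deterministic convention. Non-bilaterian ESUs are carried through
assignment but never counted as prey (microbial hits in gut contents
are parasites or incidental ingestion rather than diet).

**Rarefaction.** Samples are subsampled without replacement
(multivariate hypergeometric) to a common depth of 1950 reads; samples
below the depth are discarded, never padded, and logged with reason
`LOW_DEPTH`. Rarefaction curves are Monte-Carlo means of observed
richness; the hypergeometric closed form
Σᵢ (1 − C(N−nᵢ, d)/C(N, d)) is implemented as an independent check.

**Diet matrix.** Per sample, the predator's own ("self") ESUs and all
non-bilaterian or unassigned features are removed. Self ESUs are
declared per predator species in the taxonomy, so taxonomically close
predators share a self ESU and reads from one predator's taxon remain
countable prey in samples from unrelated predators. A sample whose
remaining prey reads number fewer than 20 (1% of the rarefied depth) is
excluded as a likely empty stomach — reason `ALL_SELF` when no prey
read remains at all, else `LOW_PREY`. The prey-read threshold is
applied after non-bilaterian removal, i.e. to true prey reads only.
Surviving rows are normalized to prey proportions; every excluded
sample appears exactly once in the exclusion log with a
machine-readable reason code.

## Amplification bias

The relative correction factor RCF_t = (S_t/S_m)·(B_m/B_t) is a pure
odds ratio; it makes no mechanistic claim about rRNA copy number or
primer mismatch. On two families RCF₁·RCF₂ = 1 exactly. When several
mock replicates are available, per-replicate RCFs are averaged
arithmetically by default (a geometric mean is exposed as an option;
note the two differ because the estimator is nonlinear, which is also
the likely origin of small inconsistencies one finds between published
RCF columns and their published mean inputs). Families that cannot be
distinguished at the locus must be merged (`merge_families`) before
computation. A family with zero biomass but nonzero sequences has no
defined odds ratio and is flagged rather than given a number.
Correcting diet proportions (`apply_rcf`: divide by RCF, renormalize)
is offered as an optional step; the main analyses operate on
uncorrected proportions.

## Drift survey and availability

Nightly family counts from 5% cod-end subsamples convert to grams as
count × individual dry mass (mg) / subsample fraction / 1000; taxa
counted in full use fraction 1. Family biomass sums into ESUs (biomass
is conserved exactly), and period averages are arithmetic means across
that period's nights, one value per night. Availability vectors n are
biomass proportions over the surveyed ESUs; zero biomasses are floored
at 0.001 of the night's total before normalization so that prey seen in
diets but absent from one night's nets keep a finite Manly ratio. The
floor preserves ranking, keeps the index defined, and is flagged in the
output; 0.001 is an arbitrary small constant and results for floored
ESUs should be read qualitatively.

## Overlap, permutation inference, selectivity

Diets are pooled per species × period by summing rarefied prey read
counts and renormalizing — at equal rarefaction depth this weights fish
near-equally; a mean-of-proportions alternative is exposed for
sensitivity analysis. Schoener's α is computed between every species
pair within each period; pairs missing from either period are dropped
from the paired analysis (complete-pairs) and logged.

The paired test flips each pair's (drift, postdrift) labels
independently with probability ½ per iteration — not a single global
flip — matching exchangeability of period labels within a pair. The
statistic is the mean over pairs of (postdrift − drift), so decreased
overlap is negative. The p-value uses the add-one convention
(1 + #extreme)/(N + 1) and is two-sided by default; sidedness is
configurable since the convention is not universal. With the default
99,999 iterations the Monte-Carlo p is stable to about ±0.002 across
seeds.

Manly's α is computed per species × sampling day from the day's mean
per-sample proportion vector, restricted to the surveyed ESUs and
renormalized (α is invariant to rescaling of n, so renormalizing
availability over the surveyed set changes nothing but the reported
n_i). Chesson's ε rescales α to [−1, 1]; it is strictly increasing in
α (derivative (2m−2)/((m−2)α+1)² > 0) with ε(1/m) = 0, so positive
values always mean positive selection regardless of m. Days are linked
to the previous night's availability, since predators are sampled the
morning after each net night.

## Synthetic communities

The generator emulates the study conditions the pipeline targets: a
default of 33 ESUs with 150–175 bp reference sequences (cross-ESU
identity forced below 95%, within-ESU variants within 2 edits),
predator self-reads at 43% of a sample, a small decoy fraction of
non-bilaterian reads, per-ESU multiplicative amplification bias drawn
lognormal(0, 0.5²) unless supplied, rarefaction depth 1950, mock
homogenates at depth 9450, and a drift survey of five drift plus two
postdrift nights counted from 5% subsamples. Within-species diet
variation uses a Dirichlet around each species × period profile with
concentration 5 — a moderate spread chosen once as plausible for
conspecific fish feeding in the same reach; no empirical variance
model was available. Each run plants guaranteed positives for every
screening rule (one over-length, one dataset singleton, one 8-bp
homopolymer sequence, injected into the deepest sample) and generates
one sample below the rarefaction depth and one near-empty stomach per
species × period so each exclusion path is exercised.

The generator does not simulate read-level quality scores, chimeras,
PCR stochasticity beyond the per-ESU bias factor, taxonomic ambiguity
between ESUs, or spatial structure among sites. Passing tests
therefore demonstrate correctness of the computations and their
behaviour under multinomial sampling noise and known bias — not
robustness to chimeric reads or reference-database error, which real
data add on top.

Randomness: a single integer seed feeds named substreams (reference /
diets / mock / drift) via `numpy` `SeedSequence`, so regenerating one
stage never perturbs another and all outputs are bit-reproducible.

## Numerical conventions

Simplex vectors are validated to sum to 1 within 1e-9 (1e-6 on user
inputs); proportions are stored at full precision and rounded only for
presentation (RCFs conventionally to 3 decimals). Agreement with a
published rounded value is asserted to one unit in its last printed
decimal, since recomputation from printed (rounded) inputs cannot be
sharper. Test problem sizes (hundreds of reads to a few thousand, 8–12
ESUs, 999–99,999 permutations) were chosen to make the statistical
assertions well-powered while keeping the default suite fast.

## Known limitations

- Greedy centroid clustering can split a true group if its variants
  exceed 2 edits from the most-abundant centroid; this mirrors the
  stated clustering rule rather than attempting consensus refinement.
- The availability floor makes selectivity for unobserved-in-drift
  ESUs depend on an arbitrary constant.
- RCF estimation assumes the mock families span the diet taxa;
  uncalibrated taxa default to RCF 1 during correction.
- PERMANOVA/ordination of diet and selectivity matrices is out of
  scope; the diet matrix and Chesson tables are exported as TSVs
  directly consumable by standard multivariate software (e.g. vegan).
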