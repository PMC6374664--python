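# driftdiet

Diet metabarcoding analysis for riverine fish predator communities.

When predator gut contents are characterized by amplicon sequencing of a
universal marker (here the ~150–175 bp 18S V9 region), turning raw read
tables into ecological conclusions takes a chain of decisions: quality
screening, OTU clustering, rarefaction to a common depth, removal of the
predator's own reads, aggregation into ecologically significant units
(ESUs), calibration of amplification bias against mock communities, and
finally the community statistics — dietary overlap between predator
species, its change between prey-rich and prey-poor periods, and prey
selectivity against availability measured by drift-net surveys.
`driftdiet` implements that chain as a tested, seeded, reusable library
with a thin CLI, plus a synthetic-community generator that produces
every input with known ground truth.

It is aimed at fish and invertebrate trophic ecologists working with
gut-content metabarcoding who want the index computations and the
permutation inference to be explicit, reproducible and unit-tested
rather than buried in one-off scripts.

## The statistics at the core

For pooled prey-proportion vectors $p_x, p_y$ of two predator species,
Schoener's overlap index is

$$\alpha = 1 - 0.5 \sum_i |p_{xi} - p_{yi}|,$$

with $\alpha > 0.6$ conventionally read as substantial overlap, and the
Bray–Curtis distance on the simplex is its complement $d = 1-\alpha$.
The change in overlap between two sampling periods is tested with a
paired sign-flip permutation test: each species pair's (drift,
postdrift) values are randomly swapped per iteration and the mean
paired difference recomputed, with $p = (1 + \#\{|\bar\Delta^\ast| \ge
|\bar\Delta|\})/(N+1)$.

Amplification bias is quantified per family $t$ from a mock tissue
homogenate of known composition via the relative correction factor
(an odds ratio of sequence share $S_t$ to biomass share $B_t$):

$$\mathrm{RCF}_t = \frac{S_t}{S_m} \times \frac{B_m}{B_t}, \qquad
S_m = 1 - S_t,\; B_m = 1 - B_t.$$

Prey selectivity compares diet proportions $r_i$ with environmental
availability $n_i$ (drift biomass proportions) through Manly's
selection index and Chesson's electivity for $m$ surveyed prey types:

$$\alpha_i = \frac{r_i/n_i}{\sum_j r_j/n_j}, \qquad
\varepsilon_i = \frac{m\,\alpha_i - 1}{(m-2)\,\alpha_i + 1} \in [-1, 1].$$

## Worked example

The package ships three small published reference tables (a
mock-homogenate composition, a nightly drift-biomass survey, and a
pairwise overlap matrix for 13 predator species in two periods):

```python
import driftdiet as dd
from driftdiet.datasets import load_mock_homogenate, load_overlap_pairs

rcf = dd.compute_rcf(load_mock_homogenate())
print(rcf[["family", "biomass_pct", "sequence_pct", "rcf"]].round(3).head(4))

pairs = load_overlap_pairs()
res = dd.paired_sign_flip_test(pairs["alpha_drift"], pairs["alpha_postdrift"],
                               n_perm=99_999, seed=1)
print(f"mean delta alpha = {res.mean_delta:.3f}, "
      f"p = {res.p_value:.4f} ({res.n_pairs} pairs)")
```

```
        family  biomass_pct  sequence_pct   rcf
 Acipenseridae         8.68         15.49 1.928
  Catostomidae         7.18          3.72 0.499
 Centrarchidae         6.77          7.00 1.037
Ephemerellidae         3.10          3.02 0.973
mean delta alpha = -0.056, p = 0.0027 (78 pairs)
```

The first block says sturgeon tissue (Acipenseridae) yields almost
twice the sequence odds its biomass share would predict (RCF 1.928,
over-amplified), while sucker tissue (Catostomidae) is under-amplified
(0.499). The second block: across all 78 species pairs, dietary overlap
dropped on average by 0.056 from the prey-rich drift period to the
postdrift period, a shift a 99,999-iteration sign-flip test finds very
unlikely under exchangeability (p ≈ 0.003) — predators partition their
niches as prey becomes scarce.

A fully synthetic end-to-end run (simulate → screen/cluster/assign →
rarefy → diet matrix → bias, drift, overlap, selectivity):

```bash
driftdiet all --seed 7 --out run1 --n-perm 9999
```

writes every intermediate TSV, a run manifest with config and digests,
and a plain-text report under `run1/`. Individual stages are exposed as
`driftdiet simulate|rcf|drift|overlap|selectivity` so printed tables
can enter mid-pipeline.

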