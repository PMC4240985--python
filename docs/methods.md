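# Methods

## The inference problem

A cohort of cultivated accessions is suspected to descend from crosses
among a panel of diploid wild species. Three observable signals carry the
parentage information:

1. **Chloroplast haplotype.** The chloroplast is uniparentally
   (maternally) inherited and effectively one linked, non-recombining
   locus. The wild species whose haplotype is nearest (p-distance) to a
   cultivar's haplotype is its maternal donor.
2. **Nuclear allele identity.** At single-copy nuclear loci a
   first-generation hybrid carries one allele from each parent. When
   divergence between species is large relative to the time since the
   cross, a cultivar allele that is 100% identical to a wild species'
   allele attributes that allele to that species.
3. **Cyto-nuclear discordance.** Among the wild species themselves,
   introgression can replace one species' chloroplast with another's
   (chloroplast capture). A chloroplast tree that contradicts the nuclear
   tree — non-monophyletic clades, positive Robinson–Foulds distance — is
   the fingerprint of such gene flow and a caution against reading the
   chloroplast phylogeny as the species tree.

`hybparent` implements each signal as a module and ties them together in
a pipeline whose accuracy is measurable because the synthetic-data
generator knows the truth.

## Synthetic data model (`simgen`)

* **Species tree.** Pure-birth (Yule) tree: with `k` extant lineages the
  waiting time to the next speciation is Exp(`k · birth_rate`); after the
  last split the tree grows a final Exp(`n · birth_rate`) interval, so the
  tree is ultrametric. `birth_rate` is per unit time (default 1.0, which
  with 9 species gives total tree lengths near 8 time units). The two
  children of the root define the two clades ("subsections") reported for
  clade-level monophyly checks.
* **Sequences.** Each locus evolves down the tree site-independently
  under JC69 (default) or K2P (`kappa`, default 2.0) using the closed-form
  branch transition matrices; the root sequence is uniform over ACGT.
  Alignments are gap-free by construction — indels are not simulated, so
  the gap/N handling in the statistics is exercised by real input, not by
  the generator. Nuclear per-locus substitution rates are drawn uniformly
  from `nuclear_rate_range` (default 0.005–0.025 /site/time), chosen so
  that with the default tree scale the per-locus variable-site
  percentages span roughly 4–19%, the spread typical of fast intron
  markers screened for this kind of study; locus lengths are uniform on
  322–3656 bp. The chloroplast is one linked haplotype (default 3000 bp,
  rate 0.008), giving the lower diversity expected of plastid regions
  while keeping species haplotypes distinct.
* **Within-species sampling.** Each species carries 1–3 sequenced
  accessions per locus (default 2–3), derived from the species sequence
  by independent per-site mutation at `within_species_rate` (default
  0.0015). This creates shallow within-species variation without
  violating the assumption that alleles are species-diagnostic.
* **Identity regime guard.** The identity-matching analysis assumes every
  species has private alleles and a private chloroplast haplotype. The
  panel builder verifies this and redraws (with a perturbed seed) in the
  rare case a collision occurs at the default divergences; the guard can
  be disabled (`ensure_species_private_alleles=False`) to study the
  failure mode deliberately.
* **Cultivars.** A parental pool (default 5 species) is drawn once; its
  first member is the dominant maternal donor and is chosen as maternal
  parent with probability `dominant_maternal_weight` (default 0.7,
  mirroring a cohort in which one species mothers roughly three quarters
  of the cultivars). Cultivars are F1s by default (`parental_set_sizes =
  ((2, 1.0),)`): chloroplast copied from the maternal species, one
  nuclear allele per parent per locus, each copied from a random
  accession of the origin species. Larger parental sets (multi-generation
  gene pools) are a configuration extension; allele origins are then
  drawn from the set and the recorded truth is the realized union.
* **Observation noise.** Post-origin mutation (`post_origin_mutation_rate`)
  and per-site clone error (`clone_error_rate`) both default to 0 — the
  regime in which identity matching is exact and recovery must be
  perfect; raising them degrades matching in a controlled way. Each
  cultivar × locus yields 8–16 clones, each a copy of one of the two
  alleles with independent errors.
* **Determinism.** Every draw flows from the configured seed through
  `numpy` generators; identical configurations give byte-identical
  datasets and pipeline artifacts.

What the generator does **not** emulate: indels and alignment error,
intragenic recombination in cultivar alleles, incomplete lineage sorting
of nuclear alleles (species sequences are fixed at the species-tree
tips), PCR chimeras, and multi-generation pedigrees with backcrossing.
Passing tests therefore demonstrate correctness of the inference
machinery under the identity-matching assumptions, not robustness of
those assumptions on real data.

## Marker statistics (`markerstats`)

Gaps and `N` are missing data: excluded per column for site counts and
pairwise for π and distances (a strict mode treating `-` as a fifth state
exists for the site counts). A column is *variable* with ≥2 distinct
non-missing states, *parsimony-informative* with ≥2 states each in ≥2
rows. π is the unweighted mean over row pairs of (differences / compared
sites); pairs sharing no site are skipped. The base-composition χ² drops
bases absent from every row (df adjusts as (rows−1)·(columns−1)) and
excludes rows with no countable base with a warning; the statistic is the
uncorrected Pearson χ² on the taxa × base table.

The recombination screen is a MaxChi-style scan: for each sequence pair,
mismatch indicators at mutually comparable sites are compared left versus
right of a sliding breakpoint inside a window (default 400 comparable
sites, half on each side) with a 2×2 χ² (df 1); the per-pair maximum is
Bonferroni-corrected over pairs × breakpoints within the locus. The
correction is deliberately conservative: under a clonal null the
dataset-level false-positive rate stays well under the nominal level,
while a 10%-divergent recombinant of 1000 bp is localized to within a few
bp of the true junction.

Marker ranking uses parsimony-informative % first (ties: variable %,
aligned length, locus id) — an explicit convention for "most
informative", since informativeness-for-parentage tracks the number of
species-diagnostic sites. Percentages are reported to one decimal.

## Trees (`treekit`)

* Distances: p (proportion of differing compared sites, pairwise
  deletion) or JC69, `−(3/4)·ln(1 − 4p/3)`; p ≥ 0.75 is flagged saturated
  and capped at 5.0 substitutions/site rather than returning infinity.
* Neighbor joining (Saitou–Nei). Negative branch-length estimates are
  clamped to zero with the deficit moved to the sibling edge so the
  joined pair's summed length is preserved; a warning is issued. Additive
  inputs are realized exactly, and on additive distances from random
  binary trees the generating topology is recovered (checked against
  scikit-bio's independent implementation).
* Fitch parsimony, vectorized over columns; missing states are fully
  ambiguous and never force a change. Exact search enumerates all
  (2n−5)!! unrooted topologies up to `exhaustive_max` taxa (hard cap 9,
  refused beyond with guidance); larger problems use NNI hill-climbing
  from the NJ topology plus random stepwise-addition restarts, returning
  all co-optimal trees found.
* Bootstrap: columns resampled with replacement; support for an internal
  edge of the full-data tree is the percentage of successful replicates
  containing that bipartition (failed replicates are skipped, warned and
  excluded from the denominator). Default 100 replicates; the seed is
  mandatory in pipeline mode.
* Topology comparison is unrooted throughout: bipartitions are
  normalized leaf-label splits, Robinson–Foulds is the symmetric
  difference of nontrivial splits, and a leaf set is monophyletic iff one
  edge separates exactly it (singletons, their complements and the full
  set are trivially monophyletic). Maximum-likelihood and Bayesian
  inference are intentionally out of scope: the claims the pipeline
  consumes are topological, and NJ + parsimony + bootstrap carry them at
  desk scale.

## Parentage (`parentage`)

* **Dereplication.** Identical clones collapse into haplotypes with
  counts; haplotypes under `min_count` (default 2) are treated as PCR or
  sequencing artifacts and discarded unless they exactly match a
  reference allele (rescue rule); the most frequent haplotype is always
  retained. The default of 2 balances artifact suppression against losing
  a genuine allele sampled once.
* **Matching.** Strict 100% identity over mutually non-missing sites is
  the default, matching the definition of allele sharing the analysis
  rests on; `max_mismatch > 0` switches to nearest-within-tolerance. The
  chloroplast assignment separately uses a p-distance ceiling (default
  0.002, i.e. 2 mismatches per kb) above which a cultivar is left
  unassigned rather than forced onto a distant donor.
* **Maternal ties** (equal minimal distance) are broken by the species
  matching at the most nuclear markers for that cultivar, then
  lexically; all tied species are reported.
* **Parental set.** The matrix keeps two views per cultivar × marker: the
  union of matched species (the display cell) and the per-allele match
  sets. The minimal parental set is the smallest species set that
  contains the assigned maternal donor and intersects every per-allele
  match set — per-allele constraints matter because a diploid marker
  carries two alleles that may demand two different parents, while the
  union cell is always satisfied by the maternal donor alone. Exact
  subset search is used up to 15 candidate species (candidates are only
  the species actually matched, so this covers any realistic panel), a
  greedy cover beyond; co-optimal covers are reported, ordered by total
  marker coverage then lexically. A maternal donor absent from every cell
  and unknown to the reference triggers an inconsistency warning and the
  cover is computed unconstrained. Unmatched alleles never invent
  parents; they are counted as unexplained per marker.
* Ambiguity cells (an allele identical to several species) are satisfied
  by any member — this is what lets the cover discount a species whose
  only evidence is shared with another parent.

## Pipeline and evaluation

Stages run in a fixed order (load/simulate → marker stats and top-k
selection → trees and discordance → matrix → calls → cohort summary →
recovery) and any failure aborts with the stage name. The nuclear tree is
built from the concatenated supermatrix at accession level; species-level
NJ trees (first accession per species vs chloroplast haplotypes) feed the
Robinson–Foulds comparison; clade-level monophyly is checked on the
chloroplast tree and per-species accession monophyly plus bootstrap on
the nuclear tree. Recovery metrics: cohort precision/recall on the union
of parental sets, per-cultivar maternal accuracy and exact-set rate;
an empty inferred union yields an undefined (null) precision and zero
recall.

Problem sizes used by the test suite and the acceptance script — full
pipeline at 9 species / 25 loci / 47 cultivars, 100 bootstrap replicates,
50 NJ consistency trees, 1000 χ² calibration replicates, 200 MaxChi null
replicates — were chosen so each check is statistically meaningful while
the whole suite completes in a couple of minutes on one CPU.

## Known limitations

* Identity matching is only as good as the reference panel: an unsampled
  parent manifests as unexplained alleles, never as a call.
* With union-style evidence alone, a cultivar whose every allele is
  shared with the maternal species is indistinguishable from a
  non-hybrid; per-allele constraints mitigate but cannot remove this when
  alleles are genuinely shared across species.
* The chloroplast ceiling and the clone `min_count` are knobs, not
  estimates; real studies should sweep them.
* The simulator's clean species boundaries mean recovery rates reported
  here are upper bounds for real data with lineage sorting, recombination
  or alignment error.
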