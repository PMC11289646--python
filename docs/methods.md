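# Methods

`lgptrace` reconstructs how gene families associated with stress physiology
were assembled over a rooted species phylogeny, with an emphasis on
*latent genetic potential* (LGP): families that are new as genes but built
from protein domains that are individually much older.  This note states the
models and rules the package implements, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the numerical
choices made where behaviour had to be pinned down.

## Data model

The unit of analysis is the **orthogroup**: a cluster of proteins across
species descended from one gene in their common ancestor, read from an
OrthoFinder-style table (rows = orthogroups, columns = species, cells =
comma-separated protein IDs).  Protein IDs are globally unique, so the
table is a partition of the proteome — several downstream counts rely on
each protein belonging to exactly one orthogroup, and the reader enforces
it.

Domain predictions are read from InterProScan-style TSV with 1-based
inclusive residue coordinates.  By default only hits with an integrated
InterPro accession are kept (`interpro_only`); a `fallback_signature`
policy substitutes the member-database accession when no InterPro accession
exists.  The choice matters for absolute domain counts but not for any
relative statement the pipeline makes.

## Stress annotation

"Stress" is a fixed vocabulary: 31 seed GO terms for stress-response
processes (packaged in `data/stress_seed_go_terms.txt`) expanded to their
descendant closure in the ontology.  Closure propagation follows `is_a` and
`relationship: part_of` by default; an `is_a`-only switch exists because
`part_of` propagation is a modelling choice, not a logical necessity.

An orthogroup is called stress-relevant by the conjunction of two
independent evidence lines:

* **approach 1** — it contains ≥1 stress-annotated protein from *every*
  configured reference species (curated annotation transferred through
  orthology membership);
* **approach 2** — its own de novo GO assignment intersects the closure.

The intersection trades recall for precision: each approach alone
over-calls differently (reference bias vs annotation-transfer noise).  The
run report always carries the four-way breakdown (a1-only / a2-only / both /
neither) so the conjunction's effect is visible.

## Domain architectures

Predictors emit the same domain repeatedly on overlapping windows.  Per
(protein, domain) the hit intervals are union-merged; merged spans are the
minimal interval set with the same residue union.  The default merge joins
only intervals that share a residue; a `book_ended` mode additionally joins
abutting intervals (end + 1 = start).  Merging is idempotent and
permutation-invariant, and the merged count never exceeds the raw count.

A protein's **architecture** is the left-to-right sequence of all its
merged spans ordered by (start, end, accession) — the tie-break makes the
order a deterministic function of the span set.  Repeats at disjoint
positions keep one token per occurrence (essential for repeat families such
as PPR or LRR proteins); nested spans keep both tokens.

## Origins by Dollo-style parsimony

Each entity (orthogroup or domain) is assumed to have arisen once, so its
origin node is the MRCA of its carrier species; absences inside the clade
are losses.  Under lineage loss this estimator is biased young — the origin
can be a proper descendant of the true birth node, never an ancestor — and
the simulation tests assert exactly that direction.  Domain origins are
computed over proteins of **all** orthogroups by default, not only
stress-annotated ones: the LGP question is when a domain existed anywhere
in the genomic background.

## Fold-change bursts

For each node on the root-to-focal backbone, a domain's mean merged-span
count per species in the clade is divided by the same mean over the sister
lineage (at a multifurcation, the union of co-children).  Means include
zero-count species; excluding them would make emergence undetectable.  A
positive clade mean over a zero sister mean is the categorical status
EMERGENT, reported separately and never ranked as a ratio.  A fold change
≥ 10 (configurable) flags a burst; the per-node report lists the top k
(default 10) finite ratios with ties broken by larger clade mean, then
accession.  Counts feeding fold changes default to the stress-annotated
orthogroup scope, with an all-orthogroup scope available.

## Latent genetic potential

For an orthogroup with origin node N, the evaluated domain set is its
**embryophytic domain set**: domains predicted on its proteins in ≥1
bryophyte *and* ≥1 tracheophyte — the configuration attributable to the
land-plant LCA rather than one land-plant subclade.  Orthogroups with an
empty set are counted in origin denominators but are never LGP.

The orthogroup is LGP when all three hold:

1. it originated exactly at N;
2. every set domain predates N (**age rule**, two modes below);
3. no protein outside clade(N) shows any of the orthogroup's representative
   ordered combinations (**novelty rule**): representative architectures
   are the distinct non-empty projections of embryophyte member
   architectures onto the set, and matching is exact equality of the
   set-projected tuple.  Exact projection was chosen over subsequence
   matching as the most conservative reading of "in the same order" that is
   still well defined.

Age-rule modes:

* `any_outgroup` — every set domain occurs in ≥1 species outside clade(N);
* `all_previous_lineages` (default, strictly stronger) — every set domain
  occurs in ≥1 species of *each* sister lineage branching along the root
  path above N.  The walk stops below the root: the clade on the far side
  of the root (here, cyanobacteria) is an outgroup to the whole ingroup
  radiation, not one of its "previous lineages".  Presence inside clade(N)
  itself never evidences age.

The strict mode's LGP set is nested inside the lax mode's on every input;
both are exercised in the tests and reported by the acceptance script.
Per backbone node the pipeline reports x/y — x = stress-annotated LGP
orthogroups originating there, y = all LGP orthogroups — together with both
origin denominators, so either rate can be formed without re-running.

## Synthetic data generator

The generator emulates the statistical structure of a 37-species
comparative dataset over the green lineage: 5 cyanobacteria, 6
chlorophytes, 7 streptophyte algae (one mesostigmatophyte, chlorokybophyte,
klebsormidiophyte, charophyte, coleochaetophyte and two zygnematophytes),
4 bryophytes and 15 tracheophytes on a fixed labeled backbone
(root → chloroplastida → streptophytes → Klebsormidiophyceae+Phragmoplastophyta
→ Phragmoplastophyta → Coleochaetophyceae+crown → Zygnematophyceae+land
plants → land plants).

Defaults (the study-like conditions): 2000 orthogroups, 300 domains,
`p_lgp` = 0.15, stress fraction 0.25 of orthogroups (with 5% approach-1-only
and 10% approach-2-only disagreement, mirroring the asymmetry of the two
evidence lines), mean 1.5 proteins per (species, orthogroup) (1 + Poisson
duplications), redundant-hit rate 0.1, loss and annotation noise 0.
Domain birth nodes are deep-skewed (half at or below the green-lineage
root), orthogroup births crown-skewed with a land-plant pulse — the
qualitative pattern the analysis is designed to detect.

Two constraints hold by construction.  First, an orthogroup's architecture
draws only domains born at ancestor-or-equal nodes of its own birth node
(a protein cannot contain a domain that does not yet exist in its lineage).
Second, every domain is anchored by a single-domain background orthogroup
spanning its full birth clade, so under zero loss the carrier MRCA equals
the birth node exactly and under loss it can only be younger.  Collision
cases (planted counter-examples to novelty) place one extra protein
carrying the full ordered tuple in a species inside the clade of the
youngest constituent domain but outside the orthogroup's clade, which
preserves both constraints.

Truth labels (origins, embryophytic sets, both LGP verdicts, stress calls)
are re-derived from the *materialized* tables by plain brute-force loops
inside the generator, so sampling accidents — chance architecture
collisions, losses, noise flips — cannot desynchronize `truth.json` from
the emitted data.  Approach-1 noise flips to "true" are physically
unrealizable for orthogroups lacking members of both reference species;
such flips are suppressed and per-orthogroup realizability is recorded, so
the analytic expectation of the noisy intersection count is exact.

What the generator does **not** emulate: sequence evolution (domain
accessions are atomic symbols, so "a new domain variant classified as a new
domain" cannot arise), annotation evidence codes, correlated noise between
the two GO evidence lines, internal-branch loss regimes (loss is applied at
the species level), genome-size or proteome-completeness variation, and
horizontal transfer.  Passing recovery tests therefore shows the inference
machinery is correct under the stated generative model — not that the
biological conclusions are robust to violations of it (e.g. systematic
homology-detection failure, which is known to bias origins young).

## Numerical and reproducibility choices

* All randomness flows from one integer seed through `numpy`'s
  `default_rng`; a fixed seed yields byte-identical bundles and outputs.
* Every writer sorts rows by primary key; floats are formatted with `%.6g`;
  reports contain no timestamps, and the config hash excludes the output
  directory — two runs on the same inputs are byte-identical.
* Unlabeled internal tree nodes are auto-labeled (N1, N2, … in preorder) so
  every possible origin node is addressable by a stable name.
* Degenerate inputs: empty orthogroup cells are allowed; entities with zero
  carriers are excluded from origin assignment; the root is skipped in
  fold-change paths (it has no sister); an empty species set has no mean
  (error rather than NaN).
* Test problem sizes (oracle set counts, simulation sizes of 150–2000
  orthogroups) were chosen so the whole suite runs in about a minute on one
  CPU while every planted structure is represented many times over.

## Known limitations

* Origins are point estimates under Dollo parsimony; no loss model or
  homology-detection-failure correction is applied.
* The age and novelty rules see only predicted domains; unintegrated
  signatures are dropped under the default accession policy.
* Fold changes carry no statistical test — they are descriptive ratios, and
  the burst threshold is a reporting convention, not an inference.
* `all_previous_lineages` conditions on the tree being correctly rooted;
  a misplaced root changes which lineages count as "previous".
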