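# lgptrace

Where do "new" genes come from?  In plant terrestrialization, many hallmark
stress-response gene families of land plants (embryophytes) are lineage
novelties as *genes*, yet their building blocks — protein domains — are far
older.  `lgptrace` is a pipeline for detecting exactly this pattern, called
**latent genetic potential (LGP)**: gene families assembled by reshuffling
pre-existing domains into new ordered combinations, rather than by de novo
domain birth.

It is written for comparative genomicists who already have the standard
upstream artifacts — an OrthoFinder orthogroup table, InterProScan domain
predictions, GO annotations and a rooted species tree — and want a tested,
deterministic path from those files to per-node counts of stress-relevant
and LGP gene families.

## What it computes

Given orthogroups $O$, species tree $T$ with focal node $N$ (default: the
land-plant LCA) and per-protein domain spans:

* **Stress annotation** — an orthogroup is stress-relevant iff it passes
  both evidence lines: (1) it contains ≥1 protein from *each* reference
  species annotated with a term from the stress GO closure (31 seed terms +
  descendants), and (2) its de novo GO assignment intersects that closure.
* **Architectures** — per (protein, domain) hit intervals are union-merged;
  a protein's architecture is its merged spans ordered by (start, end,
  accession).
* **Origins** — Dollo-style parsimony: $\mathrm{origin}(e) =
  \mathrm{MRCA}_T(\mathrm{carriers}(e))$ for every orthogroup and domain.
* **Bursts** — for each backbone node $v$, per-domain fold change
  $\bar{c}_{\mathrm{clade}(v)} / \bar{c}_{\mathrm{sister}(v)}$ of mean
  merged-span counts per species (zeros included); ratios ≥ 10 are bursts,
  domains absent from the sister are reported as EMERGENT.
* **LGP** — an orthogroup born at $N$ with embryophytic domain set $S$
  (domains on its proteins in ≥1 bryophyte and ≥1 tracheophyte) is LGP iff
  every $d \in S$ predates $N$ (present in each earlier-branching sister
  lineage, or — lax mode — anywhere outside $\mathrm{clade}(N)$) **and** no
  protein outside $\mathrm{clade}(N)$ shows any of its set-projected ordered
  domain combinations.  Per node the pipeline reports $x/y$: stress-LGP and
  all-LGP counts with their origin denominators.

A deterministic synthetic-data generator (`lgptrace simulate`) emits
complete input bundles on a 37-species green-lineage phylogeny with planted
domain births, orthogroup origins, duplications, losses, redundant hits,
annotation noise and LGP cases, plus a `truth.json` — so every stage is
testable against known ground truth.

## Worked example

The packaged six-species micro-case contains three decisive orthogroups:
a Remorin-like LGP case (both domains occur separately in the algae, never
together on one algal protein), a genuinely-new-domain case, and an
architecture collision (one charophyte protein already carries both domains
in the same order):

```
$ lgptrace simulate --micro --out demo/bundle
$ lgptrace run-all --bundle demo/bundle --out demo/results
$ cat demo/results/lgp.tsv
orthogroup  node         origin       eligible  domain_age_ok  architecture_novel  lgp  stress
OG0000001   land_plants  land_plants  1         1              1                   1    1
OG0000002   land_plants  land_plants  1         0              1                   0    0
OG0000003   land_plants  land_plants  1         1              0                   0    0
OG0000004   streptophytes streptophytes 0       0              0                   0    0
...
$ cat demo/results/node_tallies.tsv
node                          x  y  n_origin_stress  n_origin_total
root                          0  0  0                0
streptophytes                 0  0  0                5
zygnematophyceae_land_plants  0  0  0                0
land_plants                   1  1  1                3
```

Reading: of the three orthogroups originating at the land-plant LCA, only
`OG0000001` is LGP — its domains are older than the family (`domain_age_ok`)
and their ordered combination is new (`architecture_novel`).  `OG0000002`
fails the age rule (one domain exists nowhere outside land plants: de novo
novelty, not recombination) and `OG0000003` fails the novelty rule (an
algal protein already has the combination).  The focal-node tally is
x/y = 1/1: one stress-annotated LGP family out of one LGP family.

The same commands work on real data — point `--bundle` at a directory with
`Orthogroups.tsv`, `domains.tsv`, `ontology.obo`, `tree.nwk`,
`lineages.tsv`, `og_go.tsv` and `ref_go_<species>.tsv`, or use a YAML
config with explicit paths (`--config`).

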