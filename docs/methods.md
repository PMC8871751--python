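# Methods

## Inheritance model and premises

The package models a strictly paternally inherited, non-recombining haploid
locus (the MSY). Three premises carry the whole analysis:

1. **Single-copy haploidy.** Every male carries exactly one allele per
   site; an apparently heterozygous call is a technical artifact (mapping
   error, duplicated region) and never a genotype.
2. **Infinite sites.** Over the shallow time depth of interest (roughly
   1,500 years for the recently expanded "crown" haplogroup, ~190
   transmissions at an eight-year sire generation interval) each site is
   assumed to mutate at most once. Consequently the derived-carrier sets of
   polymorphic sites form a laminar family and the haplotype phylogeny is a
   unique rooted perfect phylogeny, recoverable by parsimony without search.
3. **Outgroup polarization.** The ancestral allele at each site is the one
   carried by a deeply diverged outgroup male (Przewalski's Horse in the
   horse application). Sites where the outgroup has no call get an unknown
   ancestral state and are excluded from tree building rather than guessed.

## Variant ascertainment filters

A site is removed when any rule fires (all reasons are reported):

| rule | default | meaning |
|---|---|---|
| `low_quality_fraction` | >10 % of samples | call with depth <3 **or** GQ <5 |
| `call_rate` | <75 % of samples | fraction of samples with any call |
| `heterozygous_only` | on | every called ingroup genotype is heterozygous |
| `multiallelic` | on | more than one alternative allele |
| `reference_error` | on | every called ingroup genotype is the alternative |

The published filter phrasing couples depth and quality ambiguously; this
package treats a call as low-quality when **either** threshold is violated
(the stricter reading — a call failing on depth alone is not trustworthy).
"Reference error" is operationalized as *the reference assembly itself is
the singleton*: when every called ingroup sample carries the alternative
allele, the site reflects an error or private variant of the assembly
individual, not variation in the panel. The rule deliberately ignores the
outgroup, because deep divergence means the outgroup legitimately disagrees
with the ingroup at many genuine sites. Inputs with no depth/quality
metadata (plain matrix tables) pass those thresholds vacuously, which lets
summary-table fixtures flow through the same code path. Surviving
heterozygous artifacts are demoted to missing. Filtering is contractive and
idempotent by construction.

## Imputation

Missing calls are filled from the consensus of the sample's haplogroup,
mirroring manual gap-filling practice: within a tight clade almost every
site is invariant, so the group consensus is the only defensible value. Two
modes are exposed because no published consensus rule exists: `unanimity`
(default — fill only when all called group members agree) and `majority`
(strict majority, ties left missing; every majority fill is logged and the
pipeline surfaces a warning). Observed calls are never altered. Sites with
residual missingness after imputation are excluded from haplotype
construction — dropping the site keeps every sample in the analysis, which
matches variant-centric reporting; the alternative (dropping samples) would
silently shrink the panel.

## Tree construction

Sites with identical derived-carrier sets are merged onto one edge; the
laminar containment order of the carrier sets *is* the tree. The root is
fixed at the all-ancestral vector even when no sampled male carries it.
Polytomies are kept explicit: a multifurcation at the crown node is a
finding about a demographic expansion, not an artifact to be resolved.
Compatibility inside `build_tree` counts the root as an all-ancestral
sample (two sites conflict when their carrier sets partially overlap),
which is the correct rooted criterion; the standalone `four_gamete_check`
implements the classical unrooted test (all four gametes observed among
samples) — the two differ only in the corner case where the union of two
carrier sets covers every sampled male. Under `greedy_drop`, conflicting
sites are removed rarest-first (ties by site id): dropping the rarer site
erases the fewest carrier observations, and the tie-break makes runs
reproducible.

## Nomenclature

Names grow by one alphanumeric character per level, alternating character
class with the parent's final character (after a letter a digit starting
"1", after a digit a lowercase letter starting "a"; 36 symbols per level).
Historic labels are *legacy stems* anchored to specific nodes and treated
as opaque strings — hyphens belong to the stem, case is significant, and
uppercase appends (e.g. a stem `Ta-bA` below `Ta-b`) enter through the stem
registry rather than the mechanical rule, which keeps published labels
representable without inventing a separator grammar. A trailing `*`
denotes placement at the internal node named by the remainder, compatible
with every descendant. Ancestry between two names is decided purely by
prefix testing after stripping the asterisk; on mechanically named trees
this agrees exactly with tree ancestry (verified exhaustively in the test
suite).

## Marker panels and consecutive genotyping

`select_backbone` tags every edge on the root path of each *focus* node
(full traceability for lineages of interest) and only the subtending edge
of each *coarse* node (recognition without resolution), choosing the
lexicographically smallest site on multi-site edges. Stages mirror bench
practice: `key` (edges off the root), `clade` (the first split below),
`ht` (the rest). `assign_sample` evaluates the final call set
declaratively — the assigned node is the deepest node whose root path is
fully supported by tested derived markers with no tested derived marker off
the path; markers informative only in other clades are auto-imputed
ancestral first (and never count as evidence); untested or failed markers
below the node leave the placement unresolved and append `*`; derived
markers on two disjoint branches are irreconcilable with a single patriline
and yield the verdict `conflict`. Failed assays are handled exactly like
untested markers since the assay gives no information either way. The
declarative evaluation provably returns the same answer as modeling the
sequential assay order, without simulating the bench workflow.

The shipped backbone fixture encodes only the marker-branch relations named
in the genotyping narrative (crown keys rAY/rAX; clade tests rA/rW/fYR —
the clade-to-marker mapping is a configurable convention fixed here as
rA→A, rW→T, fYR→H; the six Ta-branch markers; the Ta-s/Ta-b split markers
qGB/qGC/sPY; the four subline variants qDK/qFE/rAB/fWO). Edges whose
defining variants are not individually published ship without markers.

## Congruence classification

A line's distinct haplotype labels are greedily merged (shortest core
first) into groups in which every pair is ancestry-compatible; `X*` is
compatible with every descendant of `X`. One group with one label is
*consistent*; one group with several labels is *subline-consistent*, and
each non-minimal label is reported as a candidate de novo subline event
tied to the sublines carrying it; two or more groups are *incongruent* —
mutation cannot produce disjoint labels inside one patriline, so more than
one stallion contributed. Two sibling haplotypes without their shared
ancestor observed are classified incongruent: on name evidence alone they
are indistinguishable from two contributors, and treating them otherwise
would hide real errors. The verdict is invariant to member order and
duplication. Haplogroup rollups in the panel summary are pure name-nesting
against a supplied haplogroup list (default `Ao-aA`, `Ta`, `Ao-aD2`).

## The packaged screening fixture

`data/table1.tsv` encodes the occidental Arabian screening panel: 145
males from 26 foundation sires across 44 (sire, subline, haplotype) rows
with verbatim remarks. Where the published table's multi-line cells leave
the subline-to-count allocation ambiguous, counts were allocated so that
every row and column total matches the printed table; the Ilderim line is
encoded as Aquinor 3×`Ao-aA1a*`, Maharadscha 3×`Ao-aA1a4`, Doktryner
2×`Ta-b` — the only allocation consistent with the eight genotyped
descendants shown for that genealogy and the haplogroup totals. The two
incongruence verdicts and all summary counts are *computed* from these raw
rows, never stored.

## Synthetic data: what it emulates, what it does not

The forward simulator produces male genealogies (founders → fixed number of
generations), with each father-to-son transmission adding Poisson(`mu`)
mutations at previously unmutated sites drawn from a finite pool (a
`SitesExhaustedError` rather than silent recurrence when the pool runs
out). Offspring numbers are zero-truncated Poisson with an optional
*popular sire* multiplier (one male per generation), reproducing the
star-like expansions that heavy sire use creates; a `fixed` law exists for
constructing exact pedigrees in tests. `founder_mutations` optionally seeds
each founder with private derived sites, emulating haplogroup divergence
that predates the recorded pedigree window — the situation of real
foundation sires, whose haplogroups split long before studbooks existed.
Degradation flips each ingroup call to missing or heterozygous-artifact
independently and draws depth/GQ so flagged calls violate the default
filters while clean calls pass; the outgroup is never degraded. Pedigree
perturbation replaces recorded fathers with a contemporaneous male at a
configurable rate.

Not emulated: recurrent or multistep mutation (STRs are binarized as
outgroup-length vs other, with a warning that multistep evolution is not
modeled), sequencing-depth correlation along the chromosome, reference
bias, female-line information, and selection beyond the popular-sire
multiplier. Passing tests therefore demonstrate correctness of the
inference machinery under the stated model, not robustness to model
violations real data may contain.

## Study conditions used by the validation suite

Problem sizes were chosen so each property is measured where it genuinely
holds, with simulations small enough to replicate hundreds of times:

- *Noisy end-to-end recovery* (filter → impute → tree, ≥95 % topology
  recovery): 60 replicates, 4 founders with 5 private sites each, 4
  generations, within-pedigree `mu`=0.015, 2 % missingness + 0.5 %
  heterozygous artifacts. The regime is deliberately sub-saturated: a
  terminal mutation observed in exactly one male is information-
  theoretically unrecoverable when its single informative call is
  corrupted, so the expected number of such events is kept well below one
  per replicate — the claim verified is that the pipeline loses nothing
  *recoverable*.
- *Imputation fidelity* (≥99 % of filled cells correct): 10 % missingness
  on clade-structured genealogies (founder divergence 6 sites, `mu`=0.05),
  unanimity mode, groups = founder clades.
- *Four-gamete cleanliness*: 100 infinite-sites replicates, plus planted
  recurrent mutations (a derived allele copied onto a disjoint clade) that
  must always be reported with the planted site in a conflicting pair.
- *Panel concordance*: full-resolution panels on simulated trees must
  reproduce the sequencing placement for every sample; withholding all
  markers below an ancestor must place the sample at that starred ancestor
  and never deeper.
- *Pedigree-error detection*: 100 replicates at a 5 % paternity-error rate
  with diverged founders and `mu`=0 inside the pedigree window (haplogroup
  divergence predates records; within-window de novo mutation is handled by
  the subline-consistent verdict instead). Every recorded line mixing
  descendants of two founders must be flagged incongruent; lines whose
  members all share one true founder must never be flagged — including the
  pathological case of a line swapped *wholesale* onto a single wrong
  founder, which is undetectable from MSY data by construction.

## Numerical and degenerate-input choices

Coordinates are 1-based; the missing symbol in delimited matrices is `.`;
unparseable genotype fields load as missing rather than erroring. Sites
order by position (ties by site id), samples keep input order, children
sort by their smallest member sample id — all outputs are deterministic,
and the pipeline manifest records SHA-256 checksums so reruns are
byte-identical. Empty site lists, duplicate sample ids, unknown outgroups,
all-missing site sets and exhausted naming alphabets are hard errors with
the offending identifier in the message. Simulation randomness comes from
a single integer seed; degradation and pedigree perturbation use
sub-streams derived from it so each stage is independently reproducible.

## Known limitations

Ascertainment bias is inherent to panel genotyping: markers discovered in
sequenced lineages cannot resolve variation private to unsequenced ones,
which is exactly what the `*` placements make explicit. The nomenclature's
prefix test assumes labels below a stem extend the stem text; unrelated
stems that happen to be prefixes of each other would confuse nesting and
are rejected only by the uniqueness check. The greedy conflict resolution
is a heuristic: it guarantees a compatible remainder, not the maximum
compatible site subset. Branch lengths are mutation counts; no time
calibration is attempted.
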