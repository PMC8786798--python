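# Methods

`tlpfam` characterizes thaumatin-like protein (TLP, PR-5) gene families in
cereal genomes. This note documents the models and procedures the package
implements, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Family membership and protein characterization

A candidate protein is accepted into the family when it carries at least
one complete instance of the thaumatin signature motif

```
G-X-[GF]-X-C-X-T-[GA]-D-C-X(1,2)-G-X(2,3)-C
```

scanned with PROSITE-style semantics: every start position is tested, and
variable-length runs take the shortest satisfying expansion at each start
(non-greedy, leftmost-first). The screen accepts a hit anywhere in the
protein, not only inside the annotated domain; the hit coordinates are
recorded so users can apply a stricter rule downstream.

Long (L-type) and small (S-type) TLPs differ in their conserved cysteine
census (16 vs 10, forming 8 vs 5 disulfides) and domain size. Published
domain-length ranges for the two classes (202–217 vs 134–154 aa) are
disjoint, while the molecular-weight ranges of full-length proteins overlap
once signal peptides are included; classification therefore uses
thaumatin-domain length as the primary criterion (>= 180 aa -> long) with
molecular weight as a secondary guard on the small call (< 180 aa AND
< 22 kDa -> small). Anything else is flagged `ambiguous` rather than
silently assigned. Domain spans come from a user-supplied annotation table
(`domains.tsv`); absent that, the signature-hit footprint extended by 60 aa
per side is used as a proxy and flagged as such.

Molecular weight is the sum of average (isotope-weighted) residue masses
plus one water, in kDa; unknown residues (X) contribute the mean residue
mass with a warning. The isoelectric point solves net charge = 0 under
Henderson–Hasselbalch with a Bjellqvist-style pKa set (N-terminus 7.5,
C-terminus 3.55; D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0) by
bisection on pH in [0, 14] to |charge| < 1e-4. The REDDD acidic-cleft
motif is checked column-wise against five user-annotated columns of a
reference alignment; any deviation (including a gap) is reported as a
substitution, e.g. the R -> K replacement seen in some family members.

## Family structure

**Percent identity.** "Sequence similarity" is implemented as percent
identity over the columns of one canonical optimal global alignment
(Gotoh affine-gap dynamic programming, BLOSUM62, gap open 10, extend 0.5
per additional residue), not BLOSUM positives: identity is reproducible
without fixing a similarity definition. Terminal gap overhangs and columns
containing an unknown residue are excluded from the denominator. Ties in
the dynamic program are broken by a fixed state preference (substitution >
gap-in-second-sequence > gap-in-first), applied at the terminus and at
every traceback step, and the operand pair is ordered canonically before
alignment, so identity is symmetric and deterministic. The matrix fill is
compiled with numba; a naive recursive implementation with the same
contract serves as the test oracle.

**Homeolog groups** (hexaploid mode) are maximal cliques — not connected
components, so one promiscuous member cannot chain unrelated triplets —
over edges with identity >= 90% between genes on the same chromosome
number but different A/B/D subgenomes. **Duplicate pairs** require
identity >= 80% and a bidirectional best hit; disjoint pairs are formed
greedily by descending identity (ties by id). The pipeline excludes
intra-homeolog-group edges from duplicate detection: homeologous copies
arise from polyploidy, not duplication, and would otherwise dominate the
mutual-best-hit graph. **Tandem vs segmental**: tandem requires the same
chromosome AND (gap <= 100 kb OR <= 5 intervening family genes); these two
thresholds are not published values but common gene-family conventions,
and both are configurable. Pairs on unplaced scaffolds are flagged, not
classified.

**Intron phases.** Phase of intron i = cumulative CDS length 5' of the
intron, mod 3, computed in transcription order (so - strand genes are
handled by coordinate order reversal at parse time); a CDS total not
divisible by 3 warns but still reports phases.

## Molecular evolution

**Codon alignment.** CDS are threaded onto a protein alignment
(PAL2NAL-style back-translation): aligned protein column i maps to codon
column i, protein gaps to `---` gap codons, and a trailing stop codon is
stripped. Translation mismatches and internal stops are hard errors naming
the sequence and codon.

**Ka/Ks** uses the Nei–Gojobori (1986) estimator. Synonymous site
fractions per codon count each of the three alternative nucleotides at
each position; mutations creating a stop codon count as non-synonymous
(the original site definition). Sites are averaged over both sequences.
Observed differences per codon pair are averaged with equal weight over
all minimal mutational pathways, excluding pathways through stop codons
(all pathways are used in the rare case that every one is blocked).
Proportions are corrected with Jukes–Cantor, d = -(3/4) ln(1 - (4/3) p);
p >= 3/4 is reported as a saturated flag rather than a number. Codon
columns containing a gap, an N, or a stop in either sequence are skipped
and excluded from `usable_codons`. The estimator choice matters less than
it may appear: the published ratio and divergence-time columns this
package verifies depend only on the printed Ka and Ks, and the estimator
is swappable behind `KaKsResult`.

**Selection and divergence time.** omega = Ka/Ks (undefined when Ks = 0
or saturated); omega < 1 purifying, = 1 neutral, > 1 positive. T = Ks/2r
with the synonymous clock rate r = 6.5e-9 substitutions/site/year assumed
for grasses; T is reported in million years to 1 decimal.

**Tajima relative-rate test** (1993): on three aligned sequences, per
column, identical in all three -> Nt; lineage A differing while B equals
the outgroup -> Na; the reverse -> Nb; columns where all three differ, or
where A and B jointly differ from the outgroup, count nowhere. chi2 =
(Na-Nb)^2/(Na+Nb) with 1 df (0 when Na+Nb = 0, P = 1). The published
counts are ambiguous about amino-acid vs nucleotide sites; the pipeline
runs the test on the codon alignment flattened to nucleotides, and the
function itself is symbol-agnostic so either mode is available. The
pipeline's three-way alignment is a transitive merge of two pairwise
alignments anchored on the first pair member; the outgroup defaults to
the lexicographically first accepted gene outside any pair and is
configurable.

**Rounding for report parity.** Ka/Ks to 4 decimals, T to 1, chi2 to 2,
P to 5 — always half-up (`rounding.round_half_up`), because the published
tables round halves up (e.g. a statistic of exactly 0.125 printed as
0.13) while Python's built-in round() is banker's rounding.

**Published-table verification.** `verify_tables` recomputes every
derived column of the two bundled table transcriptions. chi2 and P checks
are exact (integer inputs). Ratio and T checks use interval consistency:
the printed value, within half an ulp of its printed precision, must be
attainable from Ka and Ks each perturbed within half an ulp of their
4-decimal printing — the printed ratios were evidently computed upstream
from unrounded Ka and Ks, so strict re-rounding would flag rows that are
in fact consistent. Seven cells in the Ka/Ks table fail even this check
and are carried as documented anomalies: the OsTLP22/OsTLP24 and
OsTLP23/OsTLP25 rows (their ratio and T columns appear shifted between the
two rows in print) and three divergence times off by one unit in the last
decimal (OsTLP26/OsTLP27, ZmTLP13/ZmTLP37, ZmTLP20/ZmTLP25). The
relative-rate table reproduces 21/21 rows.

## Promoter elements

The promoter window is the 1.5 kb upstream of the initiation codon
(+ strand: [start-1500, start-1]; - strand: reverse complement of the
mirrored window), truncated and flagged at chromosome boundaries. Scanning
expands IUPAC degeneracy codes into character classes and reports all
overlapping matches on both strands by default (restrictable by flag);
hits are never deduplicated. A sequence N matches only a pattern N. The
bundled table carries 27 elements commonly reported in cereal TLP
promoters with their consensus patterns, each assigned to exactly one of
four categories (growth and development, light, hormone, stress); the
table is plain TSV and fully user-replaceable.

## Expression and qPCR

FPKM = counts * 1e9 / (exonic length * mapped fragments); effective-length
corrections used by assembly-based quantifiers are not reproduced.
Differential calls use fold = (treated + 0.01)/(control + 0.01) on FPKM,
flagging genes with fold >= 2 or <= 0.5 in any treated condition; the
0.01 pseudocount (configurable) keeps zero-FPKM genes finite, and whether
published 2-fold calls used raw or log ratios is unstated, so the raw
ratio is the documented default. Clustering is agglomerative on
log2(FPKM+1) rows, Euclidean distance, average (UPGMA) linkage — the
linkage choice is a package default, configurable — with deterministic
tie-breaking delegated to the linkage implementation.

qPCR fold change: per replicate dCt = Ct(target) - Ct(reference); ddCt =
mean dCt(treated) - mean dCt(control); fold = 2^-ddCt. The reported SD is
that of per-replicate folds (each treated replicate against the control
mean), and P comes from a two-tailed equal-variance t-test on the two
replicate dCt samples, starred at p <= 0.05/0.01/0.001. Fewer than two
replicates on either side: fold reported, statistics omitted, flagged.

Duplicate-pair fates: a gene is expressed when max FPKM >= 1 (floor
configurable); exactly one expressed -> pseudo-functionalization; both
expressed with Pearson r >= 0.6 -> retention; both expressed, r < 0.6 ->
neo-functionalization. The floor and correlation threshold are package
decisions — the source analysis names the categories but no cutoffs.
Zero-variance profiles leave r undefined and the call is flagged.

## Synthetic data

The generator produces every pipeline input with serialized ground truth.
Defaults mirror the scale of the wheat family that motivated the package:
32 homeolog groups of three near-identical copies (~2% substitution,
cysteines and motif protected) on matching A/B/D chromosomes, six
duplicate pairs (five segmental, one tandem under 100 kb) evolved from
independent ancestors at omega ~0.1 and Ks 0.45–0.7, roughly one small
TLP in five, and five motif-free, cysteine-free decoys the screen must
reject. Long proteins carry a 24-aa signal peptide, a 202–217 aa domain
with 16 cysteines and a C-terminal extension; small proteins a 134–154 aa
domain with 10 cysteines. All randomness flows from one seed through
named child streams, so sub-generators are independently reproducible and
outputs are byte-identical per seed.

**Codon-substitution calibration.** `evolve_pair` targets are
expectations of the *estimates*: planted difference counts are Poisson
with mean sites * p where p = 3/4 (1 - exp(-4/3 d)) inverts the JC
correction, substitutions are planted one per nucleotide position across
both descendants, and planting continues until the pathway-averaged NG86
difference counts of the realized pair — measured against the pair's
current (drifting) site totals — reach the targets. Calibrating against
the estimator's own counting rule removes the two biases a naive event
simulator shows at these divergences (two-fold synonymous sites saturate
as two-state systems faster than JC assumes, and pathway averaging
reclassifies a small fraction of multi-hit codons): mean recovered omega
is within ~3% of truth at omega 0.1–1.0, Ks 0.8, 500 codons. Duplicate
ancestors keep their signature motif under absolute non-synonymous
constraint so both descendants remain screenable — the in-family analogue
of the motif's empirical conservation.

**What the generator does not emulate**, and hence what passing recovery
tests do not show about real data: codon-usage bias and GC heterogeneity,
indels (descendants stay colinear, so back-translation round-trips are
exact by construction), rate variation across sites and lineages beyond
the protected motif, UTRs and alternative transcripts (exons equal CDS
segments, one transcript per gene), read-level noise (counts are exact at
zero noise, log-normal otherwise), and genuine homeology-duplication
entanglement (planted duplicates are standalone genes, whereas real wheat
paralogs are themselves members of homeolog triplets).

## Problem sizes

The default bundle is 113 genes (~110 kb of protein and CDS sequence);
an end-to-end run takes ~10 s. Monte-Carlo checks use 100 replicates per
omega setting at 500 codons, 1,000 equal-rate triples at 600 bp for test
calibration, and 50 pairs at 100 codons for oracle agreement; these sizes
give means stable to a few percent while keeping the full suite around a
minute after numba warm-up.

## Known limitations

* NG86 with JC correction is the only built-in Ka/Ks estimator; no
  maximum-likelihood codon models, branch models, or trees.
* Percent identity depends on the documented alignment parameters;
  reproducing counts from BLAST-based "similarity" on real genomes may
  shift pairs near the 80/90% thresholds, and the unpublished
  tandem-distance criterion means tandem/segmental splits on real data
  depend on the chosen 100 kb / 5-gene defaults.
* The pI model ignores conformational and neighbor effects, as all
  composition-based calculators do.
* Promoter scanning is consensus-pattern matching; no position-weight
  matrices or enrichment statistics.
* The differential filter is a fold-change rule on FPKM, not a
  count-model test; replicate variance is used only by the qPCR t-test.
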