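# Methods

This note documents the models and procedures `phaeotools` implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Taxonomy scheme and reference-library variants

The reference set is a two-level taxonomy: sub-categories (fine bins such as
"raphid pennate diatoms" or "cyanobacteria") nested in nine groups. Nested
clade membership is encoded as flags with an enforced implication chain
`pennate_diatom ⇒ diatom ⇒ ochrophyte ⇒ stramenopile ⇒ sar`; flags rather
than a full tree suffice for every deletion rule the pipeline uses, and keep
user configs trivial to write and validate. The published scheme at full
scale holds 25 prokaryotic and 49 eukaryotic sub-categories; the full name
list lives in supplementary material of the underlying resources, so the
package ships a representative, user-editable default (34 sub-categories,
at least two per group so the two-sub-category rules are exercisable) and
validates any user-supplied YAML scheme with the same invariants.

The deletion series is the ordered set of seven library variants: full,
minus pennate diatoms, minus diatoms, minus ochrophytes, minus
stramenopiles, minus SAR, minus SAR+CCTH. A variant includes exactly the
sub-categories whose flag set is disjoint from the excluded flags, so
included sets shrink monotonically along the series. The complex-algae-free
variant removes every sub-category flagged as a secondary-endosymbiotic alga
unless it is an ochrophyte; it composes with any deletion level as a set
intersection. Which sub-categories carry the secondary-endosymbiosis flag is
left to the scheme author (the packaged default flags cryptomonads,
haptophytes, dinoflagellates, apicomplexans/chromerids, chlorarachniophytes
and euglenids).

## Similarity hits and the internal aligner

Production-scale searches are consumed as standard 12-column tabular files;
the e-value threshold 10⁻¹⁰ is applied inclusively (`e ≤ 10⁻¹⁰` passes), the
same threshold in both search directions, and self-hits (subject id equal to
query id) are dropped since the query proteome may be present in the
reference data. Hit ordering is everywhere the same strict total order —
e-value ascending, bitscore descending, subject id ascending — which makes
every "best hit" deterministic.

For desk-scale synthetic work the package carries an exact Smith–Waterman
local aligner with affine gaps (Gotoh recurrences; BLOSUM62, gap open 11,
extend 1 by default). Two implementations share one contract: a full
three-state DP with traceback returning the aligned spans, and a
score-only row-vectorised variant in which the within-row horizontal-gap
recurrence is solved by a cumulative maximum, used for all-vs-all scoring
(the two agree exactly on random pairs, and against an independent
brute-force DP; symmetry lets forward and reverse searches share one score
matrix). Raw scores map to e-values by the Karlin–Altschul formula
`E = K·m·n·exp(−λS)` with the standard gapped-BLOSUM62 parameters
`K = 0.041`, `λ = 0.267`. The aligner is for synthetic tests and small
worked examples only — there is no seeding heuristic, no database indexing.

## Conservation (reciprocal best hits)

Sub-category `S` enters gene `g`'s RbH set iff `g`'s best hit within `S` is
protein `p` and `p`'s best hit among query genes is `g`; reciprocal best is
evaluated within each sub-category independently. A gene is present in a
group when ≥ 2 of its sub-categories hold an RbH (`min_subcategories`,
default 2; raising it can only remove presence). Restriction classes are a
fixed truth table over the 9-bit presence vector: all-false →
species-specific; exactly {diatoms} → diatom-restricted; presence confined
to the two stramenopile groups *with* non-diatom stramenopiles present →
stramenopile-restricted; anything else → shared wider. Whether the
stramenopile-restricted class should also require diatom presence is not
decidable from the protocol wording; the table above is the recorded
choice, not an assertion of the original intent.

## Origin calling and acquisition dating

Per gene and library variant, the best hit per sub-category is ranked by the
strict hit order. The call is group `G` iff the first two ranked entries
both belong to `G` ("top hits in two or more sub-categories of one lineage
prior to the best hit from another lineage"); no entries → NO_HIT; anything
else → AMBIGUOUS. Because the ranking is a strict total order, the
alternative reading "≥ 2 entries of `G` anywhere before the best non-`G`
entry" coincides with the default; both are selectable via a strictness
flag.

Dating scans the seven calls in series order. Calls in the query's own
lineage groups (diatoms, non-diatom stramenopiles by default) are vertical.
The gene's foreign category `C` is the call of the **deepest** variant with
a foreign call — deeper libraries have had more of the vertical lineage
removed, so they expose the donor — and the branch is mapped from the
**shallowest** variant calling `C` (full → terminal, …, minus-SAR+CCTH →
pre-SAR). This handles the genuinely ambiguous middle of the series: a gene
transferred from prokaryotes into the SAR ancestor legitimately calls
non-stramenopile SAR at the minus-stramenopiles level (those are its
vertical relatives at that depth) before the donor appears at minus-SAR;
taking the deepest call dates it correctly. Genes whose call series is
interrupted or mixed after the first appearance of `C` keep that date but
carry `consistent = False`.

## Alternative splicing

Eligibility: ≥ 2 annotated exons; introns < 50 bp are excluded from
retention analysis (the gene stays eligible for skipping and for its other
introns). Coverage: a feature passes when
`#{bases with depth > 4} / length > 0.80` — both cutoffs strict, read as one
joint horizontal/vertical rule (a base only contributes horizontally when it
meets the vertical cutoff); an alternative split rule (any-depth horizontal
plus mean-depth vertical) was considered and rejected as it decouples the
two thresholds the protocol states jointly, though both cutoffs remain
configurable in `ASConfig`. A gene is expressed in a sample iff its exonic
union passes; only expressed samples count toward consensus denominators,
since an unexpressed gene is uninformative about inclusion. Consensus:
retention fraction > 0.20 → IR; inclusion fraction strictly inside
(0.20, 0.80) → ES, restricted to internal exons (terminal exons cannot be
"skipped" by coverage logic). The skipping detector is coverage-gap based —
no junction reads, no transcript assembly; that interpretation is a recorded
assumption of this implementation. Coordinates are 0-based half-open
internally; GFF3 is converted from 1-based inclusive on read, bedGraph is
already half-open. Splice sites: canonical iff transcript-orientation
donor/acceptor dinucleotides are GT/AG, i.e. reference GT…AG (+) or CT…AC
(−).

Expression contrasts compare event-gene expression per condition against a
reference condition with the Welch test; sets smaller than two genes report
NA.

## Chromatin, expression and enrichment

Mark polarity is fixed (repressive: CG, CHG, CHH, H3K27me3, H3K9me2,
H3K9me3; active: H3K4me2, H3K9_14Ac). Presence is binary by ≥ 1 bp interval
overlap with the gene body only (both the overlap threshold and the
decision not to include flanks are configurable/recorded choices; the
protocol states neither). Chromatin states partition the 2⁸ combinations
exactly: UNMARKED / ACTIVE_ONLY / REPRESSIVE_ONLY / BOTH. Methylation
contexts partition the (CG, CHG, CHH) triple: unmethylated, CG-only,
CHH-only, CG+CHH, and any CHG-containing combination pooled as
CHG-involved; the `other_combination` label of the public enum is reserved
and unreachable for well-formed rows.

Expression normalisation is the median-of-ratios size factor — the
documented DESeq definition, stated openly as such rather than a
reimplementation of the full DESeq model, since only normalised counts are
needed as an expression measure: `factor_j = median_i(count_ij / geomean_i)`
over genes with a positive geometric mean across samples. Note the
consequence: scaling *all* counts by `c` cancels and leaves the factors
unchanged (normalised counts scale by `c`), while scaling one column moves
its factor exactly. Quartile profiling uses linear-interpolation 25/50/75
percentiles with ties assigned to the lower quartile (all-equal input is
all Q1). The Welch statistic uses Welch–Satterthwaite degrees of freedom and
a two-sided p (sidedness is not stated in the protocol; two-sided is the
conservative default); samples smaller than two give NA. No
multiple-testing correction is applied by default because the protocol
reports raw thresholds; a Benjamini–Hochberg column can be added downstream
from the returned p-values.

Enrichment uses Pearson chi-squared without Yates correction on the 2×2
table (in-set with/without term vs rest-of-catalog with/without term),
df = 1. Expected counts below 5 set a warning flag rather than silently
switching tests. The background is the full annotated catalog (all genes of
the term map); no term-graph (ancestor) propagation is performed.

## Synthetic generators: what they emulate, and limits

All generators are pure functions of `(SimConfig, seed)`; reruns are
byte-identical. Defaults define the study conditions:

- **Families** (`n_families = 350`): 100 vertical, 100 prokaryotic
  transfers spread uniformly over the seven datable branches, 50 red, 50
  green, 50 species-specific. Substitution is i.i.d. uniform replacement at
  `subst_prob = 0.05` per site per clade branch — deliberately simple; rule
  recovery, not evolutionary realism, is the goal. Vertical families are
  conserved within the stramenopile lineage; transferred families root the
  query copy (and the recipient clade below the acquisition branch) in the
  donor group.
- **Score-level hit tables**: scores decay linearly with planted clade
  distance (base 400, 30 per level; donor hits rank just below the deepest
  recipient copies), small deterministic per-sub-category offsets break
  ties, and noisy mode adds Gaussian noise with `score_noise_sd = 8` —
  small against the level gap, so ordering errors are rare but possible.
  E-values derive from the Karlin–Altschul formula at `seq_len = 300`.
- **Coverage** (`n_genes = 50`, `n_samples = 12`, `depth_mean = 20`,
  `ir_rate = 0.24`, `es_rate = 0.20`, matching the genome-wide IR/ES
  frequencies of roughly a quarter and a fifth of genes): genes carry 5–7
  exons; the skippable exon is always the smallest internal one so the
  exonic union still passes the expression filter in skipped samples.
  Planted subsets are sized against the *expressed* samples so the
  consensus rules hold by construction; noise mode draws Poisson depths
  (exonic Poisson(20), background Poisson(0.2)). A `noncanonical_frac` of
  introns (default 0.002, mirroring the observed > 99.8% canonical rate)
  receives non-GT/AG sites.
- **Marks/expression** (`n_features = 400`, `mark_effect = 0.25`): state
  frequencies 25% unmarked / 20% active-only / 35% repressive-only / 20%
  both, CG weighted highest among repressive marks; baseline lognormal
  expression (median 100, σ = 1), any repressive mark multiplies the
  expectation by `mark_effect`, counts are Poisson around
  expectation × planted size factor.

What passing tests on these data do **not** show: robustness to real
alignment artefacts (paralogy, domain shuffling, partial hits), to indel or
codon-level evolution, to junction-level splicing signals, or to
peak-calling noise in mark intervals — none of which the generators model.
The generators validate the decision rules and their thresholds, not the
upstream measurement processes.

## Problem sizes and numerics

Aligner-based stages run on a ten-sub-category desk-scale scheme (two per
group over five groups) with 40 families of 150-residue proteins — chosen so
an all-vs-all RbH analysis with exhaustive oracle comparison completes in
well under two minutes on one CPU. Score-level origin analyses use the full
350-family default. Statistical kernels are validated to 10⁻⁸ relative
error against independent references (scipy's Welch test and chi-squared
contingency). Degenerate inputs have defined behaviour throughout:
zero-variance equal-mean Welch inputs return t = 0, p = 1; degenerate 2×2
margins return chi-squared 0, p = 1; zero-length features, all-zero count
matrices, empty gene sets and malformed intervals raise informative errors.
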