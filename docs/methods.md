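# Methods

This document records the model implemented by `ba_prioritize`, every
tunable parameter with its default and rationale, and the known
limitations. All empirical numbers quoted here are recomputed by the test
suite (`tests/`) and the acceptance script (`scripts/acceptance.py`).

## 1. Variant representation and normalization

A variant is identified by `VariantKey(chrom, pos, ref, alt)` after
normalization: chromosome names are `chr`-prefixed, multi-allelic VCF rows
are decomposed into one key per alternate allele (preserving each sample's
dosage of that allele), and shared ref/alt context is trimmed
suffix-first, then prefix (advancing `pos`). Normalization is
reference-free: left-alignment across homopolymers requires the reference
genome and is out of scope, so callers feeding this pipeline should emit
atomized, left-aligned records (e.g. via `bcftools norm`).

Genotypes are abstracted to zygosity classes `HOM_REF / HET / HOM_ALT /
HEMI_REF / HEMI_ALT / MISSING`. On non-pseudoautosomal chrX, a male
sample's haploid (`1`) or diploid-coded (`1/1`) genotype maps to
`HEMI_ALT`; hemizygous calls anywhere else (autosomes, females, PAR) are
rejected as genotype inconsistencies. The pseudoautosomal intervals
default to GRCh38 PAR1/PAR2 (`10,001–2,781,479` and
`155,701,383–156,030,895`) and are overridable.

## 2. Multi-caller consensus

`consensus_intersect(callsets, min_callers=None)` keeps keys reported by
at least `min_callers` call sets; the default (`None`) is the strict
intersection of all callers. Consensus is monotone: raising `min_callers`
never adds variants.

## 3. Inheritance-mode classification

Rules are applied in fixed priority order — de novo > homozygous
recessive > X-linked — so each variant gets exactly one mode:

- **De novo**: proband carries the alternate allele, at least one parent
  is genotyped, and every genotyped parent carries zero alternate copies.
  Tier is *confirmed* with both parents genotyped, *putative* with one.
- **Homozygous recessive**: autosomal (or PAR) site, proband `HOM_ALT`,
  both parents `HET` (*confirmed*), or one `HET` and the other missing
  (*putative*).
- **X-linked**: non-PAR chrX, mother a carrier (`HET`/`HOM_ALT`), proband
  `HEMI_ALT` (males) or `HET`/`HOM_ALT` (females). A father's X is never
  transmitted to a son, so the paternal genotype is not consulted for male
  probands — a boy's X-linked call is *confirmed* even in a duo family. A
  female `HOM_ALT` call needs the father observed to be *confirmed*.

The tier semantics are uniform: a call is *putative* exactly when a
parental genotype the rule needed to consult was missing. The classifier
is verified against a hand-written exhaustive truth table over all 864
(proband × mother × father × {autosome, non-PAR X} × sex) combinations.

## 4. Prioritization filters

Defaults in `FilterConfig`:

| parameter | default | rationale |
|---|---|---|
| `maf_max` | 0.01 | conventional rare-variant bound; strict `<` |
| `maf_databases` | KHV, GnomAD_EAS, 1KG | ancestry-matched plus broad references |
| `maf_policy` | `any` | see below |
| `allowed_consequences` | missense, stopgain, splice | protein-altering classes |
| `cadd_min` | 10.0 | CADD Phred 10 ≈ top 10% deleterious; strict `>` |
| `missing_cadd` | `fail` | a variant without a score cannot demonstrate deleteriousness |

**Why `maf_policy = any`:** the reference cohort's published candidate set
contains variants whose frequency exceeds 1% in two of the three
databases (e.g. a THOC2 variant at 0.0148/0.0159 in the two non-KHV
databases, and conversely HACE1/VPS13C at exactly 1% in KHV). Only a
policy that passes a variant rare in *at least one* database reproduces
the published 28-variant set; `all` and `majority` are available as
stricter options. An unobserved database (blank MAF cell) counts as rare
in that database, since absence from a population panel is itself evidence
of rarity.

Every input record receives an audit row with its verdicts; rejection
reasons are `MOI_NONE`, `FAIL_MAF`, `FAIL_CONSEQUENCE`, `FAIL_CADD`, or
`NO_ANNOTATION`. Survival is monotone in `cadd_min` (nonincreasing) and
`maf_max` (nondecreasing), and the per-policy pass sets are nested
`all ⊆ majority ⊆ any`; both properties are tested.

## 5. Tissue concordance

For each liver-assayed proband, the prioritized blood and liver calls are
compared as sets of `(variant key, zygosity)` pairs — identity is
genotype-level, so a site heterozygous in blood but homozygous in liver is
discordant, not shared. Proband status: *identical* (non-empty, equal
sets), *undetected* (both empty), *discordant* (otherwise). Liver-only
pairs are counted separately as putative somatic variants.

## 6. Gene-set overlap enrichment

For a query gene list of size `n` against a set of size `K` in a universe
of `N` genes with overlap `k`, the p-value is the hypergeometric upper
tail `P(X ≥ k)`, computed in log space (`scipy.stats.hypergeom.logsf`) so
tails near 1e-20 keep full precision; it is verified against exact
combinatorial enumeration for all small universes.

**Universe size `N = 40,075`** is a calibration constant back-solved so
that the computed tails reproduce a published set of ten overlap p-values
to 3 significant digits given their printed `n`, `K`, `k`; it is close to
the gene-symbol universe of the MSigDB-style collections these analyses
use, and it is overridable (`EnrichmentConfig.universe_size`,
`--universe`).

**Multiple testing** uses Benjamini–Hochberg step-up with an explicit
family size `m` (default 4,494 — the number of gene sets in the tested
collection), which may exceed the number of sets with non-zero overlap;
q-values are capped at 1 and verified against an independent step-up
implementation and against statsmodels when `m = len(p)`. Reported p and
q are rounded to 3 significant digits at the presentation layer only.

## 7. Synthetic cohort generator

`simulate_cohort(SimConfig(...))` builds families on a miniature genome
(chr1/chr2 at 1 Mb; chrX at 4 Mb whose declared PAR matches GRCh38 PAR1,
so default PAR handling applies unchanged). Defaults mirror a ~40-family
exome study: 56% male probands, `missing_parent_prob = 0.125` (one in
eight families is a child–mother duo), `liver_pair_prob = 0.44`.

Per family it plants one variant per inheritance mode (rare MAFs from a
Beta(0.5, 200) clipped below 0.009; CADD uniform on [15, 40];
protein-altering consequences) and 12 decoys, each violating exactly one
filter: `decoy_common` (MAF ≥ 0.02 in **all** databases, so it fails every
rarity policy), `decoy_benign` (CADD < 10), `decoy_synonymous`, and
`decoy_inherited` (rare and deleterious but with a transmission pattern
matching no mode). Optional noise: per-caller independent miss rate and
false-call rate, and liver-only somatic plants. Everything derives from a
single `numpy.random.default_rng(seed)` stream, so a config is
byte-reproducible, and a JSONL truth manifest allows exact scoring:
noise-free runs must give recall = precision = 1 with a diagonal mode
confusion matrix, and under miss rate `r` strict 3-caller consensus
survival must match `(1−r)³` within a 95% binomial CI.

Limitations of the generator: no linkage disequilibrium, no indels, no
shared variants between families, uniform position placement, and caller
errors independent across callers and variants.

## 8. Packaged reference fixtures

Three TSV fixtures ship inside the package (SHA-256 pinned):

- `table2.tsv` — 28 candidate trio variant rows (genotypes, three MAF
  columns, CADD) used for the end-to-end replay. Replaying them yields 28
  survivors in 25 genes; 17 X-linked / 6 de novo / 5 homozygous-recessive
  (61/21/18%), de novo calls in 5 distinct probands, max CADD 37. Note
  the 17 X-linked variants span 15 distinct genes (two genes recur in two
  unrelated probands each).
- `table3.tsv` — 18 proband blood/liver pairs; replay gives 8 identical,
  10 undetected, 0 discordant, 0 somatic. One undetected proband row is a
  reconstructed placeholder (`BA0XX`) completing the stated count of 18.
- `table4.tsv` — ten gene-set overlap rows (set sizes, overlaps, printed
  p/q) used to validate the enrichment arithmetic.

## 9. Numerical and tie-breaking choices

- Percentages in mode summaries are integers, rounded half-up, of the
  classified (non-`none`) total.
- `round_sig` rounds to 3 significant digits for display; internal
  computation always uses full precision (adjusting rounded p-values can
  shift a q-value in its third digit, which is why q-values are computed
  from unrounded p).
- Enrichment rows are sorted by (p, set name) for a deterministic order.
- Mode summaries deduplicate on (proband, variant key), so re-fed calls
  cannot double-count.

## 10. Limitations

- Classification considers a single variant at a time: compound
  heterozygosity, mosaicism, imprinting and mitochondrial inheritance are
  out of scope, as is chrY.
- The rarity filter treats databases as independent thresholds; no
  allele-count confidence modeling.
- Concordance is presence/absence at genotype level; it does not model
  allele fraction, so low-level somatic mosaicism in blood is invisible.
- The enrichment universe is a calibration constant, not a per-collection
  annotated-gene count; supply your own `N` for other collections.
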