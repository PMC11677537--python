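# Methods

This note documents the models, conventions and design choices behind the
package; the README covers usage.

## Coordinates and the gene model

All genomic coordinates are 1-based closed intervals, matching VCF POS
semantics. The packaged gene model (`src/metex14/data/met_grch37.yaml`)
holds *MET* exons 13–15 on GRCh37.p13 for transcript NM_000245, with
exon 14 the 141-bp in-frame exon whose loss produces METex14. The model is
a plain YAML file and can be replaced wholesale (other transcript, other
genome build, other gene); nothing in the code hard-codes positions. The
library handles minus-strand genes by mirroring the windows (acceptor at
the genomic-right exon end), although *MET* itself is plus-strand.

## Splice windows

Published analyses of METex14 never pin down exactly how many bases count
as "the splice region", so window extents are a `WindowConfig` with
defaults chosen from common clinical reporting practice:

| parameter | default | meaning |
|-----------|---------|---------|
| `acceptor_intronic_bp` | 25 | intron 13 bases upstream of the exon start (covers the branch/polypyrimidine region where skipping indels cluster) |
| `acceptor_exonic_bp` | 2 | first exonic bases |
| `donor_exonic_bp` | 2 | last exonic bases |
| `donor_intronic_bp` | 10 | intron 14 bases past the exon end (covers the donor consensus and common donor-site deletions) |

Overlap is interval intersection of the variant's affected reference span
([pos, pos + len(ref) − 1]); a deletion touching any window base counts,
even when the canonical GT/AG dinucleotide is intact, because donor-region
deletions are reported as positive METex14 DNA evidence in practice. A
side whose two extents are both zero has no window at all. Descriptions of
low-read patients' variants as lying in "the splice-donor region at the 5′
end of exon 14" conflate donor and acceptor geometry on a plus-strand
gene; rather than guess intent, the annotator always reports *which*
window was hit (acceptor, donor, or both) and the classifier accepts
either as DNA evidence.

## Filters

All "minimum"-phrased thresholds are inclusive (≥): AF ≥ 0.05 (SNV) /
0.07 (indel), alt reads ≥ 10, site depth ≥ 50, Phred quality ≥ 6 (SNV) /
20 (indel); sample QC gates ≥ 240 median reads per amplicon, ≥ 60 %
aligned DNA reads, ≥ 20,000 mapped RNA reads, ≥ 3 of 5 expression
controls. The single fusion retention rule is exclusive: strictly more
than 20 junction reads. Two alt-read phrasings ("minimum coverage that
admits a variant was 10×" and "alternative alleles with < 10 reads
removed") are treated as the same ≥ 10 alt-read rule; if the former meant
site depth the 50× site rule dominates anyway. Dropped records are kept in
an audit table with named failure reasons; a reported AF disagreeing with
alt/depth by more than 0.01 is flagged there rather than silently
accepted. The vendor hotspot list is modelled as an optional positional
allow-list (the list itself is proprietary); absent a list, all positions
are eligible. Multi-allelic VCF records are split per alternate allele
before filtering.

## Classification and concordance

The decision table is in the README. Two conventions deserve note. A
fusion record failing retention is treated exactly like an absent record —
it cannot rescue or be rescued. The positivity bound is **≥ 120** reads
(assay guides phrase it "at least 120"); occasional "> 120" phrasings in
the literature are read as loose language. Both thresholds are
configurable and stamped into every output.

DNA coverage for the read-count correlation is the alt-supporting read
count of the patient's best (maximum) splice-window variant, 0 when
undetected; `site_depth` can be selected instead via
`ClassifierConfig.coverage_metric`. The Pearson correlation uses the
ordinary product-moment estimator with the t-transform p-value (n − 2 df),
computed through `scipy.stats.pearsonr`; p-values are reported to 3
significant digits and no multiple-testing correction is applied (none is
conventional for these two correlations). `concordance_summary` accepts an
explicit low-read denominator override because published percentages for
this subgroup are quoted against 35 while the subgroup itself has 37
patients (see "fixture" below); the counts themselves are never altered.

## VUS triage

The consensus is deliberately strict — a conjunction over five predictors
— so removing any predictor can only enlarge the driver set (verified by
exhaustive 2^5 enumeration in the tests). CADD votes driver only strictly
above 25. CGI "known" and "predicted" driver labels both count as driver
votes: the distinction encodes evidence provenance, not direction. Missing
annotations raise by default; an `abstain` policy maps them to non-driver
votes, which can only make the consensus stricter. Variants already
classed actionable / likely actionable bypass prediction and are never
downgraded. The default domain table (JM 956–1009, TK 1078–1345, UniProt
P08581 numbering) ships as YAML and is overridable; residues outside every
domain map to "other".

The co-occurrence screen is set-membership only: the lung-actionable set
is the ASCO/ESMO NSCLC panel (EGFR, ALK, ROS1, ERBB2, MET, BRAF, KRAS,
RET, NTRK1/2/3); the any-solid set adds ESR1, ERBB4, PIK3CA, IDH2 and MTOR
(actionable elsewhere, not in lung). Both are config files, not a hidden
knowledge base.

## Cohort report

Prevalence is per patient (multiple variants in a gene count once), and a
patient–gene pair may come from either evidence stream: a retained fusion
record contributes its 3′ partner gene, since gene fusions are
protein-affecting variants. The two-cohort comparison uses a two-sided
Fisher exact test on the carrier/non-carrier 2×2 table — the significance
test behind published prevalence comparisons is rarely named, and Fisher
is the robust default for proportions; the test name is stamped into the
report. Reference-cohort prevalences enter as plain (count, n) numbers.
The clinical-significance breakdown takes an explicit denominator because
published percentages for these categories are not mutually consistent
with any single denominator (92 "VUS" patients is 53.7 % of the variant
count but 74.8 % of the 123 MET-variant patients); the package computes
over whatever denominator the caller states.

## Synthetic generator

`simulate_cohort` emulates the cohort structure the analysis assumes:

| parameter | default | rationale |
|-----------|---------|-----------|
| `met_variant_prevalence` | 123/1560 | observed MET-variant fraction |
| `fusion_detected_given_met` | 72/123 | detected-fusion fraction |
| `log_read_mean`, `log_read_sd` | 4.8, 2.6 | truncated log-normal reads spanning 21–67,000 with ≈ half the mass above 120 |
| `rho` | 0.45 | target observed Pearson (reads vs coverage, zeros imputed) |
| `dna_dropout_given_rna_pos` | 0.539 | DNA-undetected fraction among RNA-positives |
| `dna_dropout_given_lowread` | 0.8 | 20 % DNA-rescue rate in the low-read zone |
| `log_cov_mean`, `log_cov_sd` | 4.6, 1.0 | alt-coverage marginal (median ≈ 100 reads) |
| `af_mixture` | Beta(3,12) ⊕ Beta(40,40), weight 0.15 | somatic mode ≈ 0.2 plus a germline-like mode at 0.5 |

Reads and coverage are coupled by a Gaussian copula on the log scale. The
*latent* copula correlation is calibrated at generation time: the induced
observed correlation (after truncation, rounding, floor-at-25 coverage,
subgroup-specific dropout and zero imputation) is evaluated on a 25-point
latent grid with 150,000 common random numbers and inverted by monotone
interpolation. Calibration is deterministic given the seed, adds ≈ 0.5 s,
and adapts automatically when any marginal or dropout parameter changes.
Infeasible requests fail loudly: under the default dropout the maximum
achievable observed |r| is ≈ 0.57, so e.g. ρ = 0.8 raises a validation
error instead of silently undershooting (without dropout it is
achievable). A single `numpy` Generator seeded from `SimConfig.seed`
drives all randomness; outputs are byte-reproducible per seed and every
written file carries the seed and a config hash in a header comment.

What the generator does **not** emulate: per-read data (no FASTQ/BAM),
splice-site sequence motifs, panel-specific artefacts, tumour purity, or
any dependence of clinical covariates on genotype (covariates are drawn
independently at the published marginal frequencies, for realism only).
Passing tests therefore demonstrate correctness of the decision logic and
statistics under the assumed generative structure, not performance on real
sequencing data.

## The deterministic fixture

`build_published_fixture` encodes the published aggregate counts exactly:
1560 patients, 123 MET-variant carriers, 72 retained fusion records, 35 at
or above 120 reads (up to 67,000), 37 below, 7 of them DNA-rescued, 16/35
RNA-positives with DNA evidence (19 DNA-negative ≈ 54 %), 11 T992I and 6
H1094Y carriers with all-driver predictor profiles (7 of the 17 with no
other driver/actionable variant → 41.2 %), 20 of the low-read subgroup
with no co-occurring actionable variant (57.14 % against denominator 35)
rising to 25 (71.43 %) when the ESR1/ERBB4/PIK3CA co-occurrences are
excluded as non-actionable in lung, and background KRAS/ALK/ERBB2 carriers
fixing cohort prevalences at 20 %/9 %/8 %. The source counts contain one
internal inconsistency: the low-read subgroup is 37 patients, but the
percentages quoted for it (20 %, 57.14 %, 71.43 %) only reproduce with
denominator 35. The fixture realises 72 = 35 + 37, keeps the rescued count
at exactly 7, and records both 37 (`n_lowread`) and 35
(`lowread_percent_denominator`) in its manifest; percentage computations
take the manifest denominator explicitly. Per-patient read counts are not
published, so only aggregates are encoded — per-patient values
(log-spaced reads, jittered coverage, allele frequencies) are synthetic
and deterministic (fixed internal seed).

## Numerical and testing choices

Tolerances: Pearson vs the definitional formula to 1e-12; Fisher vs exact
rational hypergeometric-tail enumeration to 1e-9 relative; generator
correlation recovery to ±0.05 at 10,000 pairs (sampling s.e. ≈ 0.008 plus
calibration Monte-Carlo error ≈ 0.003). Problem sizes in the tests —
10,000-pair recovery runs, exhaustive interval oracles for spans ≤ 50 bp
within ±100 bp of the windows, exhaustive Fisher tables for cohorts ≤ 8
with a deterministic sample up to 30 — were chosen to keep the full suite
under ten seconds while leaving estimator noise an order of magnitude
below the asserted tolerances. Hypothesis runs derandomised. Ties and
degenerate inputs: zero-variance or < 3-pair correlations raise a
dedicated error rather than returning NaN; empty windows hit nothing;
boundary reads of exactly 20 are "not detected" and exactly 120 is
positive.

## Known limitations

* Window extents are a modelling choice, not a published constant; results
  near window edges depend on them (they are recorded in every output).
* The consensus triage consumes predictor outputs; it cannot recover from
  annotation errors upstream, and running SIFT/PolyPhen-2/CADD/
  MutationTaster/CGI is explicitly out of scope.
* The exon coordinate file should be re-derived from the user's own
  annotation release for production use; coordinates are config, not code.
* No therapy-response logic: how many fusion reads predict benefit from
  c-Met inhibition is an open clinical question the package does not
  answer.
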