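# Methods

## Sequence model

A guide strand is a 19-nt RNA core written 5′→3′ with 1-based positions; the
synthesized oligo carries a dTdT DNA overhang at the 3′ end. The overhang is
stored for display only: it never enters position arithmetic, seed
extraction or complementarity counts, since published position conventions
(seed = positions 2–8, mismatch window 9–11, degenerate positions 2 and 18)
index only the 19-nt core. Complementarity is strict Watson–Crick (A:U,
C:G); G:U wobble pairs are not treated as complementary, and the degenerate
base N never counts as a match when a concrete transcript is scanned —
degenerate designs are scored by expanding the pool and scanning each
member. Pool expansion is deterministic (A<C<G<U per N position, leftmost N
slowest) so member indices are reproducible.

## Off-target scanning

Two liabilities are scored per guide:

* **Complementary runs.** The longest contiguous transcript stretch
  complementary (antiparallel) to a contiguous guide stretch equals the
  longest common substring between the transcript and the guide's reverse
  complement. The scanner enumerates the 19-mer's substrings longest-first
  and uses exact substring search; the test suite verifies it against an
  independent O(n·m) dynamic program that pairs bases directly. A gene is an
  off-target when any of its transcripts carries a run **strictly longer
  than `run_threshold` = 12 nt** (a literal reading of "more than 12
  consecutive basepairs": 13+ counts, 12 does not), deduplicated by gene id.
  A guide passes when **strictly fewer than `gene_limit` = 2 genes** qualify
  — i.e. at most the intended target itself. `exclude_gene` removes the
  intended target from the count when only unintended genes matter.
* **Seed-complement frequency (SCF).** The count (and fraction) of
  UTR-annotated transcripts whose 3′UTR contains ≥ 1 exact occurrence of the
  reverse complement of the 7-mer seed (positions 2–8). The source concept
  is cited without a printed formula, so per-transcript counting (multiple
  occurrences in one UTR count once) was chosen as the most conservative
  transcript-level reading; an occurrence-level count would only rescale the
  ranking, not reorder ties in practice.

Pools aggregate conservatively: off-target genes are the union over
members, SCF the maximum. Only the guide strand is scanned; passenger-strand
off-targets are a chemistry problem (asymmetry, 2′-O-methyl) rather than a
sequence-screening one, and are out of scope.

## Design rules

Candidate sites are every 19-nt window of the target transcript with **zero
overlap** with the annotated 3′UTR ("avoided" read strictly). The Mismatch
control substitutes exactly one base at positions 9–11; among the 9 possible
substitutions the engine picks the one minimizing newly created liability
(fewest qualifying off-target genes, then lowest SCF), tie-broken by lower
position then base order A<C<G<U. The selection can be pinned
(`position=11, base="A"`) to reproduce a published control. Designs are
ranked by (gene-filter pass, ascending SCF, site position). The passenger
strand is emitted as the plain reverse complement of the guide core with
its own dTdT overhang; thermodynamic asymmetry optimization is not modeled.

## Assay quantification and classification

Fold change vs the untransfected blank control (0C) is 2^−ΔΔCt with
replicate Cts arithmetically averaged before differencing; the reference
gene (GAPDH by default) cancels per-sample loading shifts, which the tests
assert as an invariance property. Knockdown efficiency is
100 × (1 − fold change), clipped below at 0 for apparent up-regulation.

Pair screening: (i) Match knockdown strictly greater than 60 %;
(ii) Match − Mismatch ≥ 50. Criterion (ii) is stated as "50 % higher" in
prose, which is ambiguous between a relative and an absolute reading; the
absolute-gap interpretation (percentage points) is used because a relative
reading would accept useless pairs such as 3 % vs 2 %. Classification of a
passing pair uses a single viability threshold (default 0.80, the printed
boundary): Mismatch viability below threshold → `off_target_confounded`
(the negative control itself kills cells, so the phenotype follows the
off-target signature); else Match below threshold → `essential`; else
`non_essential`. Pairs failing the screen are `invalid_pair`. Using one
threshold for both arms (rather than a separate "approximately 1.0" band
for the Mismatch) keeps the classifier total and monotone.

The expression filters are strict inequalities at their printed values:
|fold change| > 1.5 two-sided (direction is not stated, and knockdown
experiments perturb both directions), raw P < 0.01 (no multiple-testing
correction by default, matching the raw-P convention; Benjamini–Hochberg is
available via `fdr=True`), and FPKM strictly > 20 in **every** sample for
qPCR validation candidates.

Table formats are plain TSV: Ct tables long-format
(`sample_id, gene_id, replicate, ct`), viability tables
(`gene_id, arm, viability`) and expression tables
(`gene_id, fpkm_<sample>…, fold_change, p_value`). The screen analyzer links
the two assay tables by a sample-naming convention: the Ct samples for a
pair are `<gene>_match` and `<gene>_mismatch`, with the blank control named
`0C`.

## Synthetic fixtures

The generators emulate the *structure* of the study conditions, not
biological realism. Transcripts have uniform base composition (or a set GC
fraction), lengths uniform on 300–800 nt, and the trailing 30 % annotated
as 3′UTR. Planted features overwrite bases in place so coordinates stay
stable, and the bases flanking a planted run are set non-complementary so
the run has exactly its nominal length. Assay tables mirror a 7-pair screen
(one essential, one off-target, five null genes — the shape of the
validation screen this toolkit is built around) with defaults chosen as
typical strong-assay values: planted knockdown 85 % (Match) / 5 %
(Mismatch), target baselines at Ct 22–26 against a reference at Ct 20,
replicate noise sd 0.1 cycles over 9 Ct measurements (3 independent
experiments × triplicate reactions, the standard qPCR protocol), and
viability reported as the mean of 9 wells with sd 0.02 around pattern means
(0.75 affected / 1.00 intact vs the 0.80 threshold). All randomness flows
from one integer seed through a local `numpy.random.Generator`; identical
seeds give byte-identical files.

What passing tests show — and don't: recovery of planted calls demonstrates
that the quantification and decision logic are correct at realistic effect
sizes and noise, not that real screens are this clean. Real data add qPCR
efficiency differences, plate effects, transfection variability and
transcript-isoform ambiguity that the generator deliberately omits. The
knockdown-recovery property is asserted as a bias check (mean recovered
knockdown over 100 seeded runs within 5 percentage points per arm, exact at
zero noise): a single run's estimate for a weak-knockdown arm has several
points of spread at realistic Ct noise, which is a property of the ΔΔCt
method, not of the implementation.

## Numerical and degenerate-input choices

* Thresholds are compared with the strict inequalities documented above; the
  acceptance script recovers each boundary on a grid rather than trusting
  configuration.
* Transcripts shorter than 19 nt yield no candidates (with a warning);
  scanning an empty transcriptome is an error, but Mismatch construction
  without a transcriptome is allowed and falls back to the deterministic
  tie-break.
* 1-based closed intervals are used throughout the file formats, matching
  the guide-position idiom; the annotation TSV documents this in a header
  comment.
* A fold change of exactly the threshold (1.5) or an FPKM of exactly 20 is
  excluded, and a 12-nt run is not an off-target — boundary probes in the
  tests pin each of these.

## Limitations

* Release-agnostic: results depend on the transcript set supplied; no
  specific RefSeq/Ensembl release is assumed or bundled.
* No mismatch-tolerant or wobble-tolerant run detection, no
  position-weighted seed scoring, no free-energy models.
* Efficacy prediction (rational-design scores, thermodynamic asymmetry) is
  out of scope; the toolkit screens for specificity, not potency.
* FPKM estimation, read alignment and GO enrichment belong to upstream and
  downstream tools.
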