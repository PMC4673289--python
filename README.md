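# sirnakit

RNAi screens dramatically overestimate which genes are essential: a large
fraction of siRNA-induced viability phenotypes come from off-target effects,
not from silencing the intended gene. `sirnakit` is a toolkit for designing
siRNAs that minimize off-target potential and for analyzing the paired
positive/negative-control assays that separate on-target from off-target
phenotypes. It is aimed at people building or validating RNAi screens:

* **Design.** For a target mRNA it enumerates 19-nt guide strands (5′→3′,
  dTdT overhang) whose target sites avoid the 3′UTR, rejects guides for which
  ≥ 2 genes carry a complementary stretch of **more than 12 consecutive
  basepairs**, and ranks the rest by seed-complement frequency (SCF) — the
  number of 3′UTRs containing the Watson–Crick complement of the guide seed
  (positions 2–8), which predicts miRNA-like off-target load.
* **Negative controls.** Each Match guide gets a **Mismatch** control with a
  single substitution at position 9–11 (the catalytic center), chosen to
  introduce the least new off-target liability: it abolishes on-target
  cleavage but keeps the off-target signature, so phenotypes shared by the
  pair are off-target.
* **Degenerate pools.** **sN** (N at position 2) and **dN** (N at positions
  2 and 18) variants expand to pools of 4 or 16 oligos that dilute each
  member's off-target footprint while preserving on-target silencing.
* **Assay analysis.** qPCR quantification by 2^−ΔΔCt (ΔCt = Ct(target) −
  Ct(GAPDH); ΔΔCt = ΔCt(sample) − ΔCt(blank control)), pair screening
  (Match knockdown > 60 %, Match − Mismatch ≥ 50 points), and essential /
  off-target-confounded / non-essential calls from cell-viability ratios at
  the 0.80 threshold. Expression-table utilities cover the two-sided
  differential-expression filter (|fold change| > 1.5, P < 0.01) and the
  FPKM > 20 validation-candidate filter.
* **Synthetic fixtures.** Seeded generators plant complementary runs, seed
  matches and assay effect patterns with a ground-truth manifest, so the
  whole pipeline is testable without any external data.

## Worked example

```sh
python examples/analyze_screen.py
```

simulates a 7-pair Match/Mismatch screen (one planted essential gene, one
off-target-confounded gene) and classifies it:

```
gene_id  kd_match  kd_mismatch  viability_match  viability_mismatch  screen_pass                  call
  GENE1    86.133       11.084            0.750               0.999         True             essential
  GENE2    84.803        3.724            0.753               0.746         True off_target_confounded
  GENE3    85.101        3.769            0.988               1.000         True         non_essential
  ...
call counts: essential=1, off_target_confounded=1, non_essential=5, invalid_pair=0
```

GENE1 shows the essential pattern — the Match siRNA knocks the target down
86 % and drops viability below 0.80 while the Mismatch control leaves cells
intact — whereas GENE2's Mismatch also kills cells, so its phenotype is
attributed to off-targets. The other examples cover design
(`design_sirnas.py`), off-target scanning (`scan_offtargets.py`) and
expression filtering (`expression_filtering.py`).

The same capabilities are exposed on the command line:

```sh
sirnakit simulate --outdir fx --seed 5 --guide ACCGUAUGAAGUACUUGGC --plant-run 1:13
sirnakit scan --guide ACCGUAUGAAGUACUUGGC --fasta fx/transcripts.fasta \
              --annotation fx/annotation.tsv --out scan_report
sirnakit design --fasta fx/transcripts.fasta --annotation fx/annotation.tsv \
                --target-gene GENE3 --out designs.tsv
sirnakit analyze --ct fx/ct.tsv --viability fx/viability.tsv --out screen
```

## Scope

The toolkit covers design and desk analysis only: read alignment and FPKM
estimation, GO enrichment, thermodynamic strand-selection modeling and
chemical-modification design are out of scope. See `docs/methods.md` for the
model, parameter defaults and limitations.
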