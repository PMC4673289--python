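"""Seeded synthetic fixtures with planted ground truth.

Every component of the toolkit is testable offline against fixtures whose
truth is known by construction:

* :func:`gen_transcriptome` draws random-composition transcripts (uniform
  over A/C/G/U, or at a requested GC fraction) and plants features relative
  to a chosen guide — exact complementary stretches of a given length, or
  seed-complement matches inside the annotated 3'UTR.  Planted features
  overwrite bases in place (length-preserving) so recorded coordinates stay
  valid, and the flanking bases are broken so a planted run has exactly its
  nominal length.

* :func:`gen_assay_tables` emulates the structure of a Match/Mismatch
  viability screen: qPCR Ct tables built from a per-gene baseline plus the
  planted knockdown effect plus Gaussian replicate noise, and viability
  ratios drawn per planted pattern (essential: Match arm below threshold,
  Mismatch intact; off-target: both arms depressed; null: both intact).
  The default plan mirrors a 7-pair screen with one essential and one
  off-target gene.

All randomness flows from a single integer seed through a local
``numpy.random.Generator``; identical seeds give byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sequences import GuideStrand, NucSeq, reverse_complement, seed as guide_seed
from .transcriptome import Transcript, Transcriptome, write_transcriptome

RNA_BASES = "ACGU"

AssayPattern = Literal["essential", "off_target", "null"]


@dataclass(frozen=True)
class PlantedRun:
    """An exact complementary stretch to the guide, planted in one transcript.

    ``length`` transcript bases complementary to guide positions
    ``guide_start..guide_start+length-1`` are written at ``position``
    (1-based; defaults near the middle of the transcript's non-UTR region).
    """

    transcript_index: int
    length: int
    guide_start: int = 1
    position: Optional[int] = None


@dataclass(frozen=True)
class PlantedSeedMatch:
    """One exact seed-complement occurrence inside a transcript's 3'UTR."""

    transcript_index: int


@dataclass(frozen=True)
class AssayPlanEntry:
    """Planted truth for one Match/Mismatch pair."""

    gene_id: str
    pattern: AssayPattern
    kd_match: float = 85.0  # planted knockdown efficiency, %
    kd_mismatch: float = 5.0
    viability_match: Optional[float] = None  # defaults set by pattern
    viability_mismatch: Optional[float] = None

    def resolved(self) -> "AssayPlanEntry":
        defaults = {
            "essential": (0.75, 1.0),
            "off_target": (0.75, 0.75),
            "null": (1.0, 1.0),
        }[self.pattern]
        vm = self.viability_match if self.viability_match is not None else defaults[0]
        vmm = self.viability_mismatch if self.viability_mismatch is not None else defaults[1]
        return dataclasses.replace(self, viability_match=vm, viability_mismatch=vmm)


@dataclass(frozen=True)
class FixtureSpec:
    """Everything a fixture build needs; same seed, same bytes."""

    seed: int
    n_transcripts: int = 12
    length_range: tuple[int, int] = (300, 800)
    utr3_fraction: float = 0.3  # trailing fraction of each transcript
    gc_fraction: Optional[float] = None  # None = uniform composition
    planted_runs: tuple[PlantedRun, ...] = ()
    planted_seed_matches: tuple[PlantedSeedMatch, ...] = ()
    assay_plan: tuple[AssayPlanEntry, ...] = ()


def default_assay_plan() -> tuple[AssayPlanEntry, ...]:
    """A 7-pair screen: one essential, one off-target, five null genes."""
    entries = [
        AssayPlanEntry("GENE1", "essential"),
        AssayPlanEntry("GENE2", "off_target"),
    ]
    entries += [AssayPlanEntry(f"GENE{i}", "null") for i in range(3, 8)]
    return tuple(entries)


def _random_rna(rng: np.random.Generator, n: int, gc: Optional[float]) -> str:
    if gc is None:
        p = None
    else:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(RNA_BASES), size=n, p=p))


def _break_base(neighbor_complement: str, rng: np.random.Generator) -> str:
    """A base that is NOT ``neighbor_complement`` (prevents run extension)."""
    choices = [b for b in RNA_BASES if b != neighbor_complement]
    return choices[rng.integers(len(choices))]


def gen_transcriptome(
    spec: FixtureSpec, guide: Optional[GuideStrand] = None
) -> tuple[Transcriptome, dict]:
    """Build a seeded transcriptome with planted features and a truth manifest.

    ``guide`` is required when the spec plants runs or seed matches.  The
    manifest records every planted feature with its final coordinates.
    """
    if (spec.planted_runs or spec.planted_seed_matches) and guide is None:
        raise ValidationError("planted features require a guide")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_transcripts)
    seqs = [list(_random_rna(rng, int(n), spec.gc_fraction)) for n in lengths]
    utrs: list[Optional[tuple[int, int]]] = []
    for n in lengths:
        if spec.utr3_fraction > 0:
            start = int(n) - max(1, int(round(spec.utr3_fraction * int(n)))) + 1
            utrs.append((start, int(n)))
        else:
            utrs.append(None)

    manifest: dict = {"seed": spec.seed, "planted_runs": [], "planted_seed_matches": []}

    for pr in spec.planted_runs:
        i = pr.transcript_index
        if not 0 <= i < spec.n_transcripts:
            raise ValidationError(f"transcript_index {i} out of range")
        n = int(lengths[i])
        if pr.length > n:
            raise ValidationError(
                f"planted run of {pr.length} nt does not fit transcript of {n} nt"
            )
        if not 1 <= pr.guide_start <= GuideStrand.CORE_LENGTH - pr.length + 1:
            raise ValidationError("planted run falls off the guide")
        rc = reverse_complement(guide.core).residues
        # guide positions p..p+L-1 correspond, antiparallel, to rc indices
        # 19-(p+L-1) .. 19-p  (0-based)
        o = GuideStrand.CORE_LENGTH - (pr.guide_start + pr.length - 1)
        segment = rc[o : o + pr.length]
        utr_start = utrs[i][0] if utrs[i] else n + 1
        pos = pr.position if pr.position is not None else max(1, (utr_start - pr.length) // 2)
        if pos + pr.length - 1 > n:
            raise ValidationError("planted run overruns the transcript")
        seqs[i][pos - 1 : pos - 1 + pr.length] = list(segment)
        if pos > 1 and o > 0:
            seqs[i][pos - 2] = _break_base(rc[o - 1], rng)
        right = pos + pr.length  # 1-based base just past the run
        if right <= n and o + pr.length < len(rc):
            seqs[i][right - 1] = _break_base(rc[o + pr.length], rng)
        manifest["planted_runs"].append(
            {"transcript_index": i, "length": pr.length, "position": pos,
             "guide_start": pr.guide_start}
        )

    for ps in spec.planted_seed_matches:
        i = ps.transcript_index
        if utrs[i] is None:
            raise ValidationError("seed match requires a UTR-annotated transcript")
        probe = reverse_complement(guide_seed(guide)).residues
        u_start, u_end = utrs[i]
        if u_end - u_start + 1 < len(probe):
            raise ValidationError("3'UTR shorter than the seed complement")
        pos = u_start + (u_end - u_start + 1 - len(probe)) // 2
        seqs[i][pos - 1 : pos - 1 + len(probe)] = list(probe)
        manifest["planted_seed_matches"].append(
            {"transcript_index": i, "position": pos}
        )

    transcripts = [
        Transcript(
            transcript_id=f"TX{i + 1:03d}",
            gene_id=f"GENE{i + 1}",
            sequence=NucSeq("".join(s), "RNA"),
            utr3=utrs[i],
        )
        for i, s in enumerate(seqs)
    ]
    return Transcriptome(transcripts), manifest


def gen_assay_tables(
    plan: Sequence[AssayPlanEntry] | None = None,
    seed: int = 0,
    noise_sd_ct: float = 0.1,  # cycles, per replicate
    n_ct_replicates: int = 9,  # 3 independent experiments x triplicate reactions
    viability_well_sd: float = 0.02,
    n_viability_wells: int = 9,  # 3 independent experiments x triplicate wells
    reference_gene: str = "GAPDH",
    control_sample: str = "0C",
    reference_ct: float = 20.0,
    baseline_ct_range: tuple[float, float] = (22.0, 26.0),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Emulated qPCR Ct and viability tables for a Match/Mismatch screen.

    For each planned gene the Ct table carries the blank control plus
    ``<gene>_match`` / ``<gene>_mismatch`` samples; the target's arm Ct is
    the gene baseline shifted by -log2(1 - kd/100) so the ddCt method
    recovers the planted knockdown.  Reported viability is the mean of
    ``n_viability_wells`` noisy wells, as a plate assay would average.
    Returns (ct_table, viability_table, manifest).
    """
    if plan is None:
        plan = default_assay_plan()
    plan = [e.resolved() for e in plan]
    rng = np.random.default_rng(seed)

    ct_rows: list[dict] = []
    viab_rows: list[dict] = []

    def add_ct(sample: str, gene: str, mean_ct: float) -> None:
        for rep in range(1, n_ct_replicates + 1):
            ct_rows.append(
                {
                    "sample_id": sample,
                    "gene_id": gene,
                    "replicate": rep,
                    "ct": mean_ct + rng.normal(0.0, noise_sd_ct),
                }
            )

    baselines = {
        e.gene_id: rng.uniform(*baseline_ct_range) for e in plan
    }
    add_ct(control_sample, reference_gene, reference_ct)
    for e in plan:
        add_ct(control_sample, e.gene_id, baselines[e.gene_id])
    for e in plan:
        for arm, kd in (("match", e.kd_match), ("mismatch", e.kd_mismatch)):
            sample = f"{e.gene_id}_{arm}"
            fc = 1.0 - kd / 100.0
            add_ct(sample, reference_gene, reference_ct)
            add_ct(sample, e.gene_id, baselines[e.gene_id] - np.log2(fc))
        for arm, v in (
            ("match", e.viability_match),
            ("mismatch", e.viability_mismatch),
        ):
            wells = rng.normal(v, viability_well_sd, size=n_viability_wells)
            viab_rows.append(
                {
                    "gene_id": e.gene_id,
                    "arm": arm,
                    "viability": float(np.clip(wells, 0.0, None).mean()),
                }
            )

    expected_call = {"essential": "essential", "off_target": "off_target_confounded",
                     "null": "non_essential"}
    manifest = {
        "seed": seed,
        "plan": [dataclasses.asdict(e) for e in plan],
        "expected_calls": {e.gene_id: expected_call[e.pattern] for e in plan},
    }
    ct_df = pd.DataFrame(ct_rows, columns=["sample_id", "gene_id", "replicate", "ct"])
    viab_df = pd.DataFrame(viab_rows, columns=["gene_id", "arm", "viability"])
    return ct_df, viab_df, manifest


def gen_expression_table(
    seed: int = 0,
    n_genes: int = 200,
    n_de: int = 20,
    n_samples: int = 3,
    de_fold_change: float = 3.0,
    fpkm_log_mean: float = 3.0,
    fpkm_log_sd: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """A per-gene expression table with planted differentially expressed genes.

    The first ``n_de`` genes get fold change ``de_fold_change`` (alternating
    up/down) with small p-values; the rest sit near 1.0 with uniform
    p-values.  FPKMs are log-normal per sample.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    fc = np.exp(rng.normal(0.0, 0.05, size=n_genes))
    p = rng.uniform(0.05, 1.0, size=n_genes)
    de_genes = []
    for i in range(n_de):
        fc[i] = de_fold_change if i % 2 == 0 else 1.0 / de_fold_change
        p[i] = rng.uniform(1e-6, 0.005)
        de_genes.append(gene_ids[i])
    data = {"gene_id": gene_ids}
    for s in range(1, n_samples + 1):
        data[f"fpkm_s{s}"] = np.exp(rng.normal(fpkm_log_mean, fpkm_log_sd, size=n_genes))
    data["fold_change"] = fc
    data["p_value"] = p
    return pd.DataFrame(data), {"seed": seed, "de_genes": de_genes}


def write_fixture(
    outdir: str | Path,
    spec: FixtureSpec,
    guide: Optional[GuideStrand] = None,
) -> dict:
    """Materialize a fixture on disk: FASTA, annotation TSV, assay TSVs and a
    manifest JSON.  Returns the combined manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tx, manifest = gen_transcriptome(spec, guide)
    write_transcriptome(tx, outdir / "transcripts.fasta", outdir / "annotation.tsv")
    if spec.assay_plan:
        ct, viab, assay_manifest = gen_assay_tables(spec.assay_plan, seed=spec.seed)
        ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)
        viab.to_csv(outdir / "viability.tsv", sep="\t", index=False)
        manifest["assays"] = assay_manifest
    if guide is not None:
        manifest["guide"] = str(guide)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
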