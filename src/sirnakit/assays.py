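"""Quantification and classification of paired knockdown/viability assays.

Relative expression comes from qPCR cycle thresholds by the 2^-ddCt method:

    dCt  = Ct(target) - Ct(reference)            per sample, replicates averaged
    ddCt = dCt(sample) - dCt(blank control)
    fold change = 2^-ddCt                         (1.0 = unchanged vs blank)

with GAPDH as the default reference gene and "0C" (mock-transfected blank)
as the control sample.  Knockdown efficiency is 100 x (1 - fold change),
clipped below at zero.

A Match/Mismatch pair enters classification only if it passes the screen:
(i) Match knockdown > 60% of the blank control, and (ii) Match knockdown at
least 50 percentage points above Mismatch.  Passing pairs are called from
cell-viability ratios (sample absorbance / blank control): a Mismatch arm
dropping viability below threshold flags the phenotype as off-target-driven;
otherwise a sub-threshold Match arm calls the gene essential.

Expression-table utilities mirror the RNA-seq follow-up: a two-sided
differential-expression filter (|fold change| > 1.5, P < 0.01) and a
qPCR-validation candidate filter (FPKM > 20 in every sample).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_REFERENCE_GENE = "GAPDH"
DEFAULT_CONTROL_SAMPLE = "0C"
DEFAULT_KD_MIN = 60.0  # %, criterion (i), strict
DEFAULT_KD_GAP_MIN = 50.0  # percentage points, criterion (ii)
DEFAULT_VIABILITY_THRESHOLD = 0.80
DEFAULT_FC_MIN = 1.5  # fold, strict, two-sided
DEFAULT_P_MAX = 0.01  # strict
DEFAULT_FPKM_MIN = 20.0  # strict, per sample

CT_COLUMNS = ["sample_id", "gene_id", "replicate", "ct"]
VIABILITY_COLUMNS = ["gene_id", "arm", "viability"]


class PairCall(str, enum.Enum):
    """Outcome of classifying one Match/Mismatch pair."""

    ESSENTIAL = "essential"
    OFF_TARGET_CONFOUNDED = "off_target_confounded"
    NON_ESSENTIAL = "non_essential"
    INVALID_PAIR = "invalid_pair"

    def __str__(self) -> str:  # report-friendly
        return self.value


@dataclass
class PairAssayRecord:
    """Knockdown and viability outcomes for one Match/Mismatch pair."""

    gene_id: str
    kd_match: float  # knockdown efficiency, %
    kd_mismatch: float
    viability_match: float  # ratio to blank control
    viability_mismatch: float
    screen_pass: Optional[bool] = None
    call: Optional[PairCall] = None

    def __post_init__(self) -> None:
        if self.viability_match < 0 or self.viability_mismatch < 0:
            raise ValidationError(f"{self.gene_id}: viability must be >= 0")
        if self.kd_match > 100 or self.kd_mismatch > 100:
            raise ValidationError(f"{self.gene_id}: knockdown efficiency exceeds 100%")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format Ct TSV: sample_id, gene_id, replicate, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table missing column(s) {sorted(missing)}")
    bad = df[~np.isfinite(df["ct"]) | (df["ct"] <= 0)]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"Ct table row (sample {row.sample_id!r}, gene {row.gene_id!r}): "
            f"ct must be finite and > 0, got {row.ct!r}"
        )
    return df


def read_viability_table(path: str | Path) -> pd.DataFrame:
    """Viability TSV: gene_id, arm (match|mismatch), viability ratio."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "arm": str})
    missing = set(VIABILITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"viability table missing column(s) {sorted(missing)}")
    bad_arm = set(df["arm"]) - {"match", "mismatch"}
    if bad_arm:
        raise ValidationError(f"viability arm(s) {sorted(bad_arm)} not in {{match, mismatch}}")
    return df


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Expression TSV: gene_id, fpkm_<sample>..., fold_change, p_value."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    needed = {"gene_id", "fold_change", "p_value"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"expression table missing column(s) {sorted(missing)}")
    if not fpkm_columns(df):
        raise ValidationError("expression table has no fpkm_<sample> columns")
    return df


def fpkm_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("fpkm_")]


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    control_sample: str = DEFAULT_CONTROL_SAMPLE,
) -> pd.Series:
    """Per-sample fold change of ``target_gene`` by the 2^-ddCt method.

    Replicate Cts are arithmetically averaged before differencing.  Returns a
    Series indexed by sample_id (the control sample maps to exactly 1.0).
    Raises when the reference gene or the control sample is absent for any
    sample that carries a target measurement.
    """
    means = (
        ct_table.groupby(["sample_id", "gene_id"], sort=False)["ct"].mean().unstack()
    )
    if reference_gene not in means.columns:
        raise ValidationError(f"reference gene {reference_gene!r} absent from Ct table")
    if target_gene not in means.columns:
        raise ValidationError(f"target gene {target_gene!r} absent from Ct table")
    sub = means[[target_gene, reference_gene]]
    sub = sub[sub[target_gene].notna()]  # samples where the target was assayed
    if control_sample not in sub.index:
        raise ValidationError(
            f"control sample {control_sample!r} lacks a Ct for {target_gene!r}"
        )
    gaps = sub[sub[reference_gene].isna()]
    if len(gaps):
        raise ValidationError(
            f"sample {gaps.index[0]!r} lacks a Ct for reference gene {reference_gene!r}"
        )
    dct = sub[target_gene] - sub[reference_gene]
    ddct = dct - dct.loc[control_sample]
    fc = np.power(2.0, -ddct)
    fc.name = "fold_change"
    return fc


def knockdown_efficiency(fold_change: float) -> float:
    """Percent knockdown vs the blank control: 100 x (1 - fold change).

    Fold changes above 1 (apparent up-regulation) clip to 0% knockdown.
    """
    return max(0.0, 100.0 * (1.0 - fold_change))


def screen_pair(
    record: PairAssayRecord,
    kd_min: float = DEFAULT_KD_MIN,
    kd_gap_min: float = DEFAULT_KD_GAP_MIN,
) -> bool:
    """Pair-screening criteria: (i) Match knockdown strictly above ``kd_min``
    percent, and (ii) Match at least ``kd_gap_min`` percentage points above
    Mismatch."""
    return (record.kd_match > kd_min) and (
        record.kd_match - record.kd_mismatch >= kd_gap_min
    )


def classify_pair(
    record: PairAssayRecord,
    viability_threshold: float = DEFAULT_VIABILITY_THRESHOLD,
) -> PairCall:
    """Call one screened pair from its viability ratios.

    A pair that failed the screen is uninterpretable (invalid).  A Mismatch
    arm below threshold means the phenotype follows the off-target signature
    shared by both oligos; otherwise a Match arm below threshold is an
    on-target viability effect and the gene is called essential.
    """
    if record.screen_pass is None:
        raise ValidationError(f"{record.gene_id}: run screen_pair first")
    if not record.screen_pass:
        return PairCall.INVALID_PAIR
    if record.viability_mismatch < viability_threshold:
        return PairCall.OFF_TARGET_CONFOUNDED
    if record.viability_match < viability_threshold:
        return PairCall.ESSENTIAL
    return PairCall.NON_ESSENTIAL


def analyze_screen(
    ct_table: pd.DataFrame,
    viability_table: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    control_sample: str = DEFAULT_CONTROL_SAMPLE,
    kd_min: float = DEFAULT_KD_MIN,
    kd_gap_min: float = DEFAULT_KD_GAP_MIN,
    viability_threshold: float = DEFAULT_VIABILITY_THRESHOLD,
) -> list[PairAssayRecord]:
    """Quantify and classify every Match/Mismatch pair in a screen.

    The Ct table must contain, per gene in the viability table, samples named
    ``<gene>_match`` and ``<gene>_mismatch`` plus the blank control sample.
    """
    records: list[PairAssayRecord] = []
    if viability_table.empty:
        return records
    viab = viability_table.pivot_table(
        index="gene_id", columns="arm", values="viability", aggfunc="mean"
    )
    for gene_id in viab.index:
        fc = ddct_fold_change(ct_table, gene_id, reference_gene, control_sample)
        try:
            fc_match = fc.loc[f"{gene_id}_match"]
            fc_mismatch = fc.loc[f"{gene_id}_mismatch"]
        except KeyError as e:
            raise ValidationError(f"Ct table lacks sample {e.args[0]!r}") from None
        rec = PairAssayRecord(
            gene_id=gene_id,
            kd_match=knockdown_efficiency(fc_match),
            kd_mismatch=knockdown_efficiency(fc_mismatch),
            viability_match=float(viab.loc[gene_id, "match"]),
            viability_mismatch=float(viab.loc[gene_id, "mismatch"]),
        )
        rec.screen_pass = screen_pair(rec, kd_min=kd_min, kd_gap_min=kd_gap_min)
        rec.call = classify_pair(rec, viability_threshold=viability_threshold)
        records.append(rec)
    return records


def screen_report(records: list[PairAssayRecord]) -> pd.DataFrame:
    """Classification report: one row per pair plus call counts in attrs."""
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "kd_match": r.kd_match,
                "kd_mismatch": r.kd_mismatch,
                "viability_match": r.viability_match,
                "viability_mismatch": r.viability_mismatch,
                "screen_pass": r.screen_pass,
                "call": str(r.call),
            }
            for r in records
        ],
        columns=[
            "gene_id", "kd_match", "kd_mismatch",
            "viability_match", "viability_mismatch", "screen_pass", "call",
        ],
    )
    df.attrs["call_counts"] = {
        call.value: int((df["call"] == call.value).sum()) for call in PairCall
    }
    return df


def de_filter(
    table: pd.DataFrame,
    fc_min: float = DEFAULT_FC_MIN,
    p_max: float = DEFAULT_P_MAX,
    fdr: bool = False,
) -> pd.DataFrame:
    """Differentially expressed records: |fold change| > fc_min (two-sided,
    strict) and p_value < p_max (strict).

    ``fdr=True`` applies Benjamini-Hochberg to the p-values first (off by
    default; the screen's printed threshold is a raw P).
    """
    p = table["p_value"].to_numpy(dtype=float)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    fc = table["fold_change"].to_numpy(dtype=float)
    magnitude = np.maximum(fc, 1.0 / fc)
    keep = (magnitude > fc_min) & (p < p_max)
    return table.loc[keep].reset_index(drop=True)


def validation_candidates(
    table: pd.DataFrame,
    fpkm_min: float = DEFAULT_FPKM_MIN,
    k: Optional[int] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Records expressed above ``fpkm_min`` (strict) in *every* sample,
    ordered by gene_id; optionally a seeded random subsample of size ``k``
    (for picking genes to validate by qPCR)."""
    cols = fpkm_columns(table)
    if not cols:
        raise ValidationError("no fpkm_<sample> columns in expression table")
    keep = (table[cols] > fpkm_min).all(axis=1)
    out = table.loc[keep].sort_values("gene_id", kind="stable").reset_index(drop=True)
    if k is not None:
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(out), size=min(k, len(out)), replace=False))
        out = out.iloc[idx].reset_index(drop=True)
    return out
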