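"""Design of Match siRNAs and their Mismatch / sN / dN companions.

A **Match** guide is the exact reverse complement of a 19-nt target site on
the mRNA, chosen outside the 3'UTR.  Its **Mismatch** negative control
substitutes one base at guide position 9-11 — the catalytic center — which
abolishes on-target cleavage while preserving the guide's off-target
signature, so any phenotype shared by the pair is attributable to
off-targets.  The substitution is chosen to minimize newly created off-target
liability.  **sN** and **dN** carry the degenerate base N at position 2, or
at positions 2 and 18, turning one oligo into a pool of 4 or 16 sequences
that dilutes each member's off-target footprint while the shared core keeps
the on-target effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

from .errors import ValidationError
from .offtarget import (
    DEFAULT_GENE_LIMIT,
    DEFAULT_RUN_THRESHOLD,
    ScanResult,
    scan,
)
from .sequences import GuideStrand, diff_positions, reverse_complement
from .transcriptome import Transcript, Transcriptome

logger = logging.getLogger(__name__)

#: Guide positions where the Mismatch substitution may sit (catalytic center).
MISMATCH_POSITIONS = (9, 10, 11)
#: Degenerate positions of the sN / dN variants.
SN_POSITION = 2
DN_POSITIONS = (2, 18)

REPORT_COLUMNS = [
    "target_gene",
    "transcript_id",
    "site_start",
    "site_end",
    "match",
    "mismatch",
    "mismatch_position",
    "sN",
    "dN",
    "offtarget_gene_count",
    "scf",
]


@dataclass(frozen=True)
class SiRNADesign:
    """A Match guide with its target coordinates and derived variants."""

    target_gene: str
    transcript_id: str
    site_start: int  # 1-based closed interval on the transcript
    site_end: int
    match: GuideStrand
    mismatch: Optional[GuideStrand] = None
    mismatch_position: Optional[int] = None
    sN: Optional[GuideStrand] = None
    dN: Optional[GuideStrand] = None
    scan_result: Optional[ScanResult] = None

    def __post_init__(self) -> None:
        if self.site_end - self.site_start + 1 != GuideStrand.CORE_LENGTH:
            raise ValidationError("target site must span exactly 19 nt")
        if self.mismatch is not None:
            diffs = diff_positions(self.match, self.mismatch)
            if diffs != [self.mismatch_position] or self.mismatch_position not in MISMATCH_POSITIONS:
                raise ValidationError(
                    f"mismatch must differ at exactly one position in {MISMATCH_POSITIONS}, got {diffs}"
                )
        if self.sN is not None and (
            diff_positions(self.match, self.sN) != [SN_POSITION]
            or self.sN.core.position(SN_POSITION) != "N"
        ):
            raise ValidationError("sN must carry N at position 2 and match elsewhere")
        if self.dN is not None and (
            diff_positions(self.match, self.dN) != list(DN_POSITIONS)
            or any(self.dN.core.position(p) != "N" for p in DN_POSITIONS)
        ):
            raise ValidationError("dN must carry N at positions 2 and 18 and match elsewhere")


def guide_for_site(target: Transcript, start: int) -> GuideStrand:
    """The Match guide for the 19-nt site starting at 1-based ``start``."""
    window = target.sequence.subseq(start, start + GuideStrand.CORE_LENGTH - 1)
    return GuideStrand(reverse_complement(window))


def enumerate_candidates(target: Transcript) -> list[SiRNADesign]:
    """All 19-nt target windows avoiding the 3'UTR, as match-only designs.

    The 3'UTR is avoided entirely: a window overlapping the annotated UTR
    interval by even one base is rejected.  Transcripts shorter than 19 nt
    yield an empty list with a warning.
    """
    n = len(target)
    if n < GuideStrand.CORE_LENGTH:
        warnings.warn(
            f"transcript {target.transcript_id!r} shorter than 19 nt; no candidates",
            stacklevel=2,
        )
        return []
    designs = []
    for start in range(1, n - GuideStrand.CORE_LENGTH + 2):
        end = start + GuideStrand.CORE_LENGTH - 1
        if target.utr3 is not None:
            u_start, u_end = target.utr3
            if start <= u_end and end >= u_start:  # any overlap
                continue
        designs.append(
            SiRNADesign(
                target_gene=target.gene_id,
                transcript_id=target.transcript_id,
                site_start=start,
                site_end=end,
                match=guide_for_site(target, start),
            )
        )
    return designs


def make_mismatch(
    match: GuideStrand,
    transcriptome: Optional[Transcriptome] = None,
    run_threshold: int = DEFAULT_RUN_THRESHOLD,
    exclude_gene: str | None = None,
    position: Optional[int] = None,
    base: Optional[str] = None,
) -> tuple[GuideStrand, int]:
    """Build the single-substitution Mismatch control for a Match guide.

    Considers the 9 candidate substitutions (positions 9-11 x 3 alternative
    bases) and picks the one introducing the least new off-target liability
    against ``transcriptome``: fewest genes with qualifying complementary
    runs, then lowest seed-complement frequency; ties break to the lower
    position, then base order A<C<G<U.  With no transcriptome (or an empty
    one) all candidates tie and the first in that order wins.  ``position``
    and/or ``base`` pin the choice, e.g. to reproduce a published control.
    """
    if not match.is_concrete:
        raise ValidationError("Mismatch controls are built from concrete Match guides")
    positions = (position,) if position is not None else MISMATCH_POSITIONS
    if position is not None and position not in MISMATCH_POSITIONS:
        raise ValidationError(f"mismatch position must be in {MISMATCH_POSITIONS}")
    best = None
    for pos in positions:
        current = match.core.position(pos)
        for bi, b in enumerate("ACGU"):
            if b == current or (base is not None and b != base):
                continue
            candidate = match.substitute(pos, b)
            if transcriptome is not None and len(transcriptome) > 0:
                r = scan(
                    candidate,
                    transcriptome,
                    run_threshold=run_threshold,
                    exclude_gene=exclude_gene,
                )
                score = (len(r.offtarget_genes), r.scf_count)
            else:
                score = (0, 0)
            key = (score, pos, bi)
            if best is None or key < best[0]:
                best = (key, candidate, pos)
    if best is None:
        raise ValidationError("no admissible mismatch substitution (base pinned to current?)")
    return best[1], best[2]


def make_sN(match: GuideStrand) -> GuideStrand:
    """The sN variant: degenerate N at guide position 2."""
    return match.substitute(SN_POSITION, "N")


def make_dN(match: GuideStrand) -> GuideStrand:
    """The dN variant: degenerate Ns at guide positions 2 and 18."""
    g = match
    for p in DN_POSITIONS:
        g = g.substitute(p, "N")
    return g


def passenger_strand(match: GuideStrand) -> GuideStrand:
    """The sense strand of the duplex: reverse complement of the guide core
    with its own dTdT overhang.  Thermodynamic asymmetry is not modeled."""
    return GuideStrand(reverse_complement(match.core))


def complete_design(
    design: SiRNADesign,
    transcriptome: Optional[Transcriptome] = None,
    run_threshold: int = DEFAULT_RUN_THRESHOLD,
) -> SiRNADesign:
    """Fill in Mismatch, sN and dN variants for a match-only design."""
    mm, pos = make_mismatch(
        design.match, transcriptome, run_threshold=run_threshold
    )
    return replace(
        design,
        mismatch=mm,
        mismatch_position=pos,
        sN=make_sN(design.match),
        dN=make_dN(design.match),
    )


def design_sirnas(
    tx: Transcriptome,
    target_gene: str,
    top_k: int = 5,
    run_threshold: int = DEFAULT_RUN_THRESHOLD,
    gene_limit: int = DEFAULT_GENE_LIMIT,
) -> list[SiRNADesign]:
    """End-to-end design for one gene: enumerate, scan, rank, build variants.

    Candidates are ranked by (passes gene filter, ascending SCF, site start);
    the intended target gene is excluded from its own off-target count.  The
    top ``top_k`` designs come back with Mismatch/sN/dN variants attached.
    """
    candidates: list[SiRNADesign] = []
    for t in tx.transcripts_of_gene(target_gene):
        candidates.extend(enumerate_candidates(t))
    logger.info("enumerated %d candidate sites for %s", len(candidates), target_gene)

    scored = []
    for d in candidates:
        r = scan(
            d.match, tx, run_threshold=run_threshold, gene_limit=gene_limit,
            exclude_gene=target_gene,
        )
        scored.append(replace(d, scan_result=r))
    passing = sum(r.scan_result.passes_gene_filter for r in scored)
    logger.info("%d/%d candidates pass the gene filter", passing, len(scored))

    scored.sort(
        key=lambda d: (
            not d.scan_result.passes_gene_filter,
            d.scan_result.scf_count,
            d.site_start,
        )
    )
    top = [
        complete_design(d, tx, run_threshold=run_threshold)
        for d in scored[:top_k]
    ]
    logger.info("emitting %d designs with variants", len(top))
    return top


def design_report(designs: list[SiRNADesign]) -> pd.DataFrame:
    """Tabular design report (one row per design, TSV-ready)."""
    rows = []
    for d in designs:
        rows.append(
            {
                "target_gene": d.target_gene,
                "transcript_id": d.transcript_id,
                "site_start": d.site_start,
                "site_end": d.site_end,
                "match": d.match.with_overhang,
                "mismatch": d.mismatch.with_overhang if d.mismatch else "",
                "mismatch_position": d.mismatch_position if d.mismatch else "",
                "sN": d.sN.with_overhang if d.sN else "",
                "dN": d.dN.with_overhang if d.dN else "",
                "offtarget_gene_count": (
                    len(d.scan_result.offtarget_genes) if d.scan_result else ""
                ),
                "scf": d.scan_result.scf_count if d.scan_result else "",
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
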