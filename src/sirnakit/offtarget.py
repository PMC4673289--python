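"""Off-target liability scanning for siRNA guide strands.

Two liabilities are scored against a transcriptome:

* **Complementary-run hits** — the longest contiguous stretch of a transcript
  that is Watson-Crick complementary (antiparallel) to a contiguous stretch of
  the guide.  A gene is an off-target when any of its transcripts carries a
  run strictly longer than ``run_threshold`` (default 12 nt, i.e. runs of
  >= 13 nt count).  A design passes when fewer than ``gene_limit`` (default 2)
  genes carry such a run — at most the intended target itself.

* **Seed complement frequency (SCF)** — the number (and fraction) of
  UTR-annotated transcripts whose 3'UTR contains at least one exact occurrence
  of the reverse complement of the guide's 7-nt seed (positions 2-8).  Guides
  with low SCF have experimentally fewer miRNA-like off-targets.

Because a transcript stretch complementary to the guide is exactly a substring
of the guide's reverse complement, the run search reduces to a longest common
substring problem between the transcript and the 19-nt reverse complement.
The scanner enumerates the reverse complement's substrings longest-first and
uses plain substring search; tests cross-check it against an independent
dynamic-programming oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .sequences import DegeneratePool, GuideStrand, reverse_complement, seed
from .transcriptome import Transcript, Transcriptome, utr3_sequence

#: Runs must be strictly longer than this many basepairs to count.
DEFAULT_RUN_THRESHOLD = 12
#: An oligo passes when strictly fewer than this many genes carry a run.
DEFAULT_GENE_LIMIT = 2


@dataclass(frozen=True)
class RunHit:
    """A qualifying complementary stretch on one transcript."""

    transcript_id: str
    gene_id: str
    run_length: int
    transcript_position: int  # 1-based start of the matched stretch


@dataclass(frozen=True)
class ScanResult:
    """Aggregate off-target liabilities for one guide (or pool)."""

    guide: GuideStrand
    offtarget_genes: frozenset[str]
    hits: tuple[RunHit, ...]
    scf_count: int
    scf_fraction: float
    run_threshold: int = DEFAULT_RUN_THRESHOLD
    gene_limit: int = DEFAULT_GENE_LIMIT
    passes_gene_filter: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "passes_gene_filter", len(self.offtarget_genes) < self.gene_limit
        )


def longest_complementary_run(
    guide: GuideStrand, t: Transcript
) -> tuple[int, list[int]]:
    """Longest contiguous Watson-Crick complementary stretch, with locations.

    Returns ``(run_length, positions)`` where ``positions`` are the 1-based
    transcript starts of every maximal-length stretch.  A transcript sharing
    no complementary base at all yields ``(0, [])``.
    """
    if not guide.is_concrete:
        raise ValidationError("guide must be concrete (no N); expand the pool first")
    rc = reverse_complement(guide.core).residues
    seq = t.sequence.residues
    for length in range(len(rc), 0, -1):
        positions: set[int] = set()
        for off in range(len(rc) - length + 1):
            sub = rc[off : off + length]
            i = seq.find(sub)
            while i != -1:
                positions.add(i + 1)
                i = seq.find(sub, i + 1)
        if positions:
            return length, sorted(positions)
    return 0, []


def _seed_complement(guide: GuideStrand) -> str:
    return reverse_complement(seed(guide)).residues


def _scf(guide: GuideStrand, tx: Transcriptome) -> tuple[int, float]:
    probe = _seed_complement(guide)
    annotated = 0
    count = 0
    for t in tx:
        utr = utr3_sequence(t)
        if utr is None:
            continue
        annotated += 1
        if probe in utr.residues:
            count += 1
    return count, (count / annotated if annotated else 0.0)


def scan(
    guide: GuideStrand,
    tx: Transcriptome,
    run_threshold: int = DEFAULT_RUN_THRESHOLD,
    gene_limit: int = DEFAULT_GENE_LIMIT,
    exclude_gene: str | None = None,
) -> ScanResult:
    """Score one concrete guide against every transcript.

    Genes are deduplicated by gene_id; the intended target's gene counts
    toward the limit unless named via ``exclude_gene`` (to count only
    unintended genes).
    """
    if len(tx) == 0:
        raise ValidationError("cannot scan an empty transcriptome")
    hits: list[RunHit] = []
    genes: set[str] = set()
    for t in tx:
        length, positions = longest_complementary_run(guide, t)
        if length > run_threshold:
            hits.append(
                RunHit(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    run_length=length,
                    transcript_position=positions[0],
                )
            )
            if t.gene_id != exclude_gene:
                genes.add(t.gene_id)
    scf_count, scf_fraction = _scf(guide, tx)
    return ScanResult(
        guide=guide,
        offtarget_genes=frozenset(genes),
        hits=tuple(hits),
        scf_count=scf_count,
        scf_fraction=scf_fraction,
        run_threshold=run_threshold,
        gene_limit=gene_limit,
    )


def scan_pool(
    pool: DegeneratePool,
    tx: Transcriptome,
    run_threshold: int = DEFAULT_RUN_THRESHOLD,
    gene_limit: int = DEFAULT_GENE_LIMIT,
    exclude_gene: str | None = None,
) -> ScanResult:
    """Conservative aggregate over every concrete member of a degenerate pool.

    Off-target genes are the union over members; SCF is the worst (maximum)
    member; the gene filter is evaluated on the union.
    """
    if len(pool) == 0:
        raise ValidationError("empty pool")
    genes: set[str] = set()
    hits: list[RunHit] = []
    best_scf = (0, 0.0)
    for member in pool:
        r = scan(member, tx, run_threshold, gene_limit, exclude_gene)
        genes |= r.offtarget_genes
        hits.extend(r.hits)
        best_scf = max(best_scf, (r.scf_count, r.scf_fraction))
    return ScanResult(
        guide=pool.template,
        offtarget_genes=frozenset(genes),
        hits=tuple(dict.fromkeys(hits)),
        scf_count=best_scf[0],
        scf_fraction=best_scf[1],
        run_threshold=run_threshold,
        gene_limit=gene_limit,
    )
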