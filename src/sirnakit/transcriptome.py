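"""The transcript universe designs are screened against.

A :class:`Transcriptome` is a set of mRNA transcripts, each carrying a gene
id and (optionally) a 3'UTR interval in 1-based closed transcript
coordinates.  Sequences are stored in the RNA alphabet; DNA FASTA input is
converted on load.

On-disk representation: a plain FASTA of transcript sequences plus a TSV
annotation with columns ``transcript_id, gene_id, utr3_start, utr3_end``
(empty start/end = no UTR annotation).  A GFF3 alternative maps
``three_prime_UTR`` features given in transcript coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import LoadError
from .sequences import NucSeq

ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "utr3_start", "utr3_end"]


@dataclass(frozen=True)
class Transcript:
    """One annotated mRNA.

    ``utr3`` is a closed interval ``(start, end)`` in 1-based transcript
    coordinates, or ``None`` when the transcript has no 3'UTR annotation.
    """

    transcript_id: str
    gene_id: str
    sequence: NucSeq
    utr3: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.sequence.alphabet != "RNA":
            object.__setattr__(self, "sequence", self.sequence.to_rna())
        if self.utr3 is not None:
            start, end = self.utr3
            if not 1 <= start <= end <= len(self.sequence):
                raise LoadError(
                    f"transcript {self.transcript_id!r}: 3'UTR interval "
                    f"[{start},{end}] outside 1..{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def utr3_sequence(t: Transcript) -> Optional[NucSeq]:
    """The annotated 3'UTR subsequence, or None when unannotated."""
    if t.utr3 is None:
        return None
    start, end = t.utr3
    return t.sequence.subseq(start, end)


class Transcriptome:
    """A validated collection of transcripts with a gene index."""

    def __init__(self, transcripts: list[Transcript]):
        self._transcripts: dict[str, Transcript] = {}
        self._by_gene: dict[str, list[str]] = {}
        for t in transcripts:
            if t.transcript_id in self._transcripts:
                raise LoadError(f"duplicate transcript_id {t.transcript_id!r}")
            self._transcripts[t.transcript_id] = t
            self._by_gene.setdefault(t.gene_id, []).append(t.transcript_id)

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def get(self, transcript_id: str) -> Transcript:
        try:
            return self._transcripts[transcript_id]
        except KeyError:
            raise LoadError(f"unknown transcript_id {transcript_id!r}") from None

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._by_gene)

    def transcripts_of_gene(self, gene_id: str) -> list[Transcript]:
        if gene_id not in self._by_gene:
            raise LoadError(
                f"unknown gene {gene_id!r}; available: {', '.join(self.gene_ids)}"
            )
        return [self._transcripts[tid] for tid in self._by_gene[gene_id]]


def load_transcriptome(fasta_path: str | Path, annotation_path: str | Path) -> Transcriptome:
    """Load and cross-validate a FASTA + TSV annotation pair.

    Every FASTA record must have an annotation row and vice versa; UTR
    intervals are checked against sequence length.  DNA sequences are
    converted to the RNA alphabet.
    """
    seqs: dict[str, NucSeq] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise LoadError(f"duplicate transcript_id {rec.id!r} in {fasta_path}")
        raw = str(rec.seq).upper()
        alphabet = "DNA" if "T" in raw else "RNA"
        seqs[rec.id] = NucSeq(raw, alphabet).to_rna()

    ann = pd.read_csv(
        annotation_path, sep="\t", comment="#", dtype={"transcript_id": str, "gene_id": str}
    )
    missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise LoadError(f"annotation missing column(s) {sorted(missing_cols)}")

    transcripts = []
    seen = set()
    for row in ann.itertuples(index=False):
        tid = row.transcript_id
        if tid in seen:
            raise LoadError(f"duplicate transcript_id {tid!r} in annotation")
        seen.add(tid)
        if tid not in seqs:
            raise LoadError(f"annotation row {tid!r} has no FASTA sequence")
        utr3 = None
        if not (pd.isna(row.utr3_start) or pd.isna(row.utr3_end)):
            try:
                utr3 = (int(row.utr3_start), int(row.utr3_end))
            except (TypeError, ValueError):
                raise LoadError(f"transcript {tid!r}: malformed 3'UTR interval") from None
        transcripts.append(
            Transcript(transcript_id=tid, gene_id=row.gene_id, sequence=seqs[tid], utr3=utr3)
        )
    unannotated = set(seqs) - seen
    if unannotated:
        raise LoadError(f"FASTA record(s) without annotation: {sorted(unannotated)}")
    return Transcriptome(transcripts)


def load_transcriptome_gff3(fasta_path: str | Path, gff3_path: str | Path) -> Transcriptome:
    """Load transcripts whose 3'UTRs are given as GFF3 ``three_prime_UTR`` rows.

    Features must be in transcript coordinates (seqid = transcript id); the
    gene id is taken from the feature's ``gene_id`` attribute.  Transcripts
    without a feature get no UTR annotation and gene_id = transcript_id.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    utrs: dict[str, tuple[int, int]] = {}
    genes: dict[str, str] = {}
    for feat in db.features_of_type("three_prime_UTR"):
        tid = feat.seqid
        prev = utrs.get(tid)
        # multiple UTR rows per transcript merge to their spanning interval
        utrs[tid] = (
            min(feat.start, prev[0]) if prev else feat.start,
            max(feat.end, prev[1]) if prev else feat.end,
        )
        if "gene_id" in feat.attributes:
            genes[tid] = feat.attributes["gene_id"][0]

    transcripts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        raw = str(rec.seq).upper()
        alphabet = "DNA" if "T" in raw else "RNA"
        transcripts.append(
            Transcript(
                transcript_id=rec.id,
                gene_id=genes.get(rec.id, rec.id),
                sequence=NucSeq(raw, alphabet).to_rna(),
                utr3=utrs.get(rec.id),
            )
        )
    return Transcriptome(transcripts)


def write_transcriptome(
    tx: Transcriptome, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    """Write the FASTA + TSV pair that :func:`load_transcriptome` reads."""
    records = [
        SeqRecord(Seq(t.sequence.residues), id=t.transcript_id, description=t.gene_id)
        for t in tx
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "utr3_start": t.utr3[0] if t.utr3 else None,
            "utr3_end": t.utr3[1] if t.utr3 else None,
        }
        for t in tx
    ]
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df[["utr3_start", "utr3_end"]] = df[["utr3_start", "utr3_end"]].astype("Int64")
    with open(annotation_path, "w") as fh:
        fh.write("# 1-based closed intervals; empty utr3 fields = unannotated\n")
        df.to_csv(fh, sep="\t", index=False)
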