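from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sirnakit import GuideStrand, NucSeq, Transcript, Transcriptome

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Published worked example: a Match guide, its Mismatch control (single
# substitution at position 11) and the degenerate sN/dN variants.
TABLE1 = {
    "match_0N": "ACCGUAUGAAGUACUUGGC",
    "mismatch_0N": "ACCGUAUGAAAUACUUGGC",
    "match_sN": "ANCGUAUGAAGUACUUGGC",
    "match_dN": "ANCGUAUGAAGUACUUGNC",
    "mismatch_sN": "ANCGUAUGAAAUACUUGGC",
    "mismatch_dN": "ANCGUAUGAAAUACUUGNC",
}


@pytest.fixture(scope="session")
def table1() -> dict[str, GuideStrand]:
    return {k: GuideStrand.from_string(v) for k, v in TABLE1.items()}


def make_transcript(
    seq: str,
    transcript_id: str = "TX1",
    gene_id: str = "G1",
    utr3: tuple[int, int] | None = None,
) -> Transcript:
    return Transcript(
        transcript_id=transcript_id,
        gene_id=gene_id,
        sequence=NucSeq(seq, "RNA"),
        utr3=utr3,
    )


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture
def tiny_transcriptome() -> Transcriptome:
    """Three short transcripts, two genes, mixed UTR annotation."""
    return Transcriptome(
        [
            make_transcript("ACGU" * 25, "TX1", "G1", utr3=(81, 100)),
            make_transcript("GGCC" * 30, "TX2", "G2", utr3=(100, 120)),
            make_transcript("AUAU" * 20, "TX3", "G2"),
        ]
    )
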