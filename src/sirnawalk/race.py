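"""5'RACE simulation and cleavage-site mapping.

RISC cleaves a fully complementary target at a fixed position relative to the
guide; ligating an RNA adapter to the 5'-phosphate end of the 3' cleavage
fragment (capped full-length mRNA is refractory to ligation) and sequencing
across the adapter/transcript junction localises the cut. This module
simulates those products and maps reads — simulated or from FASTA/FASTQ —
back to a transcript coordinate and a guide alignment position.

The cleavage convention is parameterised by ``g_star``, the guide position
paired with the fragment's 5'-most nucleotide (default 11, i.e. the fragment
starts at sense position ``window_end - g_star + 1``). Under the antiparallel
mapping used here, the classical "cut between the target nucleotides paired
to guide positions 10 and 11" would put the fragment's first base opposite
guide position 10; the default follows the empirical junction convention
instead, and the parameter keeps simulator and mapper self-consistent under
either reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import AntisenseDesign
from .seqcore import AlleleLocus, Alphabet, NucleotideSequence, convert_alphabet

__all__ = [
    "RACE_ADAPTER",
    "RaceRead",
    "CleavageCall",
    "simulate_cleavage",
    "ligate_adapter",
    "map_junction",
    "aggregate_calls",
]

#: RNA adapter ligated to 5'-phosphate cleavage fragments (5'-OH/3'-OH ends).
RACE_ADAPTER = "ACACUCUUUCCCUACACGACGCUCUUCCGAUCU"

DEFAULT_G_STAR = 11
DEFAULT_MIN_ANCHOR = 12


@dataclass(frozen=True)
class RaceRead:
    read_id: str
    sequence: str  # 5'->3', adapter followed by the transcript 3'-fragment prefix
    source: str = "simulated"


@dataclass(frozen=True)
class CleavageCall:
    """An adapter/transcript junction located on the sense transcript."""

    read_id: str
    transcript_id: str
    transcript_coordinate: int  # 1-based sense position of the fragment's 5' nt
    guide_alignment: int | None  # guide position paired with that nt, if a design is given
    junction_offset: int  # 0-based index in the read where transcript sequence begins
    anchor_length: int


def simulate_cleavage(
    locus: AlleleLocus,
    design: AntisenseDesign,
    g_star: int = DEFAULT_G_STAR,
    allele: str = "mut",
) -> NucleotideSequence:
    """Return the 3' cleavage fragment of the target transcript, as RNA.

    The fragment is the transcript suffix whose first base is the sense
    position paired with guide position ``g_star``; it carries the 5'
    phosphate that makes it ligatable.
    """
    if design.locus is not locus and design.locus != locus:
        raise ValueError("design does not target the supplied locus")
    if not (1 <= g_star <= design.length):
        raise ValueError(f"g_star {g_star} outside guide [1, {design.length}]")
    cut = design.target_position(g_star)
    transcript = convert_alphabet(locus.allele_sequence(allele), Alphabet.RNA)
    return transcript.slice1(cut, len(transcript))


def ligate_adapter(
    fragment: NucleotideSequence | str,
    adapter: str = RACE_ADAPTER,
    read_id: str = "read",
    read_length: int | None = 150,
    capped: bool = False,
) -> RaceRead | None:
    """Ligate the RNA adapter onto a 5'-phosphate fragment and read it out.

    Returns ``None`` for ``capped=True``: a 7-methylguanosine cap blocks
    ligation, so full-length mRNA yields no RACE read.
    """
    if capped:
        return None
    frag = str(fragment)
    if not frag:
        raise ValueError("empty cleavage fragment")
    seq = adapter + frag
    if read_length is not None:
        if read_length <= len(adapter):
            raise ValueError(
                f"read_length {read_length} does not extend past the "
                f"{len(adapter)}-nt adapter"
            )
        seq = seq[:read_length]
    return RaceRead(read_id=read_id, sequence=seq, source="simulated")


def _norm_rna(s: str) -> str:
    return s.upper().replace("T", "U")


def _count_mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def map_junction(
    read: RaceRead | str,
    transcript: AlleleLocus | NucleotideSequence | str,
    adapter: str = RACE_ADAPTER,
    design: AntisenseDesign | None = None,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    adapter_mismatches: int = 0,
    transcript_id: str | None = None,
    allele: str = "mut",
) -> CleavageCall | None:
    """Locate the adapter/transcript junction of one read.

    The adapter must be a prefix of the read (up to ``adapter_mismatches``
    substitutions); the following ``min_anchor`` nucleotides are then matched
    exactly against the transcript. Returns ``None`` (a no-call) when the
    adapter is absent, the anchor is too short, or the anchor matches the
    transcript at zero or multiple positions. T/U differences between read and
    transcript are ignored, so DNA-sequenced reads map against mRNA directly.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be positive")
    if len(adapter) < min_anchor:
        raise ValueError(
            f"adapter ({len(adapter)} nt) shorter than min_anchor {min_anchor}"
        )
    if isinstance(transcript, AlleleLocus):
        if transcript_id is None:
            transcript_id = transcript.transcript_id
        tseq = _norm_rna(transcript.allele_sequence(allele).bases)
    else:
        tseq = _norm_rna(str(transcript))
        if transcript_id is None:
            transcript_id = "transcript"
    if not tseq:
        raise ValueError("empty transcript")

    read_id = read.read_id if isinstance(read, RaceRead) else "read"
    seq = _norm_rna(read.sequence if isinstance(read, RaceRead) else str(read))
    ad = _norm_rna(adapter)
    if len(seq) < len(ad) + min_anchor:
        return None
    if _count_mismatches(seq[: len(ad)], ad) > adapter_mismatches:
        return None
    anchor = seq[len(ad) : len(ad) + min_anchor]
    hits = [i for i in range(len(tseq) - min_anchor + 1) if tseq[i : i + min_anchor] == anchor]
    if len(hits) != 1:
        return None
    coord = hits[0] + 1
    alignment = None
    if design is not None:
        alignment = design.window_end - coord + 1
        if not (1 <= alignment <= design.length):
            alignment = None  # junction falls outside this design's window
    return CleavageCall(
        read_id=read_id,
        transcript_id=transcript_id,
        transcript_coordinate=coord,
        guide_alignment=alignment,
        junction_offset=len(ad),
        anchor_length=min_anchor,
    )


def aggregate_calls(calls) -> pd.DataFrame:
    """Group cleavage calls by site: support descending, then coordinate.

    All calls must be against a single transcript; mixtures are rejected.
    """
    calls = [c for c in calls if c is not None]
    if not calls:
        return pd.DataFrame(
            columns=["transcript_coordinate", "guide_alignment", "support"]
        )
    tids = {c.transcript_id for c in calls}
    if len(tids) > 1:
        raise ValueError(f"calls span multiple transcripts: {sorted(tids)}")
    df = pd.DataFrame(
        {
            "transcript_coordinate": [c.transcript_coordinate for c in calls],
            "guide_alignment": [c.guide_alignment for c in calls],
        }
    )
    out = (
        df.groupby(["transcript_coordinate", "guide_alignment"], dropna=False)
        .size()
        .reset_index(name="support")
        .sort_values(
            ["support", "transcript_coordinate"], ascending=[False, True]
        )
        .reset_index(drop=True)
    )
    return out
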