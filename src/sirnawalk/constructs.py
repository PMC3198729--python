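"""Wet-lab artifacts derived from a guide design.

Three construct families are emitted, all as pure functions of the design and
a small set of configuration choices, so every artifact is regenerable
byte-identically:

* :func:`sirna_duplex` — synthetic siRNA duplexes: a 19-mer RNA core on each
  strand with a 3' deoxy ``dTdT`` dinucleotide overhang.
* :func:`u6_primer` — a U6 reverse PCR primer that appends a stem-loop hairpin
  template downstream of the Pol-III U6 promoter, plus the predicted hairpin
  transcript (sense arm, 9-nt loop, antisense arm, U-tract terminator). The
  antisense (guide) species occupies the hairpin's 3' arm by default.
* :func:`luciferase_insert` — annealed-oligo target inserts for a
  dual-luciferase reporter, cloned directionally XhoI -> NotI 3' of the
  Renilla gene; wild-type and mutant inserts differ at exactly the SNV.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import AntisenseDesign
from .seqcore import (
    AlleleLocus,
    Alphabet,
    NucleotideSequence,
    convert_alphabet,
    reverse_complement,
)

__all__ = [
    "SiRNADuplex",
    "HairpinConstruct",
    "LuciferaseTargetInsert",
    "sirna_duplex",
    "u6_primer",
    "luciferase_insert",
    "order_sheet",
    "U6_POLYA",
    "U6_LOOP_DNA",
    "U6_TAIL",
]

# Fixed segments of the U6 reverse-primer template, 5'->3':
# poly-A .. [antisense slot] .. loop .. [sense slot] .. promoter-annealing tail
U6_POLYA = "AAAAAA"
U6_LOOP_DNA = "TGGGTCAGG"
U6_TAIL = "GGTGTTTCGTCCTTTCCACAA"

XHOI_TOP = "TCGAG"  # XhoI-compatible 5' overhang + closing G on the top oligo
NOTI_BOTTOM = "GGCCGC"  # NotI-compatible 5' overhang + closing GC on the bottom oligo

DT_OVERHANG = "dTdT"


def _dna(seq: NucleotideSequence) -> NucleotideSequence:
    return convert_alphabet(seq, Alphabet.DNA)


def _rna(seq: NucleotideSequence) -> NucleotideSequence:
    return convert_alphabet(seq, Alphabet.RNA)


@dataclass(frozen=True)
class SiRNADuplex:
    """A fully paired siRNA duplex with 3' dTdT overhangs on both strands."""

    design_id: str
    guide_core: NucleotideSequence
    passenger_core: NucleotideSequence

    def __post_init__(self) -> None:
        if reverse_complement(self.guide_core).bases != self.passenger_core.bases:
            raise ValueError("passenger core must be the reverse complement of the guide core")

    @property
    def guide_strand(self) -> str:
        """Guide strand in order-sheet notation, e.g. ``...CUUdTdT``."""
        return self.guide_core.bases + DT_OVERHANG

    @property
    def passenger_strand(self) -> str:
        return self.passenger_core.bases + DT_OVERHANG


def sirna_duplex(design: AntisenseDesign) -> SiRNADuplex:
    """Render a design as an orderable siRNA duplex.

    The passenger strand pairs the guide over the full core — including at
    secondary-mismatch positions, which mismatch the *target*, not the duplex.
    """
    return SiRNADuplex(
        design_id=design.design_id,
        guide_core=design.guide,
        passenger_core=reverse_complement(design.guide),
    )


@dataclass(frozen=True)
class HairpinConstruct:
    """A U6 reverse primer and the hairpin transcript it is predicted to express."""

    design_id: str
    u6_reverse_primer: str  # DNA 5'->3'
    predicted_transcript: str  # RNA 5'->3': arm + loop + arm + U-tract
    loop_rna: str
    antisense_arm: str
    sense_arm: str
    terminator_u_overhang: int
    slot_mode: str


def u6_primer(
    design: AntisenseDesign,
    slot_mode: str = "architecture",
    loop_orientation: str = "revcomp",
    terminator_us: int = 6,
    terminator_u_overhang: int = 2,
) -> HairpinConstruct:
    """Assemble the U6 reverse primer and predict its hairpin transcript.

    The primer template is ``AAAAAA .. slotA .. TGGGTCAGG .. slotS ..
    GGTGTTTCGTCCTTTCCACAA`` (a reverse primer: its 3' tail anneals to the U6
    promoter template at the +1 site, and the expressed transcript is the
    reverse complement of its variable region, ending in a Pol-III U-tract
    encoded by the poly-A).

    ``slot_mode="architecture"`` (default) fills the slots so the transcript
    is ``sense_arm + loop + guide + UUUUUU`` — the guide species in the 3'
    arm, which reverse-primer geometry achieves by placing the reverse
    complement of the guide DNA in slotA and the guide DNA itself in slotS.
    ``slot_mode="literal"`` instead puts the antisense DNA literally in the
    slot of that name, which expresses the guide from the 5' arm; it is kept
    selectable because oligo sheets written with label-literal slot contents
    exist in the wild.

    ``loop_orientation="revcomp"`` reads the loop through the same
    reverse-primer geometry (transcript loop ``CCUGACCCA``); ``"forward"``
    renders the loop as ``UGGGUCAGG``.
    """
    if slot_mode not in ("architecture", "literal"):
        raise ValueError(f"slot_mode must be 'architecture' or 'literal', got {slot_mode!r}")
    if loop_orientation not in ("revcomp", "forward"):
        raise ValueError(
            f"loop_orientation must be 'revcomp' or 'forward', got {loop_orientation!r}"
        )
    guide_dna = _dna(design.guide)
    sense_dna = reverse_complement(guide_dna)
    if slot_mode == "architecture":
        slot_a, slot_s = sense_dna, guide_dna
    else:
        slot_a, slot_s = guide_dna, sense_dna
    primer = U6_POLYA + slot_a.bases + U6_LOOP_DNA + slot_s.bases + U6_TAIL

    if loop_orientation == "revcomp":
        loop = _rna(reverse_complement(NucleotideSequence(U6_LOOP_DNA, Alphabet.DNA))).bases
    else:
        loop = _rna(NucleotideSequence(U6_LOOP_DNA, Alphabet.DNA)).bases

    # transcript arm order mirrors the slot geometry: slotS is transcribed
    # first (5' arm), slotA last (3' arm), each as its reverse complement
    arm5 = _rna(reverse_complement(slot_s)).bases
    arm3 = _rna(reverse_complement(slot_a)).bases
    transcript = arm5 + loop + arm3 + "U" * terminator_us

    guide_rna = design.guide.bases
    sense_rna = _rna(sense_dna).bases
    return HairpinConstruct(
        design_id=design.design_id,
        u6_reverse_primer=primer,
        predicted_transcript=transcript,
        loop_rna=loop,
        antisense_arm=guide_rna if slot_mode == "architecture" else sense_rna,
        sense_arm=sense_rna if slot_mode == "architecture" else guide_rna,
        terminator_u_overhang=terminator_u_overhang,
        slot_mode=slot_mode,
    )


@dataclass(frozen=True)
class LuciferaseTargetInsert:
    """An annealed-oligo reporter insert for one allele of the locus."""

    allele: str
    window: NucleotideSequence  # sense DNA
    window_start: int  # 1-based sense coordinates on the transcript
    window_end: int
    snv_offset: int  # 1-based position of the SNV within the window
    top_oligo: str
    bottom_oligo: str


def luciferase_insert(
    locus: AlleleLocus, allele: str, width: int = 52, min_guide_length: int = 19
) -> LuciferaseTargetInsert:
    """Cut the reporter target window around the SNV and emit cloning oligos.

    The window is centred on the SNV: ``width // 2`` nt of 5' flank, the
    remainder 3' (width 52 puts the SNV at window position 27). Oligos carry
    XhoI/NotI-compatible sticky ends for directional insertion 3' of Renilla.
    """
    if width < min_guide_length:
        raise ValueError(
            f"insert width {width} is shorter than the guide length {min_guide_length}"
        )
    flank5 = width // 2
    flank3 = width - 1 - flank5
    start = locus.snv_position - flank5
    end = locus.snv_position + flank3
    n = len(locus.sense_sequence)
    if start < 1 or end > n:
        raise ValueError(
            f"insufficient flank for a {width}-nt insert: window [{start}, {end}] "
            f"outside transcript of length {n}"
        )
    window = _dna(locus.allele_sequence(allele).slice1(start, end))
    top = XHOI_TOP + window.bases + "GC"
    bottom = NOTI_BOTTOM + reverse_complement(window).bases + "C"
    return LuciferaseTargetInsert(
        allele=allele,
        window=window,
        window_start=start,
        window_end=end,
        snv_offset=flank5 + 1,
        top_oligo=top,
        bottom_oligo=bottom,
    )


def order_sheet(items) -> pd.DataFrame:
    """Flatten constructs into an oligo order sheet (one row per strand)."""
    rows = []
    for item in items:
        if isinstance(item, SiRNADuplex):
            rows.append((item.design_id, "guide", item.guide_strand, len(item.guide_strand)))
            rows.append(
                (item.design_id, "passenger", item.passenger_strand, len(item.passenger_strand))
            )
        elif isinstance(item, HairpinConstruct):
            rows.append(
                (item.design_id, "u6_reverse_primer", item.u6_reverse_primer,
                 len(item.u6_reverse_primer))
            )
        elif isinstance(item, LuciferaseTargetInsert):
            cid = f"reporter_{item.allele}"
            rows.append((cid, "top", item.top_oligo, len(item.top_oligo)))
            rows.append((cid, "bottom", item.bottom_oligo, len(item.bottom_oligo)))
        else:
            raise TypeError(f"cannot render {type(item).__name__} on an order sheet")
    return pd.DataFrame(rows, columns=["construct_id", "strand", "sequence", "length"])
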