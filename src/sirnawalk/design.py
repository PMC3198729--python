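"""Walk-through guide design against a single-nucleotide variant.

The central object is the :class:`AntisenseDesign`: a guide (antisense) strand
of length ``L`` (default 19) that is fully complementary to the *mutant*
allele of an :class:`~sirnawalk.seqcore.AlleleLocus`, with the variant aligned
opposite guide position ``p``. Guide positions are numbered 5'->3' with P1 the
5'-most nucleotide; because guide and target are antiparallel, guide position
``q`` pairs sense-transcript position ``t(q) = window_end - q + 1``, so the
variant sits at ``t(p) == snv_position``.

Such a guide carries exactly one mismatch to the wild-type allele (the
"primary" mismatch, at ``p``). Secondary mismatches — deliberate guide
substitutions that mismatch *both* alleles — can be layered on to widen the
wild-type/mutant silencing gap; :func:`secondary_variants` implements the
placement strategies used for that purpose (immediately 3' or 5' of the
primary alignment, at a separated position, or opposite the predicted RISC
cleavage site).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from .seqcore import (
    AlleleLocus,
    Alphabet,
    AlphabetError,
    NucleotideSequence,
    convert_alphabet,
    reverse_complement,
)

__all__ = [
    "MismatchCategory",
    "MismatchClass",
    "StrengthTable",
    "SecondaryMismatch",
    "AntisenseDesign",
    "classify_pair",
    "guide_for_position",
    "walkthrough_panel",
    "secondary_variants",
    "mismatch_profile",
    "default_strength_table",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CU")
_WC = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
_BASE_ORDER = "ACGU"


class MismatchCategory(str, enum.Enum):
    WATSON_CRICK = "WATSON_CRICK"
    WOBBLE_GU = "WOBBLE_GU"
    PURINE_PURINE = "PURINE_PURINE"
    PYRIMIDINE_PYRIMIDINE = "PYRIMIDINE_PYRIMIDINE"
    PURINE_PYRIMIDINE_MM = "PURINE_PYRIMIDINE_MM"


@dataclass(frozen=True)
class MismatchClass:
    """Classification of one target:guide base alignment.

    ``pair_label`` is written ``target_base:guide_base`` (e.g. the G2019S
    wild-type allele opposite its mutant-matched guide reads "G:U").
    """

    category: MismatchCategory
    pair_label: str

    @property
    def is_mismatch(self) -> bool:
        return self.category is not MismatchCategory.WATSON_CRICK


def classify_pair(target_base: str, guide_base: str) -> MismatchClass:
    """Classify an RNA target:guide base alignment.

    A:U, U:A, G:C, C:G are Watson-Crick; G:U and U:G are wobbles; two purines
    or two (non-WC) pyrimidines get their own classes; the remaining
    purine/pyrimidine pairs (A:C, C:A) form the last mismatch class.
    """
    t, g = target_base.upper(), guide_base.upper()
    for name, b in (("target_base", t), ("guide_base", g)):
        if b not in "ACGU":
            raise AlphabetError(f"{name} {b!r} is not an RNA base")
    label = f"{t}:{g}"
    if (t, g) in _WC:
        cat = MismatchCategory.WATSON_CRICK
    elif {t, g} == {"G", "U"}:
        cat = MismatchCategory.WOBBLE_GU
    elif t in _PURINES and g in _PURINES:
        cat = MismatchCategory.PURINE_PURINE
    elif t in _PYRIMIDINES and g in _PYRIMIDINES:
        cat = MismatchCategory.PYRIMIDINE_PYRIMIDINE
    else:
        cat = MismatchCategory.PURINE_PYRIMIDINE_MM
    return MismatchClass(cat, label)


@dataclass(frozen=True)
class StrengthTable:
    """Ordinal disruption scores over all 16 ordered target:guide pairs.

    Watson-Crick pairs score 0; every mismatch scores > 0. Used only to rank
    candidate secondary mismatches as "weak" or "strong"; the absolute values
    carry no physical meaning.
    """

    scores: dict[str, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        expected = {f"{a}:{b}" for a in "ACGU" for b in "ACGU"}
        if set(self.scores) != expected:
            missing = expected - set(self.scores)
            extra = set(self.scores) - expected
            raise ValueError(
                f"strength table must cover all 16 ordered RNA pairs "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        for label, score in self.scores.items():
            wc = tuple(label.split(":")) in _WC
            if wc and score != 0:
                raise ValueError(f"Watson-Crick pair {label} must score 0")
            if not wc and score <= 0:
                raise ValueError(f"mismatch pair {label} must score > 0")

    def score(self, target_base: str, guide_base: str) -> int:
        return self.scores[f"{target_base.upper()}:{guide_base.upper()}"]

    @classmethod
    def from_yaml(cls, path) -> "StrengthTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(scores=dict(doc["scores"]), provenance=doc.get("provenance", ""))


def default_strength_table() -> StrengthTable:
    """Load the table shipped with the package (see its provenance note)."""
    ref = resources.files("sirnawalk.data") / "strength_table.yaml"
    doc = yaml.safe_load(ref.read_text())
    return StrengthTable(scores=dict(doc["scores"]), provenance=doc.get("provenance", ""))


@dataclass(frozen=True)
class SecondaryMismatch:
    guide_position: int
    original_guide_base: str
    substituted_guide_base: str
    class_vs_wt: MismatchClass
    class_vs_mut: MismatchClass


@dataclass(frozen=True)
class AntisenseDesign:
    """A guide strand aligned against one allele locus (see module docstring)."""

    design_id: str
    guide: NucleotideSequence
    p: int
    locus: AlleleLocus
    window_start: int
    window_end: int
    primary_mismatch: MismatchClass
    secondary_mismatches: tuple[SecondaryMismatch, ...] = ()

    def __post_init__(self) -> None:
        if self.guide.alphabet is not Alphabet.RNA:
            raise AlphabetError("guide strand must be RNA")
        L = len(self.guide)
        if self.window_end - self.window_start + 1 != L:
            raise ValueError("target window length must equal guide length")
        if not (1 <= self.p <= L):
            raise ValueError(f"alignment position p={self.p} outside guide [1, {L}]")

    @property
    def length(self) -> int:
        return len(self.guide)

    def target_position(self, q: int) -> int:
        """Sense coordinate paired with guide position ``q`` (antiparallel)."""
        if not (1 <= q <= self.length):
            raise ValueError(f"guide position {q} outside [1, {self.length}]")
        return self.window_end - q + 1

    def target_window(self, allele: str) -> NucleotideSequence:
        """The targeted sense window of the requested allele, as RNA."""
        win = self.locus.allele_sequence(allele).slice1(self.window_start, self.window_end)
        return convert_alphabet(win, Alphabet.RNA)


def guide_for_position(
    locus: AlleleLocus, p: int, L: int = 19, design_id: str | None = None
) -> AntisenseDesign:
    """Design the guide that aligns the variant opposite guide position ``p``.

    The targeted sense window is ``[snv - (L - p), snv + (p - 1)]`` and the
    guide is its mutant-allele reverse complement in RNA, so the design has 0
    mismatches to the mutant allele and exactly 1 (at ``p``) to wild type.
    """
    if not 19 <= L <= 23:
        raise ValueError(f"guide length L={L} outside supported range 19-23")
    if not (1 <= p <= L):
        raise ValueError(f"alignment position p={p} outside guide [1, {L}]")
    snv = locus.snv_position
    window_start = snv - (L - p)
    window_end = snv + (p - 1)
    n = len(locus.sense_sequence)
    if window_start < 1 or window_end > n:
        need_5p, need_3p = L - p, p - 1
        have_5p, have_3p = snv - 1, n - snv
        raise ValueError(
            f"insufficient flank for p={p}, L={L}: need {need_5p} nt 5' and "
            f"{need_3p} nt 3' of the SNV, have {have_5p} and {have_3p}"
        )
    mut_window = locus.allele_sequence("mut").slice1(window_start, window_end)
    guide = convert_alphabet(reverse_complement(mut_window), Alphabet.RNA)
    wt_rna = convert_alphabet(
        NucleotideSequence(locus.wt_base, locus.alphabet), Alphabet.RNA
    ).bases
    primary = classify_pair(wt_rna, guide[p - 1])
    return AntisenseDesign(
        design_id=design_id if design_id is not None else f"p{p}",
        guide=guide,
        p=p,
        locus=locus,
        window_start=window_start,
        window_end=window_end,
        primary_mismatch=primary,
    )


def walkthrough_panel(
    locus: AlleleLocus, positions: list[int], L: int = 19
) -> list[AntisenseDesign]:
    """One design per alignment position, ids ``p{p}``, order preserved."""
    if not positions:
        raise ValueError("empty position list")
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate alignment positions: {dupes}")
    return [guide_for_position(locus, p, L=L) for p in positions]


_STRATEGIES = ("adjacent_3prime", "adjacent_5prime", "separated", "cleavage_opposite")


def _secondary_position(design: AntisenseDesign, strategy: str, position: int | None) -> int:
    if strategy == "adjacent_3prime":
        q = design.p + 1
    elif strategy == "adjacent_5prime":
        q = design.p - 1
    elif strategy == "separated":
        if position is None:
            raise ValueError("strategy 'separated' requires a position")
        q = position
    elif strategy == "cleavage_opposite":
        if position is None:
            raise ValueError("strategy 'cleavage_opposite' requires a position")
        if position not in (9, 10, 11):
            raise ValueError(
                f"cleavage_opposite position must be 9, 10 or 11, got {position}"
            )
        q = position
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {_STRATEGIES}")
    if not (1 <= q <= design.length):
        raise ValueError(f"secondary position {q} outside guide [1, {design.length}]")
    if q == design.p:
        raise ValueError(
            f"secondary position {q} collides with the primary alignment p={design.p}"
        )
    return q


def _variant_id(design: AntisenseDesign, strategy: str, q: int, base: str | None, tag: str | None) -> str:
    # Reproduces the field's construct-naming habits: adjacent-3' doubles with a
    # fixed substitution concatenate positions ("p1314"); every other explicit
    # substitution spells it out ("p11_9C"); rank-selected variants are tagged.
    if tag is not None:
        core = f"p{design.p}{q}" if strategy == "adjacent_3prime" else f"p{design.p}_{q}"
        return f"{core}:{tag}"
    if strategy == "adjacent_3prime" and base is not None:
        return f"p{design.p}{q}"
    return f"p{design.p}_{q}{base}"


def secondary_variants(
    design: AntisenseDesign,
    strategy: str,
    bases: str = "all",
    position: int | None = None,
    table: StrengthTable | None = None,
) -> list[AntisenseDesign]:
    """Enumerate secondary-mismatch variants of ``design``.

    Parameters
    ----------
    strategy : str
        Placement of the secondary mismatch: ``adjacent_3prime`` (guide
        position p+1), ``adjacent_5prime`` (p-1), ``separated`` (explicit
        ``position``) or ``cleavage_opposite`` (``position`` in {9, 10, 11},
        opposite the predicted RISC cleavage site).
    bases : str
        ``"all"`` (the 3 non-original guide bases), ``"weakest"`` /
        ``"strongest"`` (single substitution ranked by ``table`` against the
        mutant-allele target base; ties broken A<C<G<U), or one explicit base.
    """
    q = _secondary_position(design, strategy, position)
    if design.secondary_mismatches:
        raise ValueError("secondary variants are generated from a single-mismatch design")
    original = design.guide[q - 1]
    t_q = design.target_position(q)
    mut_target = design.target_window("mut")[t_q - design.window_start]  # == complement(original)
    wt_target = design.target_window("wt")[t_q - design.window_start]
    candidates = [b for b in _BASE_ORDER if b != original]

    mode = bases.lower()
    if mode == "all":
        chosen = [(b, None) for b in candidates]
    elif mode in ("weakest", "strongest"):
        tbl = table if table is not None else default_strength_table()
        key = {b: tbl.score(mut_target, b) for b in candidates}
        pick = min(candidates, key=lambda b: (key[b], b)) if mode == "weakest" else max(
            candidates, key=lambda b: (key[b], -_BASE_ORDER.index(b))
        )
        chosen = [(pick, "weak" if mode == "weakest" else "strong")]
    elif bases.upper() in _BASE_ORDER:
        b = bases.upper()
        if b == original:
            raise ValueError(
                f"explicit base {b} equals the original guide base at position {q}"
            )
        chosen = [(b, None)]
    else:
        raise ValueError(f"bases must be 'all', 'weakest', 'strongest' or a base, got {bases!r}")

    out = []
    for b, tag in chosen:
        new_bases = design.guide.bases[: q - 1] + b + design.guide.bases[q:]
        sec = SecondaryMismatch(
            guide_position=q,
            original_guide_base=original,
            substituted_guide_base=b,
            class_vs_wt=classify_pair(wt_target, b),
            class_vs_mut=classify_pair(mut_target, b),
        )
        out.append(
            replace(
                design,
                design_id=_variant_id(design, strategy, q, b if tag is None else None, tag),
                guide=NucleotideSequence(new_bases, Alphabet.RNA),
                secondary_mismatches=(sec,),
            )
        )
    return out


def mismatch_profile(design: AntisenseDesign, allele: str) -> list[tuple[int, MismatchClass]]:
    """Non-Watson-Crick alignments of the guide against one allele.

    Returned as ``(guide_position, MismatchClass)`` sorted by position. A
    design with k secondary mismatches has k mismatches to the mutant allele
    and k+1 to wild type.
    """
    window = design.target_window(allele).bases
    out = []
    for q in range(1, design.length + 1):
        target = window[design.target_position(q) - design.window_start]
        cls = classify_pair(target, design.guide[q - 1])
        if cls.is_mismatch:
            out.append((q, cls))
    return out
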