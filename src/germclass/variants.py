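"""Core domain types: variants, protein changes, annotations, thresholds.

Coordinates are 1-based inclusive throughout (VCF/HGVS convention); BED
inputs are converted at the reader boundary.  Variant identity is the
normalized ``(contig, position, ref, alt)`` tuple — rsIDs, where present,
are metadata only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "GenomicVariant",
    "ProteinChange",
    "Consequence",
    "NULL_CONSEQUENCES",
    "PredictionScores",
    "SiftCall",
    "PolyPhenCall",
    "MutationTasterCall",
    "VariantAnnotation",
    "Thresholds",
    "InvalidVariantError",
    "ProteinChangeParseError",
    "normalize_variant",
    "parse_protein_change",
]

_DNA = frozenset("ACGT")

AA_ONE_LETTER = frozenset("ACDEFGHIKLMNPQRSTVWY")

AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "STOP", "Sec": "U",
}

#: Special alt-residue tokens for non-missense protein changes.
STOP = "STOP"
FS = "FS"
DEL = "DEL"
INS = "INS"
STARTLOSS = "STARTLOSS"
_SPECIAL_ALT = frozenset({STOP, FS, DEL, INS, STARTLOSS})


class InvalidVariantError(ValueError):
    """A genomic variant violates its invariants (bad alleles, ref == alt, ...)."""


class ProteinChangeParseError(ValueError):
    """An HGVS p. string could not be interpreted."""


@dataclass(frozen=True, order=True)
class GenomicVariant:
    """A site + allele with 1-based coordinates.

    Two variants are the same variant iff their *normalized* tuples are
    equal; callers should compare through :func:`normalize_variant`.
    """

    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.contig:
            raise InvalidVariantError("empty contig name")
        if self.position < 1:
            raise InvalidVariantError(f"position must be >= 1, got {self.position}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _DNA:
                raise InvalidVariantError(
                    f"{name} allele {allele!r} is not a nonempty ACGT string"
                )
        if self.ref == self.alt:
            raise InvalidVariantError(
                f"ref and alt are identical ({self.ref!r}) — not a variant"
            )

    def __str__(self) -> str:  # chr11:g.44109284G>C style
        return f"{self.contig}:g.{self.position}{self.ref}>{self.alt}"


def normalize_variant(raw: GenomicVariant) -> GenomicVariant:
    """Return the minimal (trimmed) representation of ``raw``.

    Shared suffix bases are removed first, then shared prefix bases (the
    position advancing accordingly), always leaving at least one base in
    each allele.  The operation is idempotent and total on valid variants.
    """
    ref, alt, pos = raw.ref, raw.alt, raw.position
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (raw.ref, raw.alt, raw.position):
        return raw
    return GenomicVariant(raw.contig, pos, ref, alt)


@dataclass(frozen=True, order=True)
class ProteinChange:
    """One amino-acid-level change on one transcript.

    ``alt_aa`` is either a one-letter amino acid (missense / synonymous)
    or one of the tokens STOP, FS, DEL, INS, STARTLOSS.
    """

    gene: str
    transcript: str
    residue_index: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ProteinChangeParseError(
                f"residue index must be >= 1, got {self.residue_index}"
            )
        if self.ref_aa not in AA_ONE_LETTER and self.ref_aa != STOP:
            raise ProteinChangeParseError(f"unknown reference residue {self.ref_aa!r}")
        if self.alt_aa not in AA_ONE_LETTER and self.alt_aa not in _SPECIAL_ALT:
            raise ProteinChangeParseError(f"unknown alternate residue {self.alt_aa!r}")

    @property
    def is_missense(self) -> bool:
        return (
            self.ref_aa in AA_ONE_LETTER
            and self.alt_aa in AA_ONE_LETTER
            and self.alt_aa != self.ref_aa
        )

    def hgvs_p(self) -> str:
        """Compact 1-letter HGVS-like rendering (``p.R175H``, ``p.W79*``)."""
        alt = {STOP: "*", FS: "fs", DEL: "del", INS: "ins", STARTLOSS: "?"}.get(
            self.alt_aa, self.alt_aa
        )
        return f"p.{self.ref_aa}{self.residue_index}{alt}"


_HGVS_P_RE = re.compile(
    r"^(?:p\.)?\(?"
    r"(?P<ref>[A-Z][a-z]{2}|[A-Z*])"
    r"(?P<pos>\d+)"
    r"(?P<rest>.*?)"
    r"\)?$"
)
_RANGE_RE = re.compile(r"^_(?:[A-Z][a-z]{2}|[A-Z])\d+")


def _residue(token: str) -> str:
    if len(token) == 3:
        aa = AA_THREE_TO_ONE.get(token)
        if aa is None:
            raise ProteinChangeParseError(f"unknown residue code {token!r}")
        return aa
    return token


def parse_protein_change(hgvs_p: str, gene: str, transcript: str = "") -> ProteinChange:
    """Parse an HGVS p. substitution/indel/frameshift description.

    Accepts 1- and 3-letter residue codes; ``*``/``X``/``Ter`` map to STOP,
    ``fs`` to FS, ``del`` to DEL, ``ins``/``dup``/``delins`` to INS, and
    ``Met1?`` to STARTLOSS.  Unparseable strings raise
    :class:`ProteinChangeParseError` — they are never silently dropped.
    """
    text = hgvs_p.strip()
    m = _HGVS_P_RE.match(text)
    if not m:
        raise ProteinChangeParseError(f"cannot parse protein change {hgvs_p!r}")
    ref_aa = _residue(m.group("ref")) if m.group("ref") != "*" else STOP
    residue_index = int(m.group("pos"))
    rest = m.group("rest")

    # consume a range tail like "_L508" before classifying the suffix
    range_match = _RANGE_RE.match(rest)
    if range_match:
        rest = rest[range_match.end():]

    low = rest.lower()
    if low.startswith("fs") or "fs" in low[:5]:
        alt_aa = FS
    elif low.startswith("delins"):
        alt_aa = INS
    elif low.startswith("del"):
        alt_aa = DEL
    elif low.startswith(("ins", "dup")):
        alt_aa = INS
    elif rest in ("*", "X", "Ter"):
        alt_aa = STOP
    elif rest == "?":
        if ref_aa == "M" and residue_index == 1:
            alt_aa = STARTLOSS
        else:
            raise ProteinChangeParseError(
                f"'?' alternate only meaningful for Met1 (got {hgvs_p!r})"
            )
    elif rest == "=":
        alt_aa = ref_aa if ref_aa != STOP else STOP
    elif rest:
        alt_aa = _residue(rest) if rest != "*" else STOP
        if alt_aa == "STOP" and rest == "Ter":
            alt_aa = STOP
    else:
        raise ProteinChangeParseError(f"missing alternate residue in {hgvs_p!r}")

    return ProteinChange(
        gene=gene,
        transcript=transcript,
        residue_index=residue_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


class Consequence(str, Enum):
    """Functional consequence of a variant (one per annotation row)."""

    SPLICE_SITE = "splice_site"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    STARTLOSS = "startloss"
    NONSYNONYMOUS_SNV = "nonsynonymous_snv"
    NONFRAMESHIFT_INSERTION = "nonframeshift_insertion"
    NONFRAMESHIFT_DELETION = "nonframeshift_deletion"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Predicted-null consequence classes (the PVS1-eligible set).
NULL_CONSEQUENCES = frozenset(
    {
        Consequence.SPLICE_SITE,
        Consequence.FRAMESHIFT_INSERTION,
        Consequence.FRAMESHIFT_DELETION,
        Consequence.STARTLOSS,
        Consequence.STOPGAIN,
    }
)


class SiftCall(str, Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"


class PolyPhenCall(str, Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"


class MutationTasterCall(str, Enum):
    DELETERIOUS = "deleterious"
    POLYMORPHISM = "polymorphism"


@dataclass(frozen=True)
class PredictionScores:
    """Per-variant in-silico predictor outputs; ``None`` means not scored.

    An absent predictor contributes neither a pathogenic nor a benign vote.
    REVEL is per protein change (keys parallel the annotation's changes).
    """

    revel_per_change: tuple[tuple[ProteinChange, float], ...] = ()
    cadd_phred: Optional[float] = None
    sift_call: Optional[SiftCall] = None
    polyphen_hdiv_call: Optional[PolyPhenCall] = None
    polyphen_hvar_call: Optional[PolyPhenCall] = None
    mutationtaster_call: Optional[MutationTasterCall] = None

    def revel_scores(self) -> tuple[float, ...]:
        return tuple(score for _, score in self.revel_per_change)


@dataclass(frozen=True)
class VariantAnnotation:
    """A case variant with its gene, consequence, protein changes and scores."""

    variant: GenomicVariant
    gene: str
    consequence: Consequence
    protein_changes: tuple[ProteinChange, ...] = ()
    in_repeat_region: bool = False
    scores: PredictionScores = field(default_factory=PredictionScores)

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("annotation requires a nonempty gene symbol")


@dataclass(frozen=True)
class Thresholds:
    """All tunable cutoffs of the pipeline, with the study defaults.

    revel_pathogenic/revel_benign
        REVEL score cutoffs; >0.68 counts pathogenic (95% specificity
        operating point), <=0.32 counts benign (symmetric choice).
    cadd_pathogenic
        PHRED-scaled CADD cutoff; >20 is roughly the top 0.1% of SNVs.
    bs1_maf
        Minor-allele-frequency exclusion threshold (strict >1%).
    ps4_alpha
        Per-comparison significance level for the Fisher tests.
    interpolation_window_bp
        Maximum distance to a flanking recorded site usable for
        allele-number interpolation, on each side.
    pp3_min_pathogenic_votes
        Minimum concordant deleterious predictions for PP3.
    """

    revel_pathogenic: float = 0.68
    revel_benign: float = 0.32
    cadd_pathogenic: float = 20.0
    bs1_maf: float = 0.01
    ps4_alpha: float = 0.05
    interpolation_window_bp: int = 150
    pp3_min_pathogenic_votes: int = 2
    pm4_stoploss_repeat_exempt: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.revel_benign < self.revel_pathogenic < 1.0):
            raise ValueError("need 0 < revel_benign < revel_pathogenic < 1")
        if not 0.0 < self.bs1_maf < 1.0:
            raise ValueError("bs1_maf must lie in (0, 1)")
        if not 0.0 < self.ps4_alpha < 1.0:
            raise ValueError("ps4_alpha must lie in (0, 1)")
        if self.interpolation_window_bp <= 0:
            raise ValueError("interpolation_window_bp must be positive")
        if self.pp3_min_pathogenic_votes < 1:
            raise ValueError("pp3_min_pathogenic_votes must be >= 1")
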