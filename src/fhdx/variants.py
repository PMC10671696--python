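"""LDLR cDNA variant parsing, consequence typing and spectrum summaries.

Variants are carried in HGVS-style cDNA notation on the canonical LDLR
transcript (NM_000527.5, annotation only).  The parser covers the small
grammar the cohort's variant table needs — substitutions, duplications,
deletions, insertions, and intronic positions with +/- offsets — and is
whitespace-tolerant.  Consequence classification combines the cDNA
change, the protein-level annotation and any free-text note (e.g. a new
splice site introduced by a synonymous change); the expected functional
receptor class follows the conventional mapping: truncating and
splice-disrupting changes are receptor-negative, missense changes
receptor-defective.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

from .config import VariantsConfig, default_config
from .evaluation import round_half_up_percent


class VariantParseError(ValueError):
    def __init__(self, text: str, reason: str = "unrecognised cDNA notation"):
        super().__init__(f"{reason}: {text!r}")
        self.text = text


@dataclass(frozen=True)
class CdnaPosition:
    """A cDNA coordinate, optionally with an intronic +/- offset."""

    base: int
    offset: int = 0

    @property
    def is_intronic(self) -> bool:
        return self.offset != 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.base)
        return f"{self.base}{self.offset:+d}"


@dataclass(frozen=True)
class CdnaChange:
    """A structured cDNA-level change."""

    kind: str  # substitution | duplication | deletion | insertion
    start: CdnaPosition
    end: Optional[CdnaPosition] = None
    ref: str = ""
    alt: str = ""

    @property
    def is_intronic(self) -> bool:
        return self.start.is_intronic or (self.end is not None and self.end.is_intronic)

    @property
    def max_intron_offset(self) -> int:
        offsets = [abs(self.start.offset)]
        if self.end is not None:
            offsets.append(abs(self.end.offset))
        return max(offsets)

    def format(self) -> str:
        span = str(self.start)
        if self.end is not None:
            span += f"_{self.end}"
        if self.kind == "substitution":
            return f"c.{span} {self.ref}>{self.alt}"
        if self.kind == "duplication":
            return f"c.{span} dup{self.alt}"
        if self.kind == "deletion":
            return f"c.{span} del{self.ref}"
        return f"c.{span} ins{self.alt}"


_POS = r"(\d+)([+-]\d+)?"
_SUB_RE = re.compile(rf"^c\.{_POS}\s*([ACGT])\s*>\s*([ACGT])$")
_DUPDEL_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?\s*(dup|del|ins)\s*([ACGT]*)$")


def _pos(base: str, offset: Optional[str]) -> CdnaPosition:
    return CdnaPosition(base=int(base), offset=int(offset) if offset else 0)


def parse_cdna(text: str) -> CdnaChange:
    """Parse an HGVS-style ``c.`` string into a :class:`CdnaChange`."""
    if not text or not text.strip():
        raise VariantParseError(text, "empty cDNA string")
    compact = text.strip()
    m = _SUB_RE.match(compact)
    if m:
        return CdnaChange(
            kind="substitution",
            start=_pos(m.group(1), m.group(2)),
            ref=m.group(3),
            alt=m.group(4),
        )
    m = _DUPDEL_RE.match(compact)
    if m:
        start = _pos(m.group(1), m.group(2))
        end = _pos(m.group(3), m.group(4)) if m.group(3) else None
        op = m.group(5)
        bases = m.group(6)
        kind = {"dup": "duplication", "del": "deletion", "ins": "insertion"}[op]
        return CdnaChange(
            kind=kind,
            start=start,
            end=end,
            ref=bases if op == "del" else "",
            alt=bases if op in ("dup", "ins") else "",
        )
    raise VariantParseError(text)


_TER_RE = re.compile(r"(Ter|\*)\)?$")
_FS_RE = re.compile(r"fs", re.IGNORECASE)
_SYN_RE = re.compile(r"[A-Za-z]{3}\d+=\)?$")
_SPLICE_NOTE_RE = re.compile(r"splice", re.IGNORECASE)


def classify_consequence(
    change: CdnaChange,
    protein_change: Optional[str] = None,
    note: Optional[str] = None,
    config: Optional[VariantsConfig] = None,
) -> str:
    """Assign a consequence class: ``missense``, ``nonsense``,
    ``frameshift``, ``splice`` or ``synonymous_splice``."""
    cfg = config if config is not None else default_config().variants
    protein = protein_change or ""
    if _FS_RE.search(protein):
        return "frameshift"
    if _SYN_RE.search(protein):
        if note and _SPLICE_NOTE_RE.search(note):
            return "synonymous_splice"
        raise ValueError(
            f"synonymous change {protein!r} without a splice annotation "
            "has no expected consequence"
        )
    if change.is_intronic:
        if change.max_intron_offset <= cfg.splice_offset_window:
            return "splice"
        raise ValueError(
            f"intronic change beyond the +/-{cfg.splice_offset_window} window"
        )
    if note and _SPLICE_NOTE_RE.search(note):
        return "splice"
    if change.kind in ("duplication", "deletion", "insertion"):
        # out-of-frame indels are frameshifts even when the protein
        # annotation only shows the resulting stop (e.g. p.(Cys667*))
        length = len(change.ref or change.alt)
        if change.end is not None:
            length = max(length, change.end.base - change.start.base + 1)
        if length % 3 != 0:
            return "frameshift"
    if _TER_RE.search(protein):
        return "nonsense"
    return "missense"


def expected_receptor_class(
    consequence: str, config: Optional[VariantsConfig] = None
) -> str:
    """Map a consequence class to the expected receptor class."""
    cfg = config if config is not None else default_config().variants
    try:
        return cfg.receptor_class_map[consequence]
    except KeyError:
        raise ValueError(f"no receptor-class rule for consequence {consequence!r}")


@dataclass(frozen=True)
class Variant:
    """One LDLR variant with its cohort counts and annotations."""

    cdna: str
    protein_change: Optional[str] = None
    localization: Optional[str] = None
    clinical_significance: Optional[str] = None
    novel: bool = False
    n_probands: int = 0
    n_cascade: int = 0
    note: Optional[str] = None
    change: CdnaChange = field(init=False)
    consequence: str = field(init=False)
    receptor_class: str = field(init=False)

    def __post_init__(self) -> None:
        if self.n_probands < 0 or self.n_cascade < 0:
            raise ValueError("variant counts must be >= 0")
        change = parse_cdna(self.cdna)
        consequence = classify_consequence(change, self.protein_change, self.note)
        object.__setattr__(self, "change", change)
        object.__setattr__(self, "consequence", consequence)
        object.__setattr__(self, "receptor_class", expected_receptor_class(consequence))


@dataclass(frozen=True)
class SpectrumSummary:
    """Table-2-style marginal summary of a variant spectrum."""

    n_unique_variants: int
    n_cases_with_variant: Optional[int]
    n_probands_tested: Optional[int]
    n_novel: int
    n_proband_observations: int
    n_cascade_observations: int
    by_consequence: Dict[str, int]
    by_receptor_class: Dict[str, int]
    percent_probands_positive: Optional[float]
    percent_expansion_vs_prior: Optional[float]
    declared_unique_variants: Optional[int] = None
    notes: Tuple[str, ...] = ()


def detection_fraction(n_positive: int, n_tested: int, ndigits: int = 1) -> float:
    """Variant-detection rate as a printed percentage (half-up)."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return round_half_up_percent(Fraction(n_positive, n_tested), ndigits)


def spectrum_expansion(
    n_new: int, prior_total_including_new: int, ndigits: int = 1
) -> float:
    """Percent growth of the known local spectrum contributed by ``n_new``
    variants, relative to the previously reported set."""
    previous = prior_total_including_new - n_new
    if previous <= 0:
        raise ValueError("prior total must exceed the number of new variants")
    return round_half_up_percent(Fraction(n_new, previous), ndigits)


def spectrum_summary(
    variants: Sequence[Variant],
    n_cases_with_variant: Optional[int] = None,
    n_probands_tested: Optional[int] = None,
    n_newly_reported: Optional[int] = None,
    prior_total_including_new: Optional[int] = None,
    declared_unique_variants: Optional[int] = None,
) -> SpectrumSummary:
    """Summarise a variant table into Table-2-style marginals.

    Case-level facts that a per-variant table cannot carry (the number
    of cases, of probands tested, of variants newly reported locally)
    are passed explicitly.  When the declared unique-variant count
    disagrees with the table's row count the summary keeps both numbers
    and flags the discrepancy instead of resolving it.
    """
    by_consequence: Dict[str, int] = {}
    by_class: Dict[str, int] = {}
    for v in variants:
        by_consequence[v.consequence] = by_consequence.get(v.consequence, 0) + 1
        by_class[v.receptor_class] = by_class.get(v.receptor_class, 0) + 1

    notes: List[str] = []
    if (
        declared_unique_variants is not None
        and declared_unique_variants != len(variants)
    ):
        notes.append(
            f"table lists {len(variants)} variants but the study declares "
            f"{declared_unique_variants} unique variants; both reported"
        )

    pct_pos = None
    if n_cases_with_variant is not None and n_probands_tested:
        pct_pos = detection_fraction(n_cases_with_variant, n_probands_tested)
    pct_exp = None
    if n_newly_reported is not None and prior_total_including_new is not None:
        pct_exp = (
            0.0
            if n_newly_reported == 0
            else spectrum_expansion(n_newly_reported, prior_total_including_new)
        )

    return SpectrumSummary(
        n_unique_variants=len(variants),
        n_cases_with_variant=n_cases_with_variant,
        n_probands_tested=n_probands_tested,
        n_novel=sum(1 for v in variants if v.novel),
        n_proband_observations=sum(v.n_probands for v in variants),
        n_cascade_observations=sum(v.n_cascade for v in variants),
        by_consequence=by_consequence,
        by_receptor_class=by_class,
        percent_probands_positive=pct_pos,
        percent_expansion_vs_prior=pct_exp,
        declared_unique_variants=declared_unique_variants,
        notes=tuple(notes),
    )
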