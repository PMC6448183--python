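"""Precision evaluation against human annotation, strict and relaxed.

The system's output (extracted triples) is reviewed by annotators, so the
natural metric is precision: positives judged correct divided by the
number of extractions.  Two annotation modes are supported.  *Strict*
counts only clearly asserted causal statements as correct; *relaxed*
additionally counts negated or hypothetical causal statements ("cell
phone radiation can cause insomnia").  The micro-average pools true
positives and extraction counts across effect categories.

Internally precisions are exact fractions; rendering rounds half-up to
two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from fractions import Fraction

from .depgraph import DependencyGraph

__all__ = [
    "Label",
    "Mode",
    "Modality",
    "AnnotationRecord",
    "CategoryPrecision",
    "PrecisionReport",
    "precision_report",
    "render_comparison",
    "read_annotations_tsv",
    "modality_flag",
    "percent",
]


class Label(Enum):
    CAUSAL = "CAUSAL"
    HYPOTHETICAL_OR_NEGATED = "HYPOTHETICAL_OR_NEGATED"
    NOT_CAUSAL = "NOT_CAUSAL"


class Mode(Enum):
    STRICT = "strict"
    RELAXED = "relaxed"


@dataclass(frozen=True)
class AnnotationRecord:
    triple_id: str
    category: str  # effect keyword
    label: Label


@dataclass(frozen=True)
class CategoryPrecision:
    tp: int
    n_extracted: int

    @property
    def precision(self) -> Fraction | None:
        if self.n_extracted == 0:
            return None
        return Fraction(self.tp, self.n_extracted)


@dataclass(frozen=True)
class PrecisionReport:
    mode: Mode
    per_category: dict
    micro: CategoryPrecision


def _positive(label: Label, mode: Mode) -> bool:
    if mode is Mode.STRICT:
        return label is Label.CAUSAL
    return label in (Label.CAUSAL, Label.HYPOTHETICAL_OR_NEGATED)


def precision_report(annotations, mode: Mode) -> PrecisionReport:
    """Per-category and micro-averaged precision for one annotation mode."""
    annotations = list(annotations)
    if not annotations:
        raise ValueError("annotations must be non-empty")
    ids = [a.triple_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise ValueError("triple_id values must be unique")
    tp: dict[str, int] = {}
    n: dict[str, int] = {}
    for a in annotations:
        n[a.category] = n.get(a.category, 0) + 1
        if _positive(a.label, mode):
            tp[a.category] = tp.get(a.category, 0) + 1
    per = {
        cat: CategoryPrecision(tp.get(cat, 0), n[cat]) for cat in sorted(n)
    }
    micro = CategoryPrecision(sum(tp.values()), sum(n.values()))
    return PrecisionReport(mode, per, micro)


def percent(fr: Fraction) -> str:
    """Exact fraction -> percentage string, half-up to 2 decimals."""
    d = Decimal(fr.numerator * 100) / Decimal(fr.denominator)
    return str(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def render_comparison(annotations) -> str:
    """Text table of strict vs relaxed precision per category plus micro."""
    strict = precision_report(annotations, Mode.STRICT)
    relaxed = precision_report(annotations, Mode.RELAXED)
    rows = [("Category", "Strict", "Relaxed")]
    for cat in strict.per_category:
        rows.append(
            (
                cat,
                percent(strict.per_category[cat].precision) + "%",
                percent(relaxed.per_category[cat].precision) + "%",
            )
        )
    rows.append(
        (
            "Micro-average",
            percent(strict.micro.precision) + "%",
            percent(relaxed.micro.precision) + "%",
        )
    )
    widths = [max(len(r[i]) for r in rows) for i in range(3)]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in rows
    )


def read_annotations_tsv(lines) -> list[AnnotationRecord]:
    """Annotation TSV with columns triple_id, category, label."""
    out = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"annotation line {lineno}: expected 3 tab-separated columns"
            )
        triple_id, category, label = parts
        if lineno == 1 and label.upper() == "LABEL":
            continue  # header row
        out.append(AnnotationRecord(triple_id, category, Label[label]))
    return out


# ---------------------------------------------------------------------------
# Modality heuristics
# ---------------------------------------------------------------------------


class Modality(Enum):
    NONE = "NONE"
    NEGATED = "NEGATED"
    HYPOTHETICAL = "HYPOTHETICAL"
    INTERROGATIVE = "INTERROGATIVE"


_NEG_LEMMAS = {"not", "no", "never", "n't"}
_MODAL_LEMMAS = {"can", "could", "may", "might", "would", "should"}


def modality_flag(graph: DependencyGraph) -> Modality:
    """Advisory modality of a sentence, for annotator triage.

    Precedence: INTERROGATIVE (text ends with "?") over NEGATED (a
    negation lemma attached via neg/advmod) over HYPOTHETICAL (a modal
    auxiliary).  This is a convenience heuristic attached to extractions
    as metadata; it is never applied silently to precision figures —
    annotation remains the source of truth.
    """
    if graph.text.rstrip().endswith("?"):
        return Modality.INTERROGATIVE
    negated = hypothetical = False
    for e in graph.edges:
        lemma = graph.token(e.dependent).lemma.lower()
        if lemma in _NEG_LEMMAS and e.relation in ("neg", "advmod"):
            negated = True
        if lemma in _MODAL_LEMMAS and (
            e.relation == "aux" or e.relation.startswith("aux:")
        ):
            hypothetical = True
    if negated:
        return Modality.NEGATED
    if hypothetical:
        return Modality.HYPOTHETICAL
    return Modality.NONE
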