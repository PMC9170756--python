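"""Joint response-pattern classification (P1-P9).

Each protein gets a category on two axes — response to the single FFA
(PA) and to the combined treatment — using the same inclusive two-fold
boundaries as the DEP call, then a pattern label from the canonical map:

=========  ================  =====================================
pattern    (PA, combined)    extra condition
=========  ================  =====================================
P1         (none, none)
P2         (none, up)
P3         (none, down)
P4         (up,   up)        combined/PA mean >= threshold (enhanced)
P5         (up,   up)        otherwise
P6         (up,   none|down) combined treatment reverses PA
P7         (down, down)      includes further-down enhancement
P8         (down, none)      combined treatment reverses PA
P9         (down, up)        over-reversal
=========  ================  =====================================

P6 + P8 together are the "reversed" group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from silacpipe.dep_volcano import DOWN, NONE, UP, call_direction
from silacpipe.io_formats import SchemaError
from silacpipe.ratio_processing import ProteinSummary

PATTERNS = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9")
REVERSED_PATTERNS = ("P6", "P8")

# re-export: the category rule is shared with the DEP direction call
categorize = call_direction

_CATEGORIES = (DOWN, NONE, UP)


@dataclass(frozen=True)
class PatternAssignment:
    protein_id: str
    gene_symbol: str
    pa_category: str
    combined_category: str
    combined_over_pa: float
    enhanced: bool
    pattern: str


@dataclass(frozen=True)
class PatternSummary:
    """Per-pattern counts and proportions.

    ``total_classified`` is the proportion denominator: the number of
    proteins that passed the minimum-quantified filter. It may exceed the
    sum of the per-pattern counts when the counts come from an external
    table whose arithmetic does not close (the summary then reports both
    numbers rather than resolving the discrepancy).
    """

    counts: Mapping[str, int]
    total_classified: int
    proportions: Mapping[str, float]
    reversed_count: int

    @property
    def counts_sum(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], total_classified: int | None = None
    ) -> "PatternSummary":
        full = {p: int(counts.get(p, 0)) for p in PATTERNS}
        unknown = set(counts) - set(PATTERNS)
        if unknown:
            raise SchemaError(f"unknown pattern labels {sorted(unknown)}")
        total = sum(full.values()) if total_classified is None else int(total_classified)
        if total > 0:
            proportions = {p: c / total for p, c in full.items()}
        else:
            proportions = {p: float("nan") for p in PATTERNS}
        return cls(
            counts=full,
            total_classified=total,
            proportions=proportions,
            reversed_count=sum(full[p] for p in REVERSED_PATTERNS),
        )


def classify_pattern(
    pa_category: str,
    combined_category: str,
    combined_over_pa_mean: float,
    threshold: float = 2.0,
) -> str:
    """Canonical pattern label for a (PA, combined) category pair.

    ``combined_over_pa_mean`` decides enhancement: a (up, up) protein
    whose combined/PA mean crosses the threshold again is P4 rather
    than P5.
    """
    for name, cat in (("pa_category", pa_category), ("combined_category", combined_category)):
        if cat not in _CATEGORIES:
            raise SchemaError(f"{name} must be one of {_CATEGORIES}, got {cat!r}")
    if not combined_over_pa_mean > 0:
        raise SchemaError(
            f"combined_over_pa_mean must be > 0, got {combined_over_pa_mean}"
        )
    if pa_category == NONE:
        return {NONE: "P1", UP: "P2", DOWN: "P3"}[combined_category]
    if pa_category == UP:
        if combined_category == UP:
            return "P4" if combined_over_pa_mean >= threshold else "P5"
        return "P6"  # combined treatment reversed (or over-reversed) the PA response
    # pa_category == DOWN
    if combined_category == DOWN:
        return "P7"
    if combined_category == NONE:
        return "P8"
    return "P9"


def _is_enhanced(pa_category: str, combined_over_pa: float, threshold: float) -> bool:
    if pa_category == UP:
        return combined_over_pa >= threshold
    if pa_category == DOWN:
        return combined_over_pa <= 1.0 / threshold
    return False


def classify_summaries(
    summaries: Iterable[ProteinSummary], threshold: float = 2.0
) -> list[PatternAssignment]:
    """Assign every summarized protein its response pattern."""
    assignments: list[PatternAssignment] = []
    for s in summaries:
        if s.n_quantified < 1:
            raise SchemaError(
                f"protein {s.protein_id!r} has no complete replicate; "
                "apply the minimum-quantified filter before classifying"
            )
        pa_cat = categorize(s.pa_mean, threshold)
        combined_cat = categorize(s.combined_mean, threshold)
        assignments.append(
            PatternAssignment(
                protein_id=s.protein_id,
                gene_symbol=s.gene_symbol,
                pa_category=pa_cat,
                combined_category=combined_cat,
                combined_over_pa=s.combined_over_pa_mean,
                enhanced=_is_enhanced(pa_cat, s.combined_over_pa_mean, threshold),
                pattern=classify_pattern(
                    pa_cat, combined_cat, s.combined_over_pa_mean, threshold
                ),
            )
        )
    return assignments


def summarize_patterns(
    assignments: Sequence[PatternAssignment],
    total_classified: int | None = None,
) -> PatternSummary:
    """Count assignments per pattern and compute proportions.

    By default the proportion denominator is the number of assignments;
    pass ``total_classified`` to use an externally fixed analysis total.
    """
    counts = {p: 0 for p in PATTERNS}
    for a in assignments:
        counts[a.pattern] += 1
    return PatternSummary.from_counts(counts, total_classified)


ASSIGNMENT_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "pa_category",
    "combined_category",
    "combined_over_pa",
    "enhanced",
    "pattern",
]


def write_assignments(assignments: Iterable[PatternAssignment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for a in assignments:
            fh.write(
                "\t".join(
                    [
                        a.protein_id,
                        a.gene_symbol,
                        a.pa_category,
                        a.combined_category,
                        repr(a.combined_over_pa),
                        "1" if a.enhanced else "0",
                        a.pattern,
                    ]
                )
                + "\n"
            )
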