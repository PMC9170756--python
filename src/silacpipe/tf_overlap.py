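"""TF-target filtering and intersection with response-pattern groups.

Predicted TF targets are kept when both binding scores are strictly
positive (configurable minimum) and the peak lies within the TSS window;
the retained gene set is then intersected with the proteins assigned to
each requested pattern. "Responders" are the targets falling in any
non-P1 pattern (P2-P9).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from silacpipe.io_formats import SchemaError, TFTargetRecord
from silacpipe.pattern_classifier import PATTERNS, PatternAssignment

RESPONDER_PATTERNS = tuple(p for p in PATTERNS if p != "P1")


@dataclass(frozen=True)
class PatternOverlap:
    """Per-pattern target overlaps plus the all-responder union."""

    per_pattern: Mapping[str, frozenset[str]]
    responders: frozenset[str]

    def count(self, pattern: str) -> int:
        return len(self.per_pattern[pattern])


def filter_tf_targets(
    records: Iterable[TFTargetRecord],
    score_min: float = 0.0,
    tss_max_kb: float = 1.0,
    require_both_scores: bool = True,
) -> frozenset[str]:
    """Genes whose binding scores exceed ``score_min`` (strict) and whose
    peak is within ``tss_max_kb`` of the TSS (inclusive).

    ``require_both_scores=False`` keeps genes where either score passes.
    """
    kept: set[str] = set()
    for r in records:
        macs2_ok = r.binding_score_macs2 > score_min
        string_ok = r.binding_score_string > score_min
        score_ok = (macs2_ok and string_ok) if require_both_scores else (macs2_ok or string_ok)
        if score_ok and r.tss_distance_kb <= tss_max_kb:
            kept.add(r.gene_symbol)
    return frozenset(kept)


def intersect_targets_with_patterns(
    targets: Iterable[str],
    assignments: Sequence[PatternAssignment],
    patterns: Iterable[str] = RESPONDER_PATTERNS,
) -> PatternOverlap:
    """Intersect a TF-target gene set with the genes assigned to each
    requested pattern; also return the union over all non-P1 patterns."""
    requested = list(patterns)
    unknown = set(requested) - set(PATTERNS)
    if unknown:
        raise SchemaError(f"unknown pattern labels {sorted(unknown)}")
    target_set = {g.upper() for g in targets}
    by_pattern: dict[str, set[str]] = {p: set() for p in PATTERNS}
    for a in assignments:
        if a.gene_symbol:
            by_pattern[a.pattern].add(a.gene_symbol.upper())
    responders: set[str] = set()
    for p in RESPONDER_PATTERNS:
        responders |= by_pattern[p] & target_set
    return PatternOverlap(
        per_pattern={p: frozenset(by_pattern[p] & target_set) for p in requested},
        responders=frozenset(responders),
    )


def write_overlap_table(overlap: PatternOverlap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pattern\tn_overlap\tgenes\n")
        for pattern in sorted(overlap.per_pattern):
            genes = sorted(overlap.per_pattern[pattern])
            fh.write(f"{pattern}\t{len(genes)}\t{';'.join(genes)}\n")
        fh.write(
            f"responders\t{len(overlap.responders)}\t{';'.join(sorted(overlap.responders))}\n"
        )
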