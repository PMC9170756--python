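"""Channel-ratio harmonization and per-protein aggregation.

The medium channel always carries the vehicle control. In a forward
replicate the light channel is the single-FFA (PA) treatment and the
heavy channel the combined treatment; a reverse replicate swaps the two.
Harmonization therefore maps (ratio_lm, ratio_hm) onto
(PA/control, combined/control) per replicate, after which the
forward/reverse distinction is gone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from silacpipe.io_formats import (
    FORWARD,
    ORIENTATIONS,
    REVERSE,
    ExperimentDesign,
    QuantRecord,
    SchemaError,
)


@dataclass(frozen=True)
class TreatmentRatios:
    """Per-replicate treatment/control ratios after orientation harmonization."""

    protein_id: str
    gene_symbol: str
    replicate_id: str
    pa_over_control: float | None
    combined_over_control: float | None

    @property
    def complete(self) -> bool:
        return self.pa_over_control is not None and self.combined_over_control is not None


@dataclass(frozen=True)
class ProteinSummary:
    """Per-protein ratio statistics over replicates.

    Only replicates quantified on BOTH axes count toward ``n_quantified``
    and enter the statistics, since the pattern taxonomy needs both.
    Means and SDs are on the linear ratio scale; the log2 lists feed the
    volcano t-tests.
    """

    protein_id: str
    gene_symbol: str
    n_quantified: int
    pa_mean: float
    pa_sd: float
    combined_mean: float
    combined_sd: float
    combined_over_pa_mean: float
    log2_pa: tuple[float, ...]
    log2_combined: tuple[float, ...]


def harmonize_orientation(record: QuantRecord, orientation: str) -> TreatmentRatios:
    """Map channel ratios to treatment/control ratios for one replicate.

    forward: PA/control = light/medium, combined/control = heavy/medium.
    reverse: PA/control = heavy/medium, combined/control = light/medium.
    Missing channels propagate to missing outputs.
    """
    if orientation not in ORIENTATIONS:
        raise SchemaError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    if orientation == FORWARD:
        pa, combined = record.ratio_lm, record.ratio_hm
    else:
        pa, combined = record.ratio_hm, record.ratio_lm
    return TreatmentRatios(
        protein_id=record.protein_id,
        gene_symbol=record.gene_symbol,
        replicate_id=record.replicate_id,
        pa_over_control=pa,
        combined_over_control=combined,
    )


def _sample_sd(values: Sequence[float], mean: float) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def aggregate_protein(ratios: Sequence[TreatmentRatios]) -> ProteinSummary:
    """Aggregate one protein's harmonized replicate ratios.

    Means are arithmetic means of the linear ratios; SDs use the sample
    (n-1) denominator and are 0 at n=1. ``combined_over_pa_mean`` is the
    mean over replicates of the per-replicate combined/PA ratio.
    """
    if not ratios:
        raise SchemaError("aggregate_protein: empty input")
    pids = {r.protein_id for r in ratios}
    if len(pids) != 1:
        raise SchemaError(f"aggregate_protein: mixed protein ids {sorted(pids)}")
    complete = [r for r in ratios if r.complete]
    n = len(complete)
    if n == 0:
        return ProteinSummary(
            protein_id=ratios[0].protein_id,
            gene_symbol=ratios[0].gene_symbol,
            n_quantified=0,
            pa_mean=math.nan,
            pa_sd=math.nan,
            combined_mean=math.nan,
            combined_sd=math.nan,
            combined_over_pa_mean=math.nan,
            log2_pa=(),
            log2_combined=(),
        )
    pa = [r.pa_over_control for r in complete]
    combined = [r.combined_over_control for r in complete]
    pa_mean = sum(pa) / n
    combined_mean = sum(combined) / n
    return ProteinSummary(
        protein_id=ratios[0].protein_id,
        gene_symbol=ratios[0].gene_symbol,
        n_quantified=n,
        pa_mean=pa_mean,
        pa_sd=_sample_sd(pa, pa_mean),
        combined_mean=combined_mean,
        combined_sd=_sample_sd(combined, combined_mean),
        combined_over_pa_mean=sum(c / p for p, c in zip(pa, combined)) / n,
        log2_pa=tuple(math.log2(v) for v in pa),
        log2_combined=tuple(math.log2(v) for v in combined),
    )


def filter_min_quantified(
    summaries: Iterable[ProteinSummary], k: int
) -> list[ProteinSummary]:
    """Keep proteins quantified (both axes) in at least ``k`` replicates."""
    if k < 1:
        raise SchemaError(f"min quantified k must be >= 1, got {k}")
    return [s for s in summaries if s.n_quantified >= k]


def summarize_records(
    records: Iterable[QuantRecord], design: ExperimentDesign
) -> list[ProteinSummary]:
    """Harmonize all records per the design and aggregate per protein.

    Output order follows first appearance of each protein in the input.
    """
    by_protein: dict[str, list[TreatmentRatios]] = {}
    for record in records:
        orientation = design.orientation_of(record.replicate_id)
        by_protein.setdefault(record.protein_id, []).append(
            harmonize_orientation(record, orientation)
        )
    return [aggregate_protein(ratios) for ratios in by_protein.values()]


SUMMARY_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "n_quantified",
    "pa_mean",
    "pa_sd",
    "combined_mean",
    "combined_sd",
    "combined_over_pa_mean",
]


def write_summary_table(summaries: Iterable[ProteinSummary], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            fh.write(
                "\t".join(
                    [
                        s.protein_id,
                        s.gene_symbol,
                        str(s.n_quantified),
                        repr(s.pa_mean),
                        repr(s.pa_sd),
                        repr(s.combined_mean),
                        repr(s.combined_sd),
                        repr(s.combined_over_pa_mean),
                    ]
                )
                + "\n"
            )
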