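"""Differential-expression calls and volcano-table statistics.

A protein is a DEP purely by fold change: mean treatment/control ratio at
or above the threshold (up) or at or below its reciprocal (down), among
proteins passing the minimum-quantified filter. t-tests on the log2
ratios annotate the volcano plot but do not gate the DEP call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from silacpipe.io_formats import SchemaError
from silacpipe.ratio_processing import ProteinSummary

UP = "up"
DOWN = "down"
NONE = "none"

PA_VS_CONTROL = "PA_vs_control"
COMBINED_VS_CONTROL = "combined_vs_control"

#: flags explaining an undefined p-value
FLAG_OK = "ok"
FLAG_INSUFFICIENT = "insufficient replicates"
FLAG_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class TTestResult:
    t_stat: float | None
    p_value: float | None
    flag: str = FLAG_OK


@dataclass(frozen=True)
class DepCall:
    protein_id: str
    gene_symbol: str
    contrast: str
    mean_ratio: float
    log2_ratio: float
    direction: str
    t_stat: float | None
    p_value: float | None
    flag: str

    @property
    def is_dep(self) -> bool:
        return self.direction != NONE


def call_direction(mean_ratio: float, threshold: float) -> str:
    """up if ratio >= threshold, down if ratio <= 1/threshold, else none.

    Both boundaries are inclusive; the no-change band is the open
    interval (1/threshold, threshold).
    """
    if threshold <= 1:
        raise SchemaError(f"threshold must be > 1, got {threshold}")
    if not (mean_ratio > 0) or not math.isfinite(mean_ratio):
        raise SchemaError(f"mean_ratio must be finite and > 0, got {mean_ratio}")
    if mean_ratio >= threshold:
        return UP
    if mean_ratio <= 1.0 / threshold:
        return DOWN
    return NONE


def one_sample_t(log2_ratios: Sequence[float]) -> TTestResult:
    """Two-sided one-sample t-test of the mean log2 ratio against 0.

    Degenerate inputs are flagged rather than raising: fewer than two
    replicates -> undefined; zero variance with nonzero mean ->
    undefined ("degenerate"); all zeros -> t=0, p=1.
    """
    values = [float(v) for v in log2_ratios]
    if any(not math.isfinite(v) for v in values):
        raise SchemaError("log2 ratios must be finite")
    n = len(values)
    if n < 2:
        return TTestResult(None, None, FLAG_INSUFFICIENT)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    if var == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 1.0, FLAG_OK)
        return TTestResult(None, None, FLAG_DEGENERATE)
    t, p = stats.ttest_1samp(values, popmean=0.0)
    return TTestResult(float(t), float(p), FLAG_OK)


def volcano_table(
    summaries: Iterable[ProteinSummary],
    fold_change_threshold: float = 2.0,
    bh_adjust: bool = False,
) -> list[DepCall]:
    """One DepCall per protein per contrast (PA and combined vs control).

    ``bh_adjust=True`` replaces each defined p-value with its
    Benjamini-Hochberg adjusted value, computed within each contrast.
    """
    calls: list[DepCall] = []
    for s in summaries:
        for contrast, mean_ratio, log2s in (
            (PA_VS_CONTROL, s.pa_mean, s.log2_pa),
            (COMBINED_VS_CONTROL, s.combined_mean, s.log2_combined),
        ):
            tt = one_sample_t(log2s) if len(log2s) >= 2 else TTestResult(
                None, None, FLAG_INSUFFICIENT
            )
            calls.append(
                DepCall(
                    protein_id=s.protein_id,
                    gene_symbol=s.gene_symbol,
                    contrast=contrast,
                    mean_ratio=mean_ratio,
                    log2_ratio=math.log2(mean_ratio),
                    direction=call_direction(mean_ratio, fold_change_threshold),
                    t_stat=tt.t_stat,
                    p_value=tt.p_value,
                    flag=tt.flag,
                )
            )
    if bh_adjust:
        calls = _apply_bh(calls)
    return calls


def _apply_bh(calls: list[DepCall]) -> list[DepCall]:
    from dataclasses import replace

    adjusted = list(calls)
    for contrast in (PA_VS_CONTROL, COMBINED_VS_CONTROL):
        idx = [i for i, c in enumerate(adjusted) if c.contrast == contrast and c.p_value is not None]
        if not idx:
            continue
        ps = [adjusted[i].p_value for i in idx]
        qs = _bh(ps)
        for i, q in zip(idx, qs):
            adjusted[i] = replace(adjusted[i], p_value=q)
    return adjusted


def _bh(p_values: Sequence[float]) -> list[float]:
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    qs = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = p_values[i] * m / rank_from_top
        running_min = min(running_min, q)
        qs[i] = running_min
    return qs


VOLCANO_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "contrast",
    "mean_ratio",
    "log2_ratio",
    "t",
    "p",
    "minus_log10_p",
    "dep_flag",
    "direction",
]


def write_volcano_table(calls: Iterable[DepCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(VOLCANO_COLUMNS) + "\n")
        for c in calls:
            minus_log10 = (
                "NA"
                if c.p_value is None
                else ("inf" if c.p_value == 0 else repr(-math.log10(c.p_value)))
            )
            fh.write(
                "\t".join(
                    [
                        c.protein_id,
                        c.gene_symbol,
                        c.contrast,
                        repr(c.mean_ratio),
                        repr(c.log2_ratio),
                        "NA" if c.t_stat is None else repr(c.t_stat),
                        "NA" if c.p_value is None else repr(c.p_value),
                        minus_log10,
                        "1" if c.is_dep else "0",
                        c.direction,
                    ]
                )
                + "\n"
            )
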