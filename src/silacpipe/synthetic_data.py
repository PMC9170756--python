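"""Synthetic triple-SILAC data with known per-protein response patterns.

Ratios are generated on the treatment/control scale — true fold times
log-normal multiplicative noise, i.i.d. across replicates — and then
converted to channel ratios by inverting the orientation mapping for
each replicate. Missingness is completely at random per protein x
replicate. One master seed drives everything; each protein gets its own
substream keyed by its index, so growing ``n_proteins`` never reshuffles
earlier proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from silacpipe.io_formats import (
    FORWARD,
    ExperimentDesign,
    GeneSet,
    QuantRecord,
    SchemaError,
    TFTargetRecord,
)
from silacpipe.pattern_classifier import PATTERNS

DEFAULT_DESIGN = ExperimentDesign(
    experiment_label="synthetic",
    replicates=(("F1", "forward"), ("F2", "forward"), ("R1", "reverse")),
)

#: pattern mix loosely shaped like a real experiment: mostly unresponsive
DEFAULT_PATTERN_MIX = {
    "P1": 0.70,
    "P2": 0.05,
    "P3": 0.02,
    "P4": 0.02,
    "P5": 0.06,
    "P6": 0.08,
    "P7": 0.02,
    "P8": 0.04,
    "P9": 0.01,
}


@dataclass(frozen=True)
class SyntheticTruth:
    protein_id: str
    gene_symbol: str
    true_pattern: str
    true_pa_fold: float
    true_combined_fold: float
    member_sets: tuple[str, ...] = ()
    is_tf_target: bool = False


@dataclass(frozen=True)
class SimulationSpec:
    n_proteins: int = 1000
    pattern_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_MIX)
    )
    fold_up: float = 4.0
    fold_down: float = 0.25
    enhancement_fold: float = 4.0
    log2_noise_sd: float = 0.2
    missing_prob: float = 0.0
    design: ExperimentDesign = DEFAULT_DESIGN
    seed: int = 0
    threshold: float = 2.0  # category boundary the folds must clear

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SchemaError("n_proteins must be >= 1")
        unknown = set(self.pattern_mix) - set(PATTERNS)
        if unknown:
            raise SchemaError(f"pattern_mix has unknown patterns {sorted(unknown)}")
        total = sum(self.pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SchemaError(f"pattern_mix must sum to 1, got {total}")
        if any(v < 0 for v in self.pattern_mix.values()):
            raise SchemaError("pattern_mix probabilities must be >= 0")
        if not (0 <= self.missing_prob < 1):
            raise SchemaError("missing_prob must be in [0, 1)")
        if self.log2_noise_sd < 0:
            raise SchemaError("log2_noise_sd must be >= 0")
        # folds inside the no-change band make the planted pattern unrecoverable
        if self.fold_up < self.threshold:
            raise SchemaError(
                f"fold_up {self.fold_up} is inside the no-change band "
                f"(needs >= {self.threshold})"
            )
        if self.fold_down > 1.0 / self.threshold:
            raise SchemaError(
                f"fold_down {self.fold_down} is inside the no-change band "
                f"(needs <= {1.0 / self.threshold})"
            )
        if self.enhancement_fold < self.threshold:
            raise SchemaError(
                f"enhancement_fold {self.enhancement_fold} must be >= {self.threshold}"
            )


def true_folds(pattern: str, spec: SimulationSpec) -> tuple[float, float]:
    """(PA fold, combined fold) planted for a pattern under ``spec``."""
    up, down, enh = spec.fold_up, spec.fold_down, spec.enhancement_fold
    table = {
        "P1": (1.0, 1.0),
        "P2": (1.0, up),
        "P3": (1.0, down),
        "P4": (up, up * enh),
        "P5": (up, up),
        "P6": (up, 1.0),
        "P7": (down, down),
        "P8": (down, 1.0),
        "P9": (down, up),
    }
    return table[pattern]


def _protein_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[list[QuantRecord], list[SyntheticTruth]]:
    """Draw a quant table plus its ground truth.

    For each protein: draw a pattern, set the true folds, then per
    replicate draw noisy PA and combined treatment/control ratios and
    convert them to (heavy/medium, light/medium) channel ratios per that
    replicate's orientation. Whole protein x replicate observations drop
    out with probability ``missing_prob``. Noise and dropout draws do not
    depend on replicate orientation, so relabeled designs over the same
    seed produce identical harmonized ratios.
    """
    labels = sorted(spec.pattern_mix)
    probs = np.array([spec.pattern_mix[p] for p in labels])
    records: list[QuantRecord] = []
    truths: list[SyntheticTruth] = []
    width = max(5, len(str(spec.n_proteins)))
    for i in range(spec.n_proteins):
        rng = _protein_rng(spec.seed, i)
        pattern = labels[rng.choice(len(labels), p=probs)]
        pa_fold, combined_fold = true_folds(pattern, spec)
        protein_id = f"PROT{i:0{width}d}"
        gene_symbol = f"GENE{i:0{width}d}"
        truths.append(
            SyntheticTruth(protein_id, gene_symbol, pattern, pa_fold, combined_fold)
        )
        for rep_id, orientation in spec.design.replicates:
            noise = rng.normal(0.0, 1.0, size=2)
            dropped = rng.random() < spec.missing_prob
            if dropped:
                continue
            pa_ratio = pa_fold * 2.0 ** (spec.log2_noise_sd * noise[0])
            combined_ratio = combined_fold * 2.0 ** (spec.log2_noise_sd * noise[1])
            if orientation == FORWARD:
                lm, hm = pa_ratio, combined_ratio
            else:
                lm, hm = combined_ratio, pa_ratio
            records.append(
                QuantRecord(
                    protein_id=protein_id,
                    gene_symbol=gene_symbol,
                    replicate_id=rep_id,
                    ratio_hm=float(hm),
                    ratio_lm=float(lm),
                )
            )
    return records, truths


def simulate_annotations(
    truth: Sequence[SyntheticTruth],
    n_sets: int,
    planted_set: tuple[str, str, float] | None = None,
    seed: int = 0,
    set_size: int = 50,
    planted_size: int | None = None,
    tf_target_patterns: Iterable[str] = ("P6", "P8"),
    tf_prob_in: float = 0.5,
    tf_prob_out: float = 0.02,
    filter_fail_frac: float = 0.0,
) -> tuple[list[SyntheticTruth], list[GeneSet], list[TFTargetRecord]]:
    """Draw gene-set and TF-target fixtures matched to a simulated truth.

    Background sets sample genes uniformly. ``planted_set`` is a
    (name, target_pattern, enrichment_odds) triple: its members are drawn
    with sampling weight ``odds`` for genes of the target pattern and 1
    otherwise, so odds=1 reduces to a background set. TF-target flags
    fire with probability ``tf_prob_in`` inside ``tf_target_patterns``
    and ``tf_prob_out`` elsewhere; a ``filter_fail_frac`` fraction of
    flagged genes get a score or TSS distance that fails the published
    filters. Returns the truth annotated with memberships and flags,
    plus the GMT-ready sets and the TF table rows.
    """
    if not truth:
        raise SchemaError("truth must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xA1,)))
    genes = np.array([t.gene_symbol for t in truth])
    patterns = np.array([t.true_pattern for t in truth])
    n = len(genes)
    size = min(set_size, n)

    memberships: dict[str, list[str]] = {g: [] for g in genes}
    gene_sets: list[GeneSet] = []

    for k in range(n_sets):
        idx = rng.choice(n, size=size, replace=False)
        name = f"SET{k:04d}"
        gene_sets.append(GeneSet(name, "background set", frozenset(genes[idx])))
        for g in genes[idx]:
            memberships[g].append(name)

    if planted_set is not None:
        name, target_pattern, odds = planted_set
        if target_pattern not in PATTERNS:
            raise SchemaError(f"unknown target pattern {target_pattern!r}")
        if odds <= 0:
            raise SchemaError("enrichment odds must be > 0")
        weights = np.where(patterns == target_pattern, odds, 1.0)
        weights = weights / weights.sum()
        p_size = min(planted_size or size, n)
        idx = rng.choice(n, size=p_size, replace=False, p=weights)
        gene_sets.append(GeneSet(name, "planted set", frozenset(genes[idx])))
        for g in genes[idx]:
            memberships[g].append(name)

    tf_patterns = set(tf_target_patterns)
    unknown = tf_patterns - set(PATTERNS)
    if unknown:
        raise SchemaError(f"unknown TF target patterns {sorted(unknown)}")
    tf_records: list[TFTargetRecord] = []
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        p_flag = tf_prob_in if patterns[i] in tf_patterns else tf_prob_out
        flagged[i] = rng.random() < p_flag
        if not flagged[i]:
            continue
        if rng.random() < filter_fail_frac:
            # fail exactly one of the three filter conditions
            mode = rng.choice(3)
            macs2 = 0.0 if mode == 0 else float(rng.uniform(1, 10))
            string = 0.0 if mode == 1 else float(rng.uniform(1, 10))
            tss = float(rng.uniform(1.5, 10)) if mode == 2 else float(rng.uniform(0, 1))
        else:
            macs2 = float(rng.uniform(1, 10))
            string = float(rng.uniform(1, 10))
            tss = float(rng.uniform(0, 1))
        tf_records.append(TFTargetRecord(str(genes[i]), macs2, string, tss))

    annotated = [
        replace(
            t,
            member_sets=tuple(memberships[t.gene_symbol]),
            is_tf_target=bool(flagged[i]),
        )
        for i, t in enumerate(truth)
    ]
    return annotated, gene_sets, tf_records


def exemplar_summaries(
    counts: Mapping[str, int], spec: SimulationSpec | None = None
) -> list:
    """Noise-free ProteinSummary rows realizing exact per-pattern counts.

    For each pattern, emits ``counts[pattern]`` proteins carrying that
    pattern's planted fold pair with three complete replicates — a
    deterministic fixture for exercising the classification and summary
    stages against externally printed count tables.
    """
    import math

    from silacpipe.ratio_processing import ProteinSummary

    spec = spec or SimulationSpec()
    unknown = set(counts) - set(PATTERNS)
    if unknown:
        raise SchemaError(f"unknown pattern labels {sorted(unknown)}")
    summaries = []
    i = 0
    for pattern in PATTERNS:
        pa_fold, combined_fold = true_folds(pattern, spec)
        for _ in range(int(counts.get(pattern, 0))):
            summaries.append(
                ProteinSummary(
                    protein_id=f"PROT{i:06d}",
                    gene_symbol=f"GENE{i:06d}",
                    n_quantified=3,
                    pa_mean=pa_fold,
                    pa_sd=0.0,
                    combined_mean=combined_fold,
                    combined_sd=0.0,
                    combined_over_pa_mean=combined_fold / pa_fold,
                    log2_pa=(math.log2(pa_fold),) * 3,
                    log2_combined=(math.log2(combined_fold),) * 3,
                )
            )
            i += 1
    return summaries


TRUTH_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "true_pattern",
    "true_pa_fold",
    "true_combined_fold",
    "member_sets",
    "is_tf_target",
]


def write_truth_table(truths: Iterable[SyntheticTruth], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write(
                "\t".join(
                    [
                        t.protein_id,
                        t.gene_symbol,
                        t.true_pattern,
                        repr(t.true_pa_fold),
                        repr(t.true_combined_fold),
                        ";".join(t.member_sets),
                        "1" if t.is_tf_target else "0",
                    ]
                )
                + "\n"
            )


def read_truth_table(path: str | Path) -> list[SyntheticTruth]:
    truths: list[SyntheticTruth] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise SchemaError(f"{path}: expected header {TRUTH_COLUMNS}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            pid, gene, pattern, pa, combined, sets, flag = line.rstrip("\n").split("\t")
            truths.append(
                SyntheticTruth(
                    protein_id=pid,
                    gene_symbol=gene,
                    true_pattern=pattern,
                    true_pa_fold=float(pa),
                    true_combined_fold=float(combined),
                    member_sets=tuple(s for s in sets.split(";") if s),
                    is_tf_target=flag == "1",
                )
            )
    return truths
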