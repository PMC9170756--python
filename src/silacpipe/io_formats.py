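"""Readers and writers for every external table the pipeline touches.

All tables are UTF-8, tab-separated, with a mandatory header row and "."
as the decimal point. Gene symbols are uppercased at ingestion so that
protein-style and gene-style capitalization match downstream.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

FORWARD = "forward"
REVERSE = "reverse"
ORIENTATIONS = (FORWARD, REVERSE)

#: tokens treated as a missing ratio on read (case-insensitive)
MISSING_TOKENS = {"", "na", "nan", "none", "null"}


class SchemaError(ValueError):
    """A file violates its declared schema or a record its invariants."""


class DesignMismatchError(SchemaError):
    """A quant table references a replicate absent from the design."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentDesign:
    """Which replicates exist and how each is labeled.

    The control is always the medium channel; the orientation decides
    whether the light or the heavy channel carries the single-FFA
    treatment.
    """

    experiment_label: str
    replicates: tuple[tuple[str, str], ...]  # (replicate_id, orientation)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise SchemaError("design must declare at least one replicate")
        ids = [rid for rid, _ in self.replicates]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate replicate ids in design: {ids}")
        for rid, orient in self.replicates:
            if orient not in ORIENTATIONS:
                raise SchemaError(
                    f"replicate {rid!r}: orientation must be one of "
                    f"{ORIENTATIONS}, got {orient!r}"
                )

    @property
    def replicate_ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.replicates)

    def orientation_of(self, replicate_id: str) -> str:
        for rid, orient in self.replicates:
            if rid == replicate_id:
                return orient
        raise DesignMismatchError(f"unknown replicate id {replicate_id!r}")


@dataclass(frozen=True)
class QuantRecord:
    """One protein x replicate observation of channel ratios.

    ``ratio_hm`` is heavy/medium, ``ratio_lm`` is light/medium; either may
    be missing (None). Present ratios must be finite and strictly positive.
    """

    protein_id: str
    gene_symbol: str
    replicate_id: str
    ratio_hm: float | None
    ratio_lm: float | None

    def __post_init__(self) -> None:
        for name, value in (("ratio_hm", self.ratio_hm), ("ratio_lm", self.ratio_lm)):
            if value is None:
                continue
            if not math.isfinite(value) or value <= 0:
                raise SchemaError(
                    f"protein {self.protein_id!r} replicate {self.replicate_id!r}: "
                    f"{name} must be finite and > 0, got {value!r}"
                )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; symbols are stored uppercase."""

    set_name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise SchemaError(f"gene set {self.set_name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


@dataclass(frozen=True)
class TFTargetRecord:
    """One ChIP-predicted TF-target gene with its two binding scores and
    the distance of the peak from the transcription start site (kb)."""

    gene_symbol: str
    binding_score_macs2: float
    binding_score_string: float
    tss_distance_kb: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_symbol", self.gene_symbol.upper())
        for name in ("binding_score_macs2", "binding_score_string", "tss_distance_kb"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise SchemaError(f"gene {self.gene_symbol!r}: {name} must be finite")
        if self.tss_distance_kb < 0:
            raise SchemaError(
                f"gene {self.gene_symbol!r}: tss_distance_kb must be >= 0, "
                f"got {self.tss_distance_kb}"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold the pipeline applies, with the published defaults."""

    fold_change_threshold: float = 2.0
    min_quantified: int = 2
    enrich_p_max: float = 0.01
    enrich_min_count: int = 3
    enrich_min_factor: float = 1.5
    tf_score_min: float = 0.0  # exclusive
    tf_tss_max_kb: float = 1.0
    random_seed: int = 0
    background_mode: str = "annotation_universe"

    def __post_init__(self) -> None:
        if self.fold_change_threshold <= 1:
            raise SchemaError("fold_change_threshold must be > 1")
        if self.min_quantified < 1:
            raise SchemaError("min_quantified must be >= 1")
        if not (0 < self.enrich_p_max <= 1):
            raise SchemaError("enrich_p_max must be in (0, 1]")
        if self.background_mode not in ("annotation_universe", "quantified_only"):
            raise SchemaError(
                f"background_mode must be 'annotation_universe' or "
                f"'quantified_only', got {self.background_mode!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"config {path}: expected a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__},
                fh,
                sort_keys=False,
            )


# ---------------------------------------------------------------------------
# quant tables
# ---------------------------------------------------------------------------

QUANT_COLUMNS = ["protein_id", "gene_symbol", "replicate_id", "ratio_hm", "ratio_lm"]


def _parse_ratio(token: str, column: str, line_no: int) -> float | None:
    if token.strip().lower() in MISSING_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError:
        raise SchemaError(f"line {line_no}: {column}={token!r} is not a number")
    if not math.isfinite(value) or value <= 0:
        raise SchemaError(
            f"line {line_no}: {column} must be finite and > 0, got {token!r}"
        )
    return value


def _check_header(header: Sequence[str], expected: Sequence[str], path: str | Path) -> None:
    if list(header) != list(expected):
        raise SchemaError(
            f"{path}: expected header {list(expected)}, got {list(header)}"
        )


def read_quant_table(path: str | Path, design: ExperimentDesign) -> list[QuantRecord]:
    """Read a channel-ratio TSV, validating rows against ``design``.

    Missing-value tokens ("", "NA", "NaN", ...) become missing ratios;
    gene symbols are uppercased. Raises :class:`DesignMismatchError` for a
    replicate id absent from the design and :class:`SchemaError` for
    non-positive ratios or duplicated (protein, replicate) keys, naming
    the offending line.
    """
    records: list[QuantRecord] = []
    seen: set[tuple[str, str]] = set()
    known = set(design.replicate_ids)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file (header required)")
        _check_header(header, QUANT_COLUMNS, path)
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(QUANT_COLUMNS):
                raise SchemaError(
                    f"line {line_no}: expected {len(QUANT_COLUMNS)} fields, got {len(row)}"
                )
            protein_id, gene_symbol, replicate_id, hm_tok, lm_tok = row
            if replicate_id not in known:
                raise DesignMismatchError(
                    f"line {line_no}: replicate {replicate_id!r} not declared in "
                    f"design {design.experiment_label!r} "
                    f"(known: {list(design.replicate_ids)})"
                )
            key = (protein_id, replicate_id)
            if key in seen:
                raise SchemaError(f"line {line_no}: duplicate record for {key}")
            seen.add(key)
            try:
                record = QuantRecord(
                    protein_id=protein_id,
                    gene_symbol=gene_symbol.upper(),
                    replicate_id=replicate_id,
                    ratio_hm=_parse_ratio(hm_tok, "ratio_hm", line_no),
                    ratio_lm=_parse_ratio(lm_tok, "ratio_lm", line_no),
                )
            except SchemaError:
                raise
            records.append(record)
    return records


def write_quant_table(records: Iterable[QuantRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(QUANT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.protein_id,
                    r.gene_symbol,
                    r.replicate_id,
                    "NA" if r.ratio_hm is None else repr(r.ratio_hm),
                    "NA" if r.ratio_lm is None else repr(r.ratio_lm),
                ]
            )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a standard GMT file: name TAB description TAB gene1 TAB gene2...

    Duplicate genes within a line are deduplicated by set semantics.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path} line {line_no}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise SchemaError(f"{path} line {line_no}: gene set {name!r} is empty")
            sets.append(GeneSet(name, description, frozenset(genes)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# TF-target tables
# ---------------------------------------------------------------------------

TF_COLUMNS = ["gene_symbol", "score_macs2", "score_string", "tss_distance_kb"]


def read_tf_targets(path: str | Path) -> list[TFTargetRecord]:
    """Read a TF-target TSV. No filtering is applied at read time;
    score/TSS filtering is a separate pipeline step."""
    records: list[TFTargetRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file (header required)")
        _check_header(header, TF_COLUMNS, path)
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(TF_COLUMNS):
                raise SchemaError(
                    f"line {line_no}: expected {len(TF_COLUMNS)} fields, got {len(row)}"
                )
            gene, macs2_tok, string_tok, tss_tok = row
            try:
                macs2 = float(macs2_tok)
                string = float(string_tok)
                tss = float(tss_tok)
            except ValueError:
                raise SchemaError(f"line {line_no}: non-numeric score or distance")
            try:
                records.append(TFTargetRecord(gene, macs2, string, tss))
            except SchemaError as exc:
                raise SchemaError(f"line {line_no}: {exc}")
    return records


def write_tf_targets(records: Iterable[TFTargetRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TF_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gene_symbol,
                    repr(r.binding_score_macs2),
                    repr(r.binding_score_string),
                    repr(r.tss_distance_kb),
                ]
            )


# ---------------------------------------------------------------------------
# experiment design (YAML)
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> ExperimentDesign:
    """Read a design YAML::

        experiment_label: PA+OA
        replicates:
          - {id: F1, orientation: forward}
          - {id: F2, orientation: forward}
          - {id: R1, orientation: reverse}
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "replicates" not in data:
        raise SchemaError(f"{path}: design must be a mapping with 'replicates'")
    reps = []
    for i, entry in enumerate(data["replicates"]):
        if not isinstance(entry, dict) or "id" not in entry or "orientation" not in entry:
            raise SchemaError(
                f"{path}: replicate #{i + 1} needs 'id' and 'orientation' keys"
            )
        reps.append((str(entry["id"]), str(entry["orientation"])))
    return ExperimentDesign(
        experiment_label=str(data.get("experiment_label", "")), replicates=tuple(reps)
    )


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "experiment_label": design.experiment_label,
                "replicates": [
                    {"id": rid, "orientation": orient}
                    for rid, orient in design.replicates
                ],
            },
            fh,
            sort_keys=False,
        )


def with_orientations(design: ExperimentDesign, orientation: str) -> ExperimentDesign:
    """Same replicate ids, all given the one orientation (testing helper)."""
    return replace(
        design,
        replicates=tuple((rid, orientation) for rid, _ in design.replicates),
    )
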