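"""Gene-set over-representation analysis.

Hypergeometric upper-tail p-values with the three published filters:
p < 0.01 (strict), observed count >= 3, and enrichment factor > 1.5
(strict), where the enrichment factor is observed / expected and
expected = query_size * set_size / background_size. Term clustering is a
single-linkage closure over Jaccard similarity of member genes — a
documented approximation of kappa-based membership clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from silacpipe.io_formats import GeneSet, PipelineConfig, SchemaError


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    observed_count: int
    query_size: int
    set_size_in_background: int
    background_size: int
    expected_count: float
    enrichment_factor: float
    p_value: float
    passes_filters: bool
    member_genes: frozenset[str]  # query genes in the set; feeds clustering


def hypergeom_upper_tail(
    observed: int, query_size: int, set_size: int, background_size: int
) -> float:
    """P(X >= observed) for X ~ Hypergeometric(N=background, K=set, n=query)."""
    if not (0 <= observed <= min(query_size, set_size) <= background_size):
        raise SchemaError(
            "inconsistent sizes: need 0 <= observed <= min(query, set) <= background, "
            f"got observed={observed}, query={query_size}, set={set_size}, "
            f"background={background_size}"
        )
    if max(query_size, set_size) > background_size:
        raise SchemaError("query and set sizes cannot exceed the background size")
    if observed == 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, background_size, set_size, query_size))


def enrich(
    query: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background: Iterable[str],
    config: PipelineConfig | None = None,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each gene set against ``background``.

    Gene sets are intersected with the background before counting; sets
    with an empty background intersection are dropped. Results come back
    sorted by ascending p-value, ties broken by set name.
    """
    config = config or PipelineConfig()
    bg = {g.upper() for g in background}
    if not bg:
        raise SchemaError("empty background")
    q = {g.upper() for g in query}
    if not q <= bg:
        missing = sorted(q - bg)[:5]
        raise SchemaError(f"query genes not in background, e.g. {missing}")
    results: list[EnrichmentResult] = []
    for gs in gene_sets:
        set_in_bg = gs.genes & bg
        if not set_in_bg:
            continue
        members = q & set_in_bg
        observed = len(members)
        expected = len(q) * len(set_in_bg) / len(bg)
        factor = observed / expected if expected > 0 else float("nan")
        p = hypergeom_upper_tail(observed, len(q), len(set_in_bg), len(bg))
        results.append(
            EnrichmentResult(
                set_name=gs.set_name,
                observed_count=observed,
                query_size=len(q),
                set_size_in_background=len(set_in_bg),
                background_size=len(bg),
                expected_count=expected,
                enrichment_factor=factor,
                p_value=p,
                passes_filters=(
                    p < config.enrich_p_max
                    and observed >= config.enrich_min_count
                    and factor > config.enrich_min_factor
                ),
                member_genes=frozenset(members),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def cluster_terms(
    results: Sequence[EnrichmentResult], similarity_threshold: float = 0.5
) -> list[list[EnrichmentResult]]:
    """Single-linkage clusters over pairwise Jaccard similarity of member
    genes; each cluster is ordered (and thus labeled) by its lowest-p term."""
    n = len(results)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _jaccard(results[i].member_genes, results[j].member_genes) >= similarity_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[EnrichmentResult]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(results[i])
    clusters = [
        sorted(members, key=lambda r: (r.p_value, r.set_name))
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: (c[0].p_value, c[0].set_name))
    return clusters


ENRICHMENT_COLUMNS = [
    "set_name",
    "observed_count",
    "query_size",
    "set_size_in_background",
    "background_size",
    "expected_count",
    "enrichment_factor",
    "p_value",
    "passes_filters",
]


def write_enrichment_table(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.set_name,
                        str(r.observed_count),
                        str(r.query_size),
                        str(r.set_size_in_background),
                        str(r.background_size),
                        repr(r.expected_count),
                        repr(r.enrichment_factor),
                        repr(r.p_value),
                        "1" if r.passes_filters else "0",
                    ]
                )
                + "\n"
            )
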