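"""Breadth-first search for common cis-regulatory modules in a gene battery.

A module is an *ordered* tuple of oriented TF-family elements, e.g.
``+NFKB__-CREB__-SP1F``.  The search enumerates tuples over the oriented
keys that are individually common in the battery, pruning on the
anti-monotone raw-presence support, and declares a module common when
the number of genes whose minimal instance span falls within the
half-to-double band of the average span reaches ``ceil(delta * N)``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .profiles import (
    GeneProfile,
    gene_min_instance,
    oriented_key,
    split_oriented_key,
)

__all__ = [
    "CRM",
    "SearchConfig",
    "required_support",
    "common_oriented_tfbs",
    "evaluate_module",
    "search_common_crms",
    "crm_label",
    "parse_label",
    "write_crm_report",
    "read_crm_report",
]

LABEL_SEP = "__"


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the common-CRM search."""

    delta: float = 0.7
    min_module_size: int = 2
    max_module_size: int = 4
    length_band: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        if not 1 <= self.min_module_size <= self.max_module_size:
            raise ValueError("require 1 <= min_module_size <= max_module_size")
        lower, upper = self.length_band
        if not (0 <= lower < 1 < upper):
            raise ValueError(f"length band must satisfy 0 <= lower < 1 < upper, got {self.length_band}")


@dataclass
class CRM:
    """A candidate/common module with its per-battery evaluation."""

    elements: tuple[tuple[str, str], ...]
    support_genes: tuple[str, ...]
    raw_support: tuple[str, ...]
    avg_len: float
    min_len: int
    max_len: int
    common_level: float
    is_common: bool
    p_value: float | None = None

    @property
    def label(self) -> str:
        return crm_label(self.elements)

    @property
    def size(self) -> int:
        return len(self.elements)


def required_support(n_genes: int, delta: float) -> int:
    """Minimum supporting genes: the common level rounded up, ceil(delta*N)."""
    if n_genes < 1:
        raise ValueError(f"battery size must be >= 1, got {n_genes}")
    if not 0 < delta <= 1:
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    return math.ceil(delta * n_genes)


def crm_label(elements: Sequence[tuple[str, str]]) -> str:
    """Canonical label: oriented keys joined by '__'."""
    return LABEL_SEP.join(oriented_key(f, o) for f, o in elements)


def parse_label(label: str) -> tuple[tuple[str, str], ...]:
    """Inverse of :func:`crm_label`."""
    if not label:
        raise ValueError("empty CRM label")
    return tuple(split_oriented_key(part) for part in label.split(LABEL_SEP))


def common_oriented_tfbs(
    genes: Sequence[GeneProfile], config: SearchConfig
) -> list[str]:
    """Oriented keys present (gene-level heuristic) in >= ceil(delta*N) genes."""
    if not genes:
        raise ValueError("battery must contain at least one gene")
    need = required_support(len(genes), config.delta)
    counts: dict[str, int] = {}
    for gene in genes:
        keys = set()
        for prom in gene.promoters:
            keys.update(prom.index)
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
    return sorted(k for k, c in counts.items() if c >= need)


def evaluate_module(
    elements: Sequence[tuple[str, str]],
    genes: Sequence[GeneProfile],
    config: SearchConfig,
) -> CRM:
    """Evaluate one ordered module against a battery.

    Per-gene minimal spans are collected with the alternative-promoter
    heuristic; the average/min/max lengths are computed once over all
    genes with any instance, then the half-to-double band against the
    average determines the supporting genes and the common flag.
    """
    spans: dict[str, int] = {}
    for gene in genes:
        present, span = gene_min_instance(gene, elements)
        if present:
            spans[gene.gene_id] = span  # type: ignore[assignment]
    raw = tuple(sorted(spans))
    if spans:
        values = list(spans.values())
        avg = sum(values) / len(values)
        lo, hi = config.length_band
        support = tuple(
            gid for gid in raw if lo * avg <= spans[gid] <= hi * avg
        )
        min_len, max_len = min(values), max(values)
    else:
        avg = 0.0
        support = ()
        min_len = max_len = 0
    n = len(genes)
    level = len(support) / n
    return CRM(
        elements=tuple(elements),
        support_genes=support,
        raw_support=raw,
        avg_len=avg,
        min_len=min_len,
        max_len=max_len,
        common_level=level,
        is_common=len(support) >= required_support(n, config.delta),
    )


def _raw_presence(
    elements: Sequence[tuple[str, str]],
    genes: Sequence[GeneProfile],
    candidates: frozenset[int] | None = None,
) -> frozenset[int]:
    """Indices of genes with heuristic raw presence, optionally restricted."""
    pool = range(len(genes)) if candidates is None else candidates
    return frozenset(i for i in pool if gene_min_instance(genes[i], elements)[0])


def search_common_crms(
    genes: Sequence[GeneProfile], config: SearchConfig = SearchConfig()
) -> list[CRM]:
    """All common modules of sizes min..max_module_size in the battery.

    Breadth-first over ordered tuples (repeats allowed) of the common
    oriented TFBSs.  A tuple is extended only while its *raw* presence
    support meets the required count — sound because raw presence is
    anti-monotone under extension — while the common flag additionally
    applies the length band.
    """
    if not genes:
        raise ValueError("battery must contain at least one gene")
    need = required_support(len(genes), config.delta)
    alphabet = [split_oriented_key(k) for k in common_oriented_tfbs(genes, config)]
    results: list[CRM] = []
    all_genes = frozenset(range(len(genes)))
    frontier: list[tuple[tuple[tuple[str, str], ...], frozenset[int]]] = [((), all_genes)]
    for size in range(1, config.max_module_size + 1):
        next_frontier: list[tuple[tuple[tuple[str, str], ...], frozenset[int]]] = []
        for stem, stem_carriers in frontier:
            for element in alphabet:
                candidate = stem + (element,)
                # raw presence of an extension is a subset of the stem's
                carriers = _raw_presence(candidate, genes, stem_carriers)
                if len(carriers) < need:
                    continue
                next_frontier.append((candidate, carriers))
                if size >= config.min_module_size:
                    crm = evaluate_module(candidate, genes, config)
                    if crm.is_common:
                        results.append(crm)
        frontier = next_frontier
        if not frontier:
            break
    results.sort(key=lambda c: (c.size, c.label))
    return results


# ---------------------------------------------------------------------------
# report IO
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "label", "size", "avg_len", "min_len", "max_len", "common_level",
    "support_genes", "raw_support", "p_value",
)


def write_crm_report(path, crms: Iterable[CRM]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for crm in crms:
            writer.writerow([
                crm.label,
                crm.size,
                f"{crm.avg_len:.2f}",
                crm.min_len,
                crm.max_len,
                f"{crm.common_level:.4f}",
                ",".join(crm.support_genes),
                ",".join(crm.raw_support),
                "" if crm.p_value is None else f"{crm.p_value:.6g}",
            ])


def read_crm_report(path) -> list[CRM]:
    crms = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            support = tuple(row["support_genes"].split(",")) if row["support_genes"] else ()
            raw = tuple(row["raw_support"].split(",")) if row["raw_support"] else ()
            crms.append(CRM(
                elements=parse_label(row["label"]),
                support_genes=support,
                raw_support=raw,
                avg_len=float(row["avg_len"]),
                min_len=int(row["min_len"]),
                max_len=int(row["max_len"]),
                common_level=float(row["common_level"]),
                is_common=True,
                p_value=float(row["p_value"]) if row["p_value"] else None,
            ))
    return crms
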