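"""Critical-TF inference from significant CRMs and regulatory edge export."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .batteries import Battery
from .crm_search import CRM

__all__ = [
    "TFReport",
    "decompose_crms",
    "critical_tfs",
    "regulatory_edges",
    "write_tf_report",
    "write_edge_list",
    "write_gml",
]


@dataclass(frozen=True)
class TFReport:
    factor_id: str
    batteries: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.batteries)


def decompose_crms(crms: Iterable[CRM]) -> list[str]:
    """Union of element factors, orientation stripped, deduplicated, sorted."""
    factors = {factor for crm in crms for factor, _ in crm.elements}
    return sorted(factors)


def critical_tfs(
    battery_factors: Mapping[str, Iterable[str]], min_batteries: int = 3
) -> list[TFReport]:
    """Factors appearing in >= ``min_batteries`` batteries.

    ``battery_factors`` maps battery_id -> factor set (one vote per
    battery, however many CRMs the factor occurs in).  Output sorted by
    descending battery count then factor name.
    """
    if not battery_factors:
        raise ValueError("need at least one battery")
    occurrences: dict[str, set[str]] = {}
    for battery_id, factors in battery_factors.items():
        for factor in set(factors):
            occurrences.setdefault(factor, set()).add(battery_id)
    reports = [
        TFReport(factor_id=f, batteries=tuple(sorted(bats)))
        for f, bats in occurrences.items()
        if len(bats) >= min_batteries
    ]
    reports.sort(key=lambda r: (-r.count, r.factor_id))
    return reports


def regulatory_edges(
    batteries: Sequence[Battery],
    significant_crms: Mapping[str, Sequence[CRM]],
) -> list[tuple[str, str, str, str]]:
    """(factor, gene, pattern, pathway) edges: each factor appearing in a
    battery's significant CRMs is linked to every gene of that battery."""
    edges = []
    for battery in batteries:
        crms = significant_crms.get(battery.battery_id, ())
        for factor in decompose_crms(crms):
            for gene in battery.genes:
                edges.append((factor, gene, battery.pattern, battery.pathway))
    edges.sort()
    return edges


def write_tf_report(path, reports: Iterable[TFReport]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["factor_id", "n_batteries", "batteries"])
        for rep in reports:
            writer.writerow([rep.factor_id, rep.count, ",".join(rep.batteries)])


def write_edge_list(path, edges: Iterable[tuple[str, str, str, str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["factor_id", "gene_id", "pattern", "pathway"])
        writer.writerows(edges)


def write_gml(path, edges: Sequence[tuple[str, str, str, str]]) -> None:
    """Minimal GML export of the factor -> gene graph for network viewers."""
    factors = sorted({e[0] for e in edges})
    genes = sorted({e[1] for e in edges})
    ids = {name: i for i, name in enumerate(factors + genes)}
    with open(path, "w") as fh:
        fh.write("graph [\n  directed 1\n")
        for name in factors:
            fh.write(f'  node [ id {ids[name]} label "{name}" kind "factor" ]\n')
        for name in genes:
            fh.write(f'  node [ id {ids[name]} label "{name}" kind "gene" ]\n')
        for factor, gene, pattern, pathway in edges:
            fh.write(
                f'  edge [ source {ids[factor]} target {ids[gene]}'
                f' pattern "{pattern}" pathway "{pathway}" ]\n'
            )
        fh.write("]\n")
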