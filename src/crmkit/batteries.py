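"""Gene batteries: intersections of expression patterns with enriched pathways.

A battery is the overlap of one temporal expression pattern with one
pathway whose enrichment in that pattern (hypergeometric upper tail
against the annotation universe) passes ``alpha``; an optional curated
allowlist can further restrict the admissible pathways.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .significance import hypergeom_upper_pvalue

__all__ = [
    "ExpressionPattern",
    "PathwaySet",
    "Battery",
    "pathway_enrichment",
    "build_batteries",
    "read_gmt",
    "write_gmt",
    "read_pattern_assignments",
    "write_pattern_assignments",
    "write_battery_table",
    "read_battery_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionPattern:
    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label or not self.genes:
            raise ValueError("expression pattern needs a label and >= 1 gene")


@dataclass(frozen=True)
class PathwaySet:
    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name or not self.genes:
            raise ValueError("pathway needs a name and >= 1 member gene")


@dataclass(frozen=True)
class Battery:
    battery_id: str
    pattern: str
    pathway: str
    genes: tuple[str, ...]
    p_value: float

    @property
    def size(self) -> int:
        return len(self.genes)


def pathway_enrichment(
    pattern_genes: Iterable[str],
    pathways: Sequence[PathwaySet],
    universe: Iterable[str],
) -> list[tuple[PathwaySet, int, float]]:
    """Per-pathway ``(pathway, overlap, p)`` rows sorted by ascending p.

    p is the hypergeometric upper tail with population = universe,
    successes = pathway ∩ universe, draws = pattern, hits = overlap.
    Pathways with no gene in the universe are skipped with a log note.
    """
    universe_set = set(universe)
    pattern_set = set(pattern_genes)
    outside = pattern_set - universe_set
    if outside:
        raise ValueError(
            f"{len(outside)} pattern gene(s) outside the universe, e.g. {sorted(outside)[:3]}"
        )
    rows = []
    for pw in pathways:
        members = pw.genes & universe_set
        if not members:
            logger.info("pathway %s has no gene in the universe; skipped", pw.name)
            continue
        overlap = len(pattern_set & members)
        p = hypergeom_upper_pvalue(
            len(universe_set), len(members), len(pattern_set), overlap
        )
        rows.append((pw, overlap, p))
    rows.sort(key=lambda r: (r[2], r[0].name))
    return rows


def build_batteries(
    patterns: Sequence[ExpressionPattern],
    pathways: Sequence[PathwaySet],
    universe: Iterable[str],
    alpha: float = 0.05,
    allowlist: Iterable[str] | None = None,
    min_size: int = 4,
) -> list[Battery]:
    """Emit a battery per (pattern, pathway) pair enriched at p < alpha.

    ``allowlist`` restricts pathways to a curated subset; undersized
    batteries are dropped with a warning.
    """
    allowed = None if allowlist is None else set(allowlist)
    universe_set = set(universe)
    batteries = []
    for pattern in patterns:
        for pw, overlap, p in pathway_enrichment(pattern.genes, pathways, universe_set):
            if p >= alpha:
                continue
            if allowed is not None and pw.name not in allowed:
                continue
            genes = tuple(sorted(pattern.genes & pw.genes & universe_set))
            if len(genes) < min_size:
                logger.warning(
                    "battery %s|%s has %d genes (< %d); dropped",
                    pattern.label, pw.name, len(genes), min_size,
                )
                continue
            batteries.append(Battery(
                battery_id=f"{pattern.label}|{pw.name}",
                pattern=pattern.label,
                pathway=pw.name,
                genes=genes,
                p_value=p,
            ))
    return batteries


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[PathwaySet]:
    """Read tab-separated GMT records: name, description, member genes."""
    pathways = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT record needs >= 3 fields: {line!r}")
            name, description, *genes = parts
            genes = [g for g in genes if g]
            pathways.append(PathwaySet(name=name, description=description,
                                       genes=frozenset(genes)))
    return pathways


def write_gmt(path, pathways: Iterable[PathwaySet]) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.name, pw.description, *sorted(pw.genes)]) + "\n")


def read_pattern_assignments(path) -> list[ExpressionPattern]:
    """Read a two-column TSV (gene_id, pattern) into patterns."""
    members: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for line in csv.reader(fh, delimiter="\t"):
            if not line or line[0].startswith("#") or line[0] == "gene_id":
                continue
            gene_id, label = line[0], line[1]
            members.setdefault(label, set()).add(gene_id)
    return [
        ExpressionPattern(label=label, genes=frozenset(genes))
        for label, genes in sorted(members.items())
    ]


def write_pattern_assignments(path, patterns: Iterable[ExpressionPattern]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "pattern"])
        for pattern in patterns:
            for gene in sorted(pattern.genes):
                writer.writerow([gene, pattern.label])


def write_battery_table(path, batteries: Iterable[Battery]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["battery_id", "pattern", "pathway", "size", "p_value", "genes"])
        for bat in batteries:
            writer.writerow([
                bat.battery_id, bat.pattern, bat.pathway, bat.size,
                f"{bat.p_value:.6g}", ",".join(bat.genes),
            ])


def read_battery_table(path) -> list[Battery]:
    batteries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            batteries.append(Battery(
                battery_id=row["battery_id"],
                pattern=row["pattern"],
                pathway=row["pathway"],
                genes=tuple(row["genes"].split(",")) if row["genes"] else (),
                p_value=float(row["p_value"]),
            ))
    return batteries
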