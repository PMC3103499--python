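"""Promoter binding-site profiles and CRM-instance queries.

A promoter is represented not by its sequence but by a position-sorted
list of oriented transcription-factor binding sites, indexed by oriented
key (``"+ETSF"``, ``"-PAX6"``).  A gene holds one or more alternative
promoter profiles; a module counts as present for the gene if it is
present on *any* of its promoters, and the gene-level instance length is
the minimum over all instances on all promoters.

Coordinates are signed integers relative to the transcription start
site (negative = upstream), intervals inclusive on both ends.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ORIENTATIONS",
    "BindingSite",
    "PromoterProfile",
    "GeneProfile",
    "CRMInstance",
    "MalformedRecordError",
    "oriented_key",
    "split_oriented_key",
    "build_promoter_profile",
    "has_oriented_site",
    "find_min_instance",
    "gene_min_instance",
    "battery_presence_vector",
    "read_site_table",
    "write_site_table",
    "genes_from_sites",
    "gff_to_tss_relative",
]

ORIENTATIONS = ("+", "-")

SITE_TABLE_COLUMNS = ("gene_id", "promoter_id", "factor_id", "start", "end", "strand")


class MalformedRecordError(ValueError):
    """Raised when an input record violates basic structural constraints."""


@dataclass(frozen=True, order=True)
class BindingSite:
    """One oriented TF-family match on a promoter.

    ``start``/``end`` are inclusive bp relative to the TSS.
    """

    start: int
    end: int
    factor_id: str
    orientation: str

    def __post_init__(self) -> None:
        if not self.factor_id:
            raise MalformedRecordError("binding site with empty factor_id")
        if self.orientation not in ORIENTATIONS:
            raise MalformedRecordError(
                f"orientation must be '+' or '-', got {self.orientation!r}"
            )
        if self.end < self.start:
            raise MalformedRecordError(
                f"site {self.factor_id} has end < start ({self.end} < {self.start})"
            )

    @property
    def key(self) -> str:
        return self.orientation + self.factor_id

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def oriented_key(factor_id: str, orientation: str) -> str:
    """Build the oriented lookup key, e.g. ``("ETSF", "+") -> "+ETSF"``."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")
    if not factor_id:
        raise ValueError("empty factor_id")
    return orientation + factor_id


def split_oriented_key(key: str) -> tuple[str, str]:
    """Inverse of :func:`oriented_key`: ``"+ETSF" -> ("ETSF", "+")``."""
    if len(key) < 2 or key[0] not in ORIENTATIONS:
        raise ValueError(f"malformed oriented key {key!r}")
    return key[1:], key[0]


@dataclass
class PromoterProfile:
    """Position-sorted site list with an oriented-key index."""

    promoter_id: str
    gene_id: str
    sites: tuple[BindingSite, ...]
    index: dict[str, list[int]] = field(default_factory=dict)

    def rebuild_index(self) -> dict[str, list[int]]:
        index: dict[str, list[int]] = {}
        for site in self.sites:
            index.setdefault(site.key, []).append(site.start)
        for positions in index.values():
            positions.sort()
        return index


@dataclass
class GeneProfile:
    """A gene with K_i >= 1 alternative promoter profiles."""

    gene_id: str
    promoters: tuple[PromoterProfile, ...]

    def __post_init__(self) -> None:
        if not self.promoters:
            raise MalformedRecordError(f"gene {self.gene_id} has no promoters")
        for prom in self.promoters:
            if prom.gene_id != self.gene_id:
                raise MalformedRecordError(
                    f"promoter {prom.promoter_id} carries gene_id {prom.gene_id!r},"
                    f" expected {self.gene_id!r}"
                )
        ids = [p.promoter_id for p in self.promoters]
        if len(set(ids)) != len(ids):
            raise MalformedRecordError(
                f"duplicate promoter_ids within gene {self.gene_id}"
            )


@dataclass(frozen=True)
class CRMInstance:
    """A concrete ordered, non-overlapping realisation of a module."""

    gene_id: str
    promoter_id: str
    site_refs: tuple[int, ...]
    span: int


def build_promoter_profile(
    gene_id: str, promoter_id: str, sites: Iterable[BindingSite]
) -> PromoterProfile:
    """Sort sites, drop exact duplicates and build the oriented-key index.

    Deterministic for a given input multiset; raises
    :class:`MalformedRecordError` (naming the promoter) for sites with
    ``end < start`` constructed by bypassing validation.
    """
    unique = sorted(set(sites))
    for site in unique:
        if site.end < site.start:  # defensive: dataclass validation normally catches
            raise MalformedRecordError(
                f"promoter {promoter_id}: site {site.factor_id} has end < start"
            )
    profile = PromoterProfile(
        promoter_id=promoter_id, gene_id=gene_id, sites=tuple(unique)
    )
    profile.index = profile.rebuild_index()
    return profile


def has_oriented_site(profile: PromoterProfile, key: str) -> bool:
    """True iff the promoter has >= 1 site with the keyed factor+orientation."""
    split_oriented_key(key)  # validates
    return key in profile.index


def _elements_to_keys(elements: Sequence[tuple[str, str]]) -> list[str]:
    if not elements:
        raise ValueError("module elements must be non-empty")
    return [oriented_key(factor, orient) for factor, orient in elements]


def find_min_instance(
    profile: PromoterProfile, elements: Sequence[tuple[str, str]]
) -> CRMInstance | None:
    """Minimum-span ordered non-overlapping instance of ``elements``, if any.

    For every candidate first site, the remaining elements are completed
    greedily by the feasible site with the smallest end (which provably
    minimises the final end, hence the span, for that first site); the
    overall minimum-span instance is returned, ties broken by the most
    upstream first site.  Successive sites must satisfy
    ``next.start > prev.end`` (strict non-overlap).
    """
    keys = _elements_to_keys(elements)
    sites = profile.sites
    by_key: dict[str, list[int]] = {}
    for i, site in enumerate(sites):
        by_key.setdefault(site.key, []).append(i)
    if any(k not in by_key for k in keys):
        return None

    best: tuple[int, int, tuple[int, ...]] | None = None  # (span, first_start, refs)
    for first in by_key[keys[0]]:
        refs = [first]
        prev_end = sites[first].end
        feasible = True
        for key in keys[1:]:
            candidates = [
                i for i in by_key[key] if sites[i].start > prev_end and i not in refs
            ]
            if not candidates:
                feasible = False
                break
            nxt = min(candidates, key=lambda i: (sites[i].end, sites[i].start))
            refs.append(nxt)
            prev_end = sites[nxt].end
        if not feasible:
            continue
        span = sites[refs[-1]].end - sites[first].start + 1
        cand = (span, sites[first].start, tuple(refs))
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    span, _, refs = best
    return CRMInstance(
        gene_id=profile.gene_id,
        promoter_id=profile.promoter_id,
        site_refs=refs,
        span=span,
    )


def gene_min_instance(
    gene: GeneProfile, elements: Sequence[tuple[str, str]]
) -> tuple[bool, int | None]:
    """Alternative-promoter heuristic: present on any promoter => present.

    Returns ``(present, span)`` with ``span`` the minimum over all
    instances on all promoters (ties resolved towards the
    lexicographically smallest promoter_id, which does not affect the
    returned numbers).
    """
    best_span: int | None = None
    for prom in sorted(gene.promoters, key=lambda p: p.promoter_id):
        inst = find_min_instance(prom, elements)
        if inst is not None and (best_span is None or inst.span < best_span):
            best_span = inst.span
    return (best_span is not None, best_span)


def battery_presence_vector(
    genes: Sequence[GeneProfile], elements: Sequence[tuple[str, str]]
) -> list[tuple[str, bool, int | None]]:
    """Per-gene ``(gene_id, present, span)`` rows, input order preserved."""
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_ids in battery")
    out = []
    for gene in genes:
        present, span = gene_min_instance(gene, elements)
        out.append((gene.gene_id, present, span))
    return out


# ---------------------------------------------------------------------------
# site-table IO
# ---------------------------------------------------------------------------

def read_site_table(path) -> list[tuple[str, str, BindingSite]]:
    """Read a TSV site table into ``(gene_id, promoter_id, site)`` rows.

    Expected columns: gene_id, promoter_id, factor_id, start, end,
    strand.  Lines starting with ``#`` are comments; a header row is
    detected and skipped.
    """
    rows: list[tuple[str, str, BindingSite]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for line in reader:
            if not line or line[0].startswith("#"):
                continue
            if line[0] == "gene_id":
                continue
            if len(line) < 6:
                raise MalformedRecordError(f"short site-table row: {line!r}")
            gene_id, promoter_id, factor_id, start, end, strand = line[:6]
            try:
                site = BindingSite(
                    start=int(start),
                    end=int(end),
                    factor_id=factor_id,
                    orientation=strand,
                )
            except MalformedRecordError as exc:
                raise MalformedRecordError(f"promoter {promoter_id}: {exc}") from exc
            rows.append((gene_id, promoter_id, site))
    return rows


def write_site_table(path, rows: Iterable[tuple[str, str, BindingSite]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_TABLE_COLUMNS)
        for gene_id, promoter_id, site in rows:
            writer.writerow(
                [gene_id, promoter_id, site.factor_id, site.start, site.end,
                 site.orientation]
            )


def genes_from_sites(
    rows: Iterable[tuple[str, str, BindingSite]],
    promoters_per_gene: dict[str, list[str]] | None = None,
) -> list[GeneProfile]:
    """Group site rows into GeneProfiles (one per gene, sorted by gene_id).

    ``promoters_per_gene`` optionally declares promoters that must exist
    even when they carry no sites (empty promoters are otherwise
    invisible in a site table).
    """
    grouped: dict[str, dict[str, list[BindingSite]]] = {}
    for gene_id, promoter_id, site in rows:
        grouped.setdefault(gene_id, {}).setdefault(promoter_id, []).append(site)
    if promoters_per_gene:
        for gene_id, prom_ids in promoters_per_gene.items():
            for pid in prom_ids:
                grouped.setdefault(gene_id, {}).setdefault(pid, [])
    genes = []
    for gene_id in sorted(grouped):
        promoters = tuple(
            build_promoter_profile(gene_id, pid, grouped[gene_id][pid])
            for pid in sorted(grouped[gene_id])
        )
        genes.append(GeneProfile(gene_id=gene_id, promoters=promoters))
    return genes


def gff_to_tss_relative(
    gff_start: int, gff_end: int, tss: int, gene_strand: str
) -> tuple[int, int]:
    """Convert half-open 0-based GFF-style coordinates to inclusive TSS-relative.

    ``tss`` is the 0-based genomic position of the transcription start
    site; for minus-strand genes the axis is flipped so that negative
    still means upstream.
    """
    if gene_strand == "+":
        start = gff_start - tss
        end = gff_end - 1 - tss
    elif gene_strand == "-":
        start = tss - (gff_end - 1)
        end = tss - gff_start
    else:
        raise ValueError(f"gene strand must be '+' or '-', got {gene_strand!r}")
    return start, end
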