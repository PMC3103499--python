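"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's search/matching code paths:
instance matching is checked by exhaustive enumeration of ordered
non-overlapping site selections, and the alternative-promoter heuristic
by evaluating every promoter combination of a gene set.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pytest

from crmkit.profiles import (
    BindingSite,
    GeneProfile,
    PromoterProfile,
    build_promoter_profile,
)


def site(factor: str, start: int, end: int | None = None, orient: str = "+") -> BindingSite:
    if end is None:
        end = start + 11  # default 12 bp nominal width
    return BindingSite(start=start, end=end, factor_id=factor, orientation=orient)


def make_profile(gene_id: str, promoter_id: str, sites: Sequence[BindingSite]) -> PromoterProfile:
    return build_promoter_profile(gene_id, promoter_id, sites)


def make_gene(gene_id: str, *promoter_sites: Sequence[BindingSite]) -> GeneProfile:
    promoters = tuple(
        build_promoter_profile(gene_id, f"{gene_id}.P{i + 1}", s)
        for i, s in enumerate(promoter_sites)
    )
    return GeneProfile(gene_id=gene_id, promoters=promoters)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_instances(
    profile: PromoterProfile, elements: Sequence[tuple[str, str]]
) -> list[tuple[int, tuple[int, ...]]]:
    """All (span, site_refs) for ordered non-overlapping selections matching
    ``elements``, by exhaustive enumeration over index combinations."""
    sites = profile.sites
    keys = [o + f for f, o in elements]
    out = []
    for combo in itertools.combinations(range(len(sites)), len(elements)):
        if any(sites[i].key != k for i, k in zip(combo, keys)):
            continue
        ok = all(
            sites[b].start > sites[a].end for a, b in zip(combo, combo[1:])
        )
        if ok:
            span = sites[combo[-1]].end - sites[combo[0]].start + 1
            out.append((span, combo))
    return out


def brute_min_span(
    profile: PromoterProfile, elements: Sequence[tuple[str, str]]
) -> int | None:
    spans = [s for s, _ in brute_instances(profile, elements)]
    return min(spans) if spans else None


def brute_gene_min_span(
    gene: GeneProfile, elements: Sequence[tuple[str, str]]
) -> int | None:
    spans = [
        s for prom in gene.promoters
        for s in [brute_min_span(prom, elements)] if s is not None
    ]
    return min(spans) if spans else None


def brute_common_modules(
    genes: Sequence[GeneProfile],
    vocabulary: Sequence[tuple[str, str]],
    delta: float,
    min_size: int,
    max_size: int,
) -> set[str]:
    """Presence-based common modules by unpruned enumeration of all ordered
    tuples over ``vocabulary`` (brute-force reference for the search)."""
    need = math.ceil(delta * len(genes))
    found = set()
    for size in range(min_size, max_size + 1):
        for tup in itertools.product(vocabulary, repeat=size):
            count = sum(
                1 for g in genes if brute_gene_min_span(g, tup) is not None
            )
            if count >= need:
                found.add("__".join(o + f for f, o in tup))
    return found


def brute_combination_union(
    genes: Sequence[GeneProfile],
    vocabulary: Sequence[tuple[str, str]],
    delta: float,
    min_size: int,
    max_size: int,
) -> set[str]:
    """Union of presence-based common-module sets over every promoter
    combination (one promoter chosen per gene) — the K^N brute force the
    any-promoter heuristic replaces."""
    need = math.ceil(delta * len(genes))
    found = set()
    choices = [range(len(g.promoters)) for g in genes]
    for size in range(min_size, max_size + 1):
        for tup in itertools.product(vocabulary, repeat=size):
            label = "__".join(o + f for f, o in tup)
            if label in found:
                continue
            for combo in itertools.product(*choices):
                count = sum(
                    1 for g, c in zip(genes, combo)
                    if brute_min_span(g.promoters[c], tup) is not None
                )
                if count >= need:
                    found.add(label)
                    break
    return found


def random_profile(
    rng: np.random.Generator,
    gene_id: str = "G1",
    promoter_id: str = "G1.P1",
    n_sites: int = 10,
    vocabulary: Sequence[str] = ("A", "B", "C"),
    region: tuple[int, int] = (-500, 100),
    width_range: tuple[int, int] = (6, 18),
) -> PromoterProfile:
    sites = []
    for _ in range(n_sites):
        start = int(rng.integers(region[0], region[1] - width_range[1]))
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        sites.append(BindingSite(
            start=start, end=start + width - 1,
            factor_id=str(rng.choice(vocabulary)),
            orientation="+" if rng.random() < 0.5 else "-",
        ))
    return build_promoter_profile(gene_id, promoter_id, sites)


def random_gene(
    rng: np.random.Generator,
    gene_id: str,
    max_promoters: int = 3,
    n_sites: int = 6,
    vocabulary: Sequence[str] = ("A", "B", "C"),
) -> GeneProfile:
    k = int(rng.integers(1, max_promoters + 1))
    promoters = tuple(
        random_profile(rng, gene_id, f"{gene_id}.P{j + 1}",
                       n_sites=int(rng.integers(0, n_sites + 1)),
                       vocabulary=vocabulary)
        for j in range(k)
    )
    return GeneProfile(gene_id=gene_id, promoters=promoters)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
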