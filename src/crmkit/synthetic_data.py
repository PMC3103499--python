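"""Seeded synthetic promoter profiles, backgrounds and battery fixtures.

Every generator takes its randomness from a single scenario seed and
records a :class:`TruthRecord` of what was planted where, so downstream
stages (instance matching, search, scoring, TF inference) can be tested
end-to-end against known ground truth without any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .batteries import (
    ExpressionPattern,
    PathwaySet,
    write_gmt,
    write_pattern_assignments,
)
from .crm_search import crm_label
from .profiles import (
    BindingSite,
    GeneProfile,
    build_promoter_profile,
    write_site_table,
)
from .significance import BackgroundSet

__all__ = [
    "PlantedModuleSpec",
    "ScenarioConfig",
    "ExpressionFixtureConfig",
    "TruthRecord",
    "generate_background",
    "generate_battery",
    "generate_expression_fixture",
    "generate_scenario",
]

DEFAULT_VOCABULARY = (
    "NFKB", "CREB", "SP1F", "ETSF", "GATA", "HEAT", "AP4R", "E2FF",
    "IRFF", "STAT", "PAX6", "MAZF",
)


@dataclass(frozen=True)
class PlantedModuleSpec:
    """One module to plant in a battery: ordered oriented elements plus
    the carrier fraction and inter-site gap distribution (uniform ints).

    ``outlier_carriers`` carriers draw gaps from ``outlier_gap_range``
    instead, which lets tests force spans outside the half-to-double
    band of the battery average.
    """

    elements: tuple[tuple[str, str], ...]
    n_genes: int = 8
    fraction: float = 0.75
    gap_range: tuple[int, int] = (5, 40)
    outlier_carriers: int = 0
    outlier_gap_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("planted fraction must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("battery size must be >= 1")
        if self.gap_range[0] < 1 or self.gap_range[0] > self.gap_range[1]:
            raise ValueError("gap_range must satisfy 1 <= lo <= hi")

    @property
    def label(self) -> str:
        return crm_label(self.elements)


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic world; ``seed`` is mandatory."""

    seed: int
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    background_size: int = 1000
    promoters_per_gene: tuple[int, int] = (1, 3)
    decoy_rate: float = 2.0
    region: tuple[int, int] = (-500, 100)
    site_width: int = 12
    leak_rate: float = 0.01
    planted: tuple[PlantedModuleSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.background_size < 1:
            raise ValueError("background_size must be >= 1")
        k_lo, k_hi = self.promoters_per_gene
        if k_lo < 1 or k_lo > k_hi:
            raise ValueError("promoters_per_gene must satisfy 1 <= lo <= hi")
        if not 0 <= self.leak_rate <= 1:
            raise ValueError("leak_rate must be in [0, 1]")


@dataclass
class TruthRecord:
    """Planted structure: module label -> carriers and instance coordinates."""

    battery_carriers: dict[str, list[dict]] = field(default_factory=dict)
    background_carriers: dict[str, list[str]] = field(default_factory=dict)

    def carriers_of(self, label: str) -> list[str]:
        return [c["gene_id"] for c in self.battery_carriers.get(label, [])]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            battery_carriers=data.get("battery_carriers", {}),
            background_carriers=data.get("background_carriers", {}),
        )


def _decoy_sites(
    rng: np.random.Generator,
    config: ScenarioConfig,
    planted: Sequence[BindingSite] = (),
) -> list[BindingSite]:
    """i.i.d. decoys: Poisson count, uniform position, fair-coin strand.

    A decoy exactly coinciding with a planted site of the same factor is
    redrawn so truth records stay unambiguous.
    """
    lo, hi = config.region
    max_start = hi - config.site_width + 1
    taken = {(s.factor_id, s.start, s.end) for s in planted}
    n_sites = int(rng.poisson(config.decoy_rate))
    sites = []
    for _ in range(n_sites):
        factor = str(rng.choice(config.vocabulary))
        orientation = "+" if rng.random() < 0.5 else "-"
        for _attempt in range(100):
            start = int(rng.integers(lo, max_start + 1))
            end = start + config.site_width - 1
            if (factor, start, end) not in taken:
                break
        else:  # pragma: no cover - vanishingly unlikely
            continue
        sites.append(BindingSite(start=start, end=end, factor_id=factor,
                                 orientation=orientation))
    return sites


def _plant_instance(
    rng: np.random.Generator,
    spec: PlantedModuleSpec,
    config: ScenarioConfig,
    gap_range: tuple[int, int],
) -> list[BindingSite]:
    """One ordered, non-overlapping instance placed uniformly in the region."""
    width = config.site_width
    n_el = len(spec.elements)
    gaps = [int(rng.integers(gap_range[0], gap_range[1] + 1)) for _ in range(n_el - 1)]
    span = n_el * width + sum(gaps)
    lo, hi = config.region
    if span > hi - lo + 1:
        raise ValueError(
            f"planted instance span {span} exceeds region {config.region}"
        )
    first = int(rng.integers(lo, hi - span + 2))
    sites = []
    pos = first
    for i, (factor, orientation) in enumerate(spec.elements):
        sites.append(BindingSite(start=pos, end=pos + width - 1,
                                 factor_id=factor, orientation=orientation))
        if i < n_el - 1:
            pos = pos + width + gaps[i]
    return sites


def _make_gene(
    rng: np.random.Generator,
    config: ScenarioConfig,
    gene_id: str,
    planted_sites: Sequence[BindingSite] = (),
    planted_promoter: int | None = None,
) -> tuple[GeneProfile, str | None]:
    """A gene with K_i promoters; planted sites land on one chosen promoter."""
    k_lo, k_hi = config.promoters_per_gene
    k = int(rng.integers(k_lo, k_hi + 1))
    if planted_sites and planted_promoter is None:
        planted_promoter = int(rng.integers(0, k))
    promoters = []
    planted_pid = None
    for j in range(k):
        pid = f"{gene_id}.P{j + 1}"
        extra: Sequence[BindingSite] = ()
        if planted_sites and j == planted_promoter:
            extra = planted_sites
            planted_pid = pid
        decoys = _decoy_sites(rng, config, planted=extra)
        promoters.append(
            build_promoter_profile(gene_id, pid, list(extra) + decoys)
        )
    return GeneProfile(gene_id=gene_id, promoters=tuple(promoters)), planted_pid


def generate_background(
    config: ScenarioConfig,
) -> tuple[BackgroundSet, TruthRecord]:
    """B decoy gene profiles; ``round(leak_rate * B)`` leak carriers per
    planted module additionally receive one planted instance."""
    rng = np.random.default_rng([config.seed, 0xBAC])
    truth = TruthRecord()
    n_leak = round(config.leak_rate * config.background_size)
    leak_map: dict[int, list[PlantedModuleSpec]] = {}
    for spec in config.planted:
        idx = rng.choice(config.background_size, size=n_leak, replace=False)
        truth.background_carriers[spec.label] = []
        for i in idx:
            leak_map.setdefault(int(i), []).append(spec)
    genes = []
    for i in range(config.background_size):
        gene_id = f"BG{i:05d}"
        specs = leak_map.get(i, [])
        planted: list[BindingSite] = []
        for spec in specs:
            planted.extend(_plant_instance(rng, spec, config, spec.gap_range))
            truth.background_carriers[spec.label].append(gene_id)
        gene, _ = _make_gene(rng, config, gene_id, planted_sites=planted)
        genes.append(gene)
    for label in truth.background_carriers:
        truth.background_carriers[label].sort()
    return BackgroundSet(genes=tuple(genes)), truth


def generate_battery(
    config: ScenarioConfig,
    spec: PlantedModuleSpec,
    gene_ids: Sequence[str] | None = None,
    stream: int = 0xBA7,
) -> tuple[list[GeneProfile], TruthRecord]:
    """N gene profiles, ``ceil(fraction * N)`` of which carry one planted
    instance on a randomly chosen alternative promoter; the rest get
    decoys only."""
    rng = np.random.default_rng([config.seed, stream])
    if gene_ids is None:
        gene_ids = [f"G{i:03d}" for i in range(spec.n_genes)]
    elif len(gene_ids) != spec.n_genes:
        raise ValueError("gene_ids length must equal the battery size")
    n_carriers = math.ceil(spec.fraction * spec.n_genes)
    carrier_idx = sorted(
        int(i) for i in rng.choice(spec.n_genes, size=n_carriers, replace=False)
    )
    outliers = set(carrier_idx[: spec.outlier_carriers])
    truth = TruthRecord(battery_carriers={spec.label: []})
    genes = []
    for i, gene_id in enumerate(gene_ids):
        planted: list[BindingSite] = []
        if i in carrier_idx:
            gaps = (
                spec.outlier_gap_range
                if i in outliers and spec.outlier_gap_range is not None
                else spec.gap_range
            )
            planted = _plant_instance(rng, spec, config, gaps)
        gene, planted_pid = _make_gene(rng, config, gene_id, planted_sites=planted)
        genes.append(gene)
        if planted:
            truth.battery_carriers[spec.label].append({
                "gene_id": gene_id,
                "promoter_id": planted_pid,
                "sites": [[s.start, s.end, s.factor_id, s.orientation]
                          for s in planted],
                "span": planted[-1].end - planted[0].start + 1,
                "outlier": i in outliers,
            })
    return genes, truth


@dataclass(frozen=True)
class ExpressionFixtureConfig:
    """Shape of the pattern x pathway fixture that build_batteries must recover."""

    seed: int
    n_batteries: int = 14
    battery_size: int = 8
    pattern_labels: tuple[str, ...] = ("early-up", "middle-up", "late-up", "down")
    fillers_per_pathway: int = 3
    extra_universe: int = 40


def generate_expression_fixture(
    config: ExpressionFixtureConfig,
) -> tuple[list[ExpressionPattern], list[PathwaySet], list[str], dict[str, list[str]]]:
    """Patterns, pathways and universe engineered so that each of the
    ``n_batteries`` configured (pattern, pathway) pairs is enriched while
    every other pair has zero overlap.

    Returns ``(patterns, pathways, universe, truth)`` where truth maps
    the expected battery_id to its gene list.
    """
    pattern_members: dict[str, set[str]] = {lb: set() for lb in config.pattern_labels}
    pathways = []
    truth: dict[str, list[str]] = {}
    universe: list[str] = []
    for i in range(config.n_batteries):
        label = config.pattern_labels[i % len(config.pattern_labels)]
        pw_name = f"PW{i:02d}"
        block = [f"B{i:02d}G{j:02d}" for j in range(config.battery_size)]
        fillers = [f"B{i:02d}F{j:02d}" for j in range(config.fillers_per_pathway)]
        pattern_members[label].update(block)
        pathways.append(PathwaySet(
            name=pw_name,
            description=f"synthetic pathway {i}",
            genes=frozenset(block + fillers),
        ))
        truth[f"{label}|{pw_name}"] = sorted(block)
        universe.extend(block + fillers)
    universe.extend(f"UX{j:03d}" for j in range(config.extra_universe))
    patterns = [
        ExpressionPattern(label=lb, genes=frozenset(members))
        for lb, members in sorted(pattern_members.items())
        if members
    ]
    return patterns, pathways, sorted(universe), truth


def generate_scenario(
    config: ScenarioConfig,
    fixture: ExpressionFixtureConfig,
    out_dir,
) -> dict:
    """Write a complete, coherent input bundle for the full pipeline.

    Emits sites.tsv (universe genes; battery carriers get planted
    instances), background_sites.tsv, patterns.tsv, pathways.gmt,
    universe.txt and truth.json under ``out_dir``.  Planted module specs
    are cycled across the fixture's batteries.
    """
    if not config.planted:
        raise ValueError("scenario needs at least one planted module spec")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patterns, pathways, universe, battery_truth = generate_expression_fixture(fixture)

    truth = TruthRecord()
    rows = []
    battery_modules: dict[str, str] = {}
    battery_gene_ids = {g for genes in battery_truth.values() for g in genes}
    for b_idx, (battery_id, gene_ids) in enumerate(sorted(battery_truth.items())):
        spec = config.planted[b_idx % len(config.planted)]
        spec = PlantedModuleSpec(
            elements=spec.elements,
            n_genes=len(gene_ids),
            fraction=spec.fraction,
            gap_range=spec.gap_range,
        )
        genes, bt_truth = generate_battery(
            config, spec, gene_ids=gene_ids, stream=1000 + b_idx
        )
        battery_modules[battery_id] = spec.label
        truth.battery_carriers.setdefault(spec.label, []).extend(
            bt_truth.battery_carriers[spec.label]
        )
        for gene in genes:
            for prom in gene.promoters:
                rows.extend((gene.gene_id, prom.promoter_id, s) for s in prom.sites)
    # universe genes outside any battery get decoy-only profiles
    rng = np.random.default_rng([config.seed, 0xF1])
    for gene_id in universe:
        if gene_id in battery_gene_ids:
            continue
        gene, _ = _make_gene(rng, config, gene_id)
        for prom in gene.promoters:
            rows.extend((gene.gene_id, prom.promoter_id, s) for s in prom.sites)

    background, bg_truth = generate_background(config)
    truth.background_carriers = bg_truth.background_carriers
    bg_rows = [
        (g.gene_id, p.promoter_id, s)
        for g in background.genes for p in g.promoters for s in p.sites
    ]

    write_site_table(out / "sites.tsv", rows)
    write_site_table(out / "background_sites.tsv", bg_rows)
    write_pattern_assignments(out / "patterns.tsv", patterns)
    write_gmt(out / "pathways.gmt", pathways)
    (out / "universe.txt").write_text("\n".join(universe) + "\n")
    truth.to_json(out / "truth.json")
    manifest = {
        "seed": config.seed,
        "battery_modules": battery_modules,
        "planted_labels": sorted({s.label for s in config.planted}),
        "background_size": config.background_size,
        "leak_rate": config.leak_rate,
        "decoy_rate": config.decoy_rate,
    }
    with open(out / "scenario.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
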