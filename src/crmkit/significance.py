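"""Hypergeometric scoring of common CRMs and randomized threshold calibration.

A module found common in a battery of N genes, n of which support it, is
scored against a background of B genes of which b carry the module
(heuristic raw presence): the p-value is the upper hypergeometric tail
P(X >= n).  Because the appropriate significance cutoff depends
strongly on N, thresholds are calibrated by repeatedly searching random
N-gene draws from the background and averaging the per-draw minimum
p-values; above a floor size a single fixed threshold is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .crm_search import CRM, SearchConfig, search_common_crms
from .profiles import GeneProfile, gene_min_instance

__all__ = [
    "BackgroundSet",
    "CalibrationTable",
    "hypergeom_upper_pvalue",
    "count_background_hits",
    "score_crm",
    "score_crms",
    "calibrate_thresholds",
    "select_significant",
    "write_calibration_table",
    "read_calibration_table",
]


@dataclass
class BackgroundSet:
    """B reference gene profiles against which enrichment is measured."""

    genes: tuple[GeneProfile, ...]
    _hit_cache: dict[tuple[tuple[str, str], ...], int] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("background must contain at least one gene")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_ids in background")
        # per-gene union of oriented keys, for fast impossible-module rejection
        self._key_sets = [
            frozenset(k for p in g.promoters for k in p.index) for g in self.genes
        ]

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def hypergeom_upper_pvalue(B: int, b: int, N: int, n: int) -> float:
    """Upper-tail P(X >= n), X ~ Hypergeometric(B population, b successes, N draws)."""
    if not (0 <= b <= B):
        raise ValueError(f"require 0 <= b <= B, got b={b}, B={B}")
    if not (0 <= N <= B):
        raise ValueError(f"require 0 <= N <= B, got N={N}, B={B}")
    if not (0 <= n <= min(N, b) or n == 0):
        raise ValueError(f"require 0 <= n <= min(N, b), got n={n}")
    if n == 0:
        return 1.0
    # sf is computed via stable log-space combinatorics inside scipy
    p = float(hypergeom.sf(n - 1, B, b, N))
    return min(max(p, 0.0), 1.0)


def count_background_hits(
    elements: Sequence[tuple[str, str]], background: BackgroundSet
) -> int:
    """Background genes with heuristic raw presence of the module (no length band)."""
    key = tuple(elements)
    cached = background._hit_cache.get(key)
    if cached is not None:
        return cached
    from .profiles import oriented_key

    needed = {oriented_key(f, o) for f, o in elements}
    hits = 0
    for gene, keys in zip(background.genes, background._key_sets):
        if not needed <= keys:
            continue
        if gene_min_instance(gene, elements)[0]:
            hits += 1
    background._hit_cache[key] = hits
    return hits


def score_crm(crm: CRM, n_battery: int, background: BackgroundSet) -> float:
    """Hypergeometric p-value of one evaluated module; also stored on the CRM."""
    b = count_background_hits(crm.elements, background)
    n = len(crm.support_genes)
    if n > b:
        # battery genes outside the background can push n past b; the
        # upper-tail sum over i = n..min(N, b) is then empty -> 0
        p = 0.0
    else:
        p = hypergeom_upper_pvalue(background.size, b, n_battery, n)
    crm.p_value = p
    return p


def score_crms(
    crms: Iterable[CRM], n_battery: int, background: BackgroundSet
) -> list[CRM]:
    out = list(crms)
    for crm in out:
        score_crm(crm, n_battery, background)
    return out


@dataclass
class CalibrationTable:
    """Battery-size -> p-value threshold map from the randomization procedure."""

    thresholds: dict[int, float]
    floor_size: int = 14
    floor_threshold: float = 0.01
    reps: int = 100
    delta: float = 0.7
    seed: int | None = None

    def threshold(self, n_genes: int) -> float:
        if n_genes >= self.floor_size:
            return self.floor_threshold
        if n_genes not in self.thresholds:
            raise KeyError(
                f"no calibrated threshold for battery size {n_genes}; "
                "re-run calibration over a range covering it or supply a fixed alpha"
            )
        return self.thresholds[n_genes]


def calibrate_thresholds(
    background: BackgroundSet,
    sizes: Iterable[int] = range(4, 21),
    reps: int = 100,
    delta: float = 0.7,
    seed: int = 0,
    config: SearchConfig | None = None,
    floor_size: int = 14,
    floor_threshold: float = 0.01,
) -> CalibrationTable:
    """Monte-Carlo thresholds: mean over reps of the minimum p-value of the
    common CRMs found in a random N-gene draw (1.0 when none is found).

    Each (N, rep) cell uses an independent RNG substream derived from the
    single seed, so results are reproducible and order-independent.
    Entries at or above ``floor_size`` are replaced by ``floor_threshold``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sizes = sorted(set(int(s) for s in sizes))
    if sizes and (sizes[0] < 2 or sizes[-1] > background.size):
        raise ValueError(
            f"battery sizes must lie in [2, B={background.size}], got {sizes[0]}..{sizes[-1]}"
        )
    base_cfg = config or SearchConfig()
    cfg = SearchConfig(
        delta=delta,
        min_module_size=base_cfg.min_module_size,
        max_module_size=base_cfg.max_module_size,
        length_band=base_cfg.length_band,
    )
    thresholds: dict[int, float] = {}
    for n_genes in sizes:
        if n_genes >= floor_size:
            thresholds[n_genes] = floor_threshold
            continue
        minima = []
        for rep in range(reps):
            rng = np.random.default_rng([seed, n_genes, rep])
            idx = rng.choice(background.size, size=n_genes, replace=False)
            battery = [background.genes[i] for i in sorted(idx)]
            crms = search_common_crms(battery, cfg)
            if crms:
                pvals = [score_crm(c, n_genes, background) for c in crms]
                minima.append(min(pvals))
            else:
                minima.append(1.0)
        thresholds[n_genes] = float(np.mean(minima))
    return CalibrationTable(
        thresholds=thresholds,
        floor_size=floor_size,
        floor_threshold=floor_threshold,
        reps=reps,
        delta=delta,
        seed=seed,
    )


def select_significant(
    crms: Sequence[CRM],
    n_battery: int,
    table: CalibrationTable | None = None,
    alpha: float | None = None,
) -> list[CRM]:
    """Modules with p strictly below the size-dependent threshold (or alpha)."""
    if (table is None) == (alpha is None):
        raise ValueError("provide exactly one of a calibration table or a fixed alpha")
    cutoff = alpha if alpha is not None else table.threshold(n_battery)
    for crm in crms:
        if crm.p_value is None:
            raise ValueError(f"CRM {crm.label} has not been scored")
    kept = [c for c in crms if c.p_value < cutoff]
    kept.sort(key=lambda c: (c.p_value, c.label))
    return kept


# ---------------------------------------------------------------------------
# calibration table IO
# ---------------------------------------------------------------------------

def write_calibration_table(path, table: CalibrationTable) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# reps={table.reps}\tdelta={table.delta}\tseed={table.seed}"
            f"\tfloor_size={table.floor_size}\tfloor_threshold={table.floor_threshold}\n"
        )
        fh.write("N\tthreshold\n")
        for n_genes in sorted(table.thresholds):
            fh.write(f"{n_genes}\t{table.thresholds[n_genes]!r}\n")


def read_calibration_table(path) -> CalibrationTable:
    meta = {}
    thresholds: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].strip().split("\t"):
                    k, _, v = part.partition("=")
                    meta[k] = v
                continue
            if not line or line.startswith("N\t"):
                continue
            n_str, t_str = line.split("\t")
            thresholds[int(n_str)] = float(t_str)
    return CalibrationTable(
        thresholds=thresholds,
        floor_size=int(meta.get("floor_size", 14)),
        floor_threshold=float(meta.get("floor_threshold", 0.01)),
        reps=int(meta.get("reps", 100)),
        delta=float(meta.get("delta", 0.7)),
        seed=None if meta.get("seed") in (None, "None") else int(meta["seed"]),
    )
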