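"""Run-to-run stability of enriched causal terms: POT curve and Venn commonality.

Repeated runs of the pipeline (same hyperparameters, different classifier
seeds) may enrich slightly different term sets.  Two summaries quantify
stability:

* **POT** (percentage of overlapped terms): rank each run's enriched terms
  by z descending; for a cutoff L, POT(L) is the number of terms common to
  every run's top-L divided by L, evaluated for L = 1..30 and averaged.
* **Venn commonality**: |intersection| / |union| of the enriched sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .causal import CausalTable

__all__ = [
    "DEFAULT_L_MAX",
    "RobustnessReport",
    "ranked_terms",
    "pot_curve",
    "average_pot",
    "venn_commonality",
    "evaluate_runs",
]

DEFAULT_L_MAX = 30


def ranked_terms(table: CausalTable) -> list[str]:
    """Enriched entity ids ranked by z descending, ties broken by id."""
    return [r.entity_id for r in sorted(table.enriched, key=lambda r: (-r.z, r.entity_id))]


def pot_curve(runs: Sequence[Sequence[str]], l_max: int = DEFAULT_L_MAX) -> dict[int, float]:
    """POT(L) = |intersection of each run's top-L| / L, for L = 1..l_max.

    A run shorter than L contributes its full list as its top-L.  Requires
    at least two non-empty runs.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    lists = [list(run) for run in runs]
    for run in lists:
        if not run:
            raise ValueError("empty run")
        if len(set(run)) != len(run):
            raise ValueError("ranked term list contains duplicates")
    curve: dict[int, float] = {}
    for l in range(1, l_max + 1):
        tops = [set(run[:l]) for run in lists]
        common = set.intersection(*tops)
        curve[l] = len(common) / l
    return curve


def average_pot(curve: Mapping[int, float]) -> float:
    """Arithmetic mean of the POT curve values."""
    if not curve:
        raise ValueError("empty POT curve")
    return sum(curve.values()) / len(curve)


def venn_commonality(term_sets: Sequence[Iterable[str]], mode: str = "iou") -> float:
    """Shared fraction of enriched terms across runs.

    ``iou`` (default): |intersection| / |union|; ``mean``: |intersection|
    divided by the mean set size.
    """
    sets = [set(s) for s in term_sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 term sets")
    union = set.union(*sets)
    if not union:
        raise ValueError("union of term sets is empty")
    intersection = set.intersection(*sets)
    if mode == "iou":
        return len(intersection) / len(union)
    if mode == "mean":
        return len(intersection) / (sum(len(s) for s in sets) / len(sets))
    raise ValueError(f"unknown commonality mode {mode!r}")


@dataclass(frozen=True)
class RobustnessReport:
    """POT curve plus scalar summaries for a set of repeated runs."""

    pot: dict[int, float]
    average_pot: float
    commonality: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("L\tpot\n")
            for l in sorted(self.pot):
                fh.write(f"{l}\t{self.pot[l]:.6g}\n")
            fh.write(f"# average_pot\t{self.average_pot:.6g}\n")
            fh.write(f"# commonality\t{self.commonality:.6g}\n")


def evaluate_runs(tables: Sequence[CausalTable], l_max: int = DEFAULT_L_MAX) -> RobustnessReport:
    """Robustness report over the causal tables of repeated runs."""
    ranked = [ranked_terms(t) for t in tables]
    curve = pot_curve(ranked, l_max=l_max)
    return RobustnessReport(
        pot=curve,
        average_pot=average_pot(curve),
        commonality=venn_commonality([set(r) for r in ranked]),
    )
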