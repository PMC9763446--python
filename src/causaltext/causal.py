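"""Named-entity do-calculus: interventional enrichment of entities over text.

For each candidate entity ``ner`` the corpus is partitioned into
S1 = {p(x_i) : ner in x_i} (the DO group) and S2 = {p(x_i) : ner not in x_i}
(the NOT-DO group), where p(x_i) is the classifier's endpoint probability.
Presence of the entity is the intervention: a one-tailed two-sample z-test

    z = (mean S1 - mean S2) / sqrt(var S1 / n1 + var S2 / n2)

(unbiased sample variances, upper-tail p-value) asks whether the entity's
presence raises the endpoint probability.  P-values are adjusted for
multiplicity across all tested entities (Benjamini-Hochberg by default) and
entities with adjusted p below alpha form the enriched causal-term set.  A
raw z-threshold decision mode (z > thr, default 1.645) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .classifier import PredictionTable
from .corpus import Corpus
from .ner import EntityOccurrence

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_MIN_GROUP",
    "DEFAULT_Z_THRESHOLD",
    "UntestableEntityError",
    "ZeroVarianceError",
    "DoPartition",
    "CausalRecord",
    "CausalTable",
    "do_partition",
    "z_test_one_tailed",
    "adjust_pvalues",
    "probability_difference",
    "infer_causal_terms",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_GROUP = 5
#: Upper-tail critical value at alpha = 0.05 for the raw-z decision mode.
DEFAULT_Z_THRESHOLD = 1.645

#: Numerical floor below which a pooled standard error is treated as zero.
_SE_FLOOR = 1e-9

_ADJUSTMENT_METHODS = {
    "fdr_bh": "fdr_bh",
    "bh": "fdr_bh",
    "benjamini-hochberg": "fdr_bh",
    "bonferroni": "bonferroni",
    "holm": "holm",
    "fdr_by": "fdr_by",
}


class UntestableEntityError(ValueError):
    """The DO or NOT-DO group of an entity is empty."""


class ZeroVarianceError(ValueError):
    """Both groups are constant, so the z statistic is undefined."""


@dataclass(frozen=True)
class DoPartition:
    """Probabilities partitioned by entity presence: S1 = DO, S2 = NOT DO."""

    entity_id: str
    s1: tuple[float, ...]
    s2: tuple[float, ...]

    @property
    def n_do(self) -> int:
        return len(self.s1)

    @property
    def n_not_do(self) -> int:
        return len(self.s2)


@dataclass(frozen=True)
class CausalRecord:
    """One tested entity: z statistic, p-values and group summaries."""

    entity_id: str
    category: str
    z: float
    p_value: float
    adjusted_p: float
    mean_do: float
    mean_not_do: float
    n_do: int
    n_not_do: int

    @property
    def probability_difference(self) -> float:
        return probability_difference(self.mean_do, self.mean_not_do)


@dataclass(frozen=True)
class CausalTable:
    """All tested entities plus the enrichment decision.

    ``records`` are sorted by z descending (ties by id); ``skipped`` maps
    untestable entities to a reason so nothing is silently dropped.  With
    ``z_threshold`` set, enrichment is decided by raw z > threshold instead
    of adjusted p < alpha.  ``excluded`` entities (e.g. non-idiosyncratic
    drugs) stay in ``records`` but are removed from the enriched set.
    """

    records: tuple[CausalRecord, ...]
    alpha: float = DEFAULT_ALPHA
    z_threshold: float | None = None
    skipped: Mapping[str, str] = field(default_factory=dict)
    excluded: Mapping[str, str] = field(default_factory=dict)

    @property
    def enriched(self) -> tuple[CausalRecord, ...]:
        if self.z_threshold is not None:
            hits = [r for r in self.records if r.z > self.z_threshold]
        else:
            hits = [r for r in self.records if r.adjusted_p < self.alpha]
        return tuple(r for r in hits if r.entity_id not in self.excluded)

    def enriched_ids(self) -> set[str]:
        return {r.entity_id for r in self.enriched}

    def record(self, entity_id: str) -> CausalRecord:
        for r in self.records:
            if r.entity_id == entity_id:
                return r
        raise KeyError(entity_id)

    def to_tsv(self, path: str | Path) -> None:
        enriched = self.enriched_ids()
        with open(path, "w") as fh:
            fh.write(
                "entity_id\tcategory\tz_score\tp_value\tadjusted_p\tprob_do\t"
                "prob_not_do\tprob_difference\tn_do\tn_not_do\tenriched\n"
            )
            for r in self.records:
                fh.write(
                    f"{r.entity_id}\t{r.category}\t{r.z:.17g}\t{r.p_value:.17g}\t"
                    f"{r.adjusted_p:.17g}\t{r.mean_do:.17g}\t{r.mean_not_do:.17g}\t"
                    f"{r.probability_difference:.17g}\t{r.n_do}\t{r.n_not_do}\t"
                    f"{int(r.entity_id in enriched)}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, alpha: float = DEFAULT_ALPHA) -> "CausalTable":
        records = []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                records.append(
                    CausalRecord(
                        entity_id=parts[0],
                        category=parts[1],
                        z=float(parts[2]),
                        p_value=float(parts[3]),
                        adjusted_p=float(parts[4]),
                        mean_do=float(parts[5]),
                        mean_not_do=float(parts[6]),
                        n_do=int(parts[8]),
                        n_not_do=int(parts[9]),
                    )
                )
        records.sort(key=lambda r: (-r.z, r.entity_id))
        return cls(records=tuple(records), alpha=alpha)


def do_partition(entity: str, occ: EntityOccurrence, preds: PredictionTable) -> DoPartition:
    """Split the prediction table by presence of ``entity``.

    Raises :class:`UntestableEntityError` when either group would be empty.
    """
    if entity not in occ.instance_sets:
        raise KeyError(f"entity {entity!r} not in occurrence map")
    containing = occ.instance_sets[entity]
    s1, s2 = [], []
    for pid, p in preds.probabilities.items():
        (s1 if pid in containing else s2).append(p)
    if not s1 or not s2:
        raise UntestableEntityError(
            f"entity {entity!r} yields an empty {'NOT-DO' if not s2 else 'DO'} group"
        )
    return DoPartition(entity_id=entity, s1=tuple(s1), s2=tuple(s2))


def z_test_one_tailed(s1: Sequence[float], s2: Sequence[float]) -> tuple[float, float]:
    """Upper-tailed two-sample z-test for mean(s1) > mean(s2).

    Uses unbiased (n-1) sample variances and the unequal-variance standard
    error; the p-value is the upper tail of the standard normal at z.
    """
    a = np.asarray(s1, dtype=float)
    b = np.asarray(s2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    # float cancellation on (near-)constant groups leaves variance dust
    # ~1e-33; any genuine standard error on probability data is orders of
    # magnitude above this floor
    if se <= _SE_FLOOR:
        raise ZeroVarianceError("zero pooled standard error: both groups are constant")
    z = (a.mean() - b.mean()) / se
    return z, float(norm.sf(z))


def adjust_pvalues(p: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Multiplicity adjustment (Benjamini-Hochberg step-up by default).

    Order-preserving; each adjusted value lies in [p_i, 1].
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    key = _ADJUSTMENT_METHODS.get(method.lower())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    adjusted = multipletests(arr, method=key)[1]
    return [float(v) for v in adjusted]


def probability_difference(mean_do: float, mean_not_do: float) -> float:
    """Interventional probability difference: mean DO minus mean NOT-DO."""
    return mean_do - mean_not_do


def infer_causal_terms(
    corpus: Corpus,
    preds: PredictionTable,
    occ: EntityOccurrence,
    alpha: float = DEFAULT_ALPHA,
    min_group: int = DEFAULT_MIN_GROUP,
    method: str = "fdr_bh",
    z_threshold: float | None = None,
) -> CausalTable:
    """Run the do-calculus enrichment over every entity in the occurrence map.

    ``occ`` is expected to be frequency-filtered already.  Entities whose DO
    or NOT-DO group is empty, smaller than ``min_group``, or constant in
    both groups are reported in ``skipped`` with a reason, never silently
    dropped.  Enrichment is adjusted-p < alpha (BH by default), or raw
    z > ``z_threshold`` when one is given.
    """
    if len(occ) == 0:
        raise ValueError("occurrence map is empty")
    if preds.ids() != set(corpus.ids()):
        raise ValueError("prediction table does not cover the corpus")
    tested: list[tuple[str, DoPartition, float, float]] = []
    skipped: dict[str, str] = {}
    for entity in sorted(occ.entity_ids()):
        try:
            part = do_partition(entity, occ, preds)
        except UntestableEntityError as exc:
            skipped[entity] = str(exc)
            continue
        if part.n_do < min_group or part.n_not_do < min_group:
            skipped[entity] = f"group below min_group={min_group} (n_do={part.n_do}, n_not_do={part.n_not_do})"
            continue
        try:
            z, p = z_test_one_tailed(part.s1, part.s2)
        except ZeroVarianceError as exc:
            skipped[entity] = str(exc)
            continue
        tested.append((entity, part, z, p))
    adjusted = adjust_pvalues([p for *_, p in tested], method=method) if tested else []
    records = []
    for (entity, part, z, p), adj in zip(tested, adjusted):
        records.append(
            CausalRecord(
                entity_id=entity,
                category=occ.categories.get(entity, "?"),
                z=z,
                p_value=p,
                adjusted_p=adj,
                mean_do=float(np.mean(part.s1)),
                mean_not_do=float(np.mean(part.s2)),
                n_do=part.n_do,
                n_not_do=part.n_not_do,
            )
        )
    records.sort(key=lambda r: (-r.z, r.entity_id))
    return CausalTable(
        records=tuple(records),
        alpha=alpha,
        z_threshold=z_threshold,
        skipped=skipped,
    )
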