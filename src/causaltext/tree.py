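"""Knowledge-based causal tree and idiosyncratic-DILI patient stratification.

Enriched causal terms are organized into the causal-factor categories of
the ACG clinical guideline for suspected idiosyncratic drug-induced liver
injury (liver enzymes, concomitant diseases, history of other liver
disorders, physical findings, laboratory results, symptoms and signs,
clinical outcome).  The tree combines those term lists with liver-enzyme
rules on the R score

    R = ALT / AST,

classifying injury pattern as hepatocellular (R > 5), mixed (2 < R < 5) or
cholestatic (R < 2); boundary values fall into "mixed" so the rule is total
(configurable).  Patients are stratified by computing R from their labs and
matching tree terms in their case-report text; matched clinical-outcome
terms map to an ordinal severity bucket (1+ mild .. 5+ fatal) through a
configurable term-to-level table.

Note: R is ALT/AST here by design of the upstream case study; the
clinical-standard R ((ALT/ULN)/(ALP/ULN)) is available via ``r_score``'s
ULN-normalized mode but is off by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr

from .causal import CausalRecord, CausalTable
from .corpus import tokenize
from .ner import EntityLexicon, _extract_from_tokens

__all__ = [
    "ACG_CATEGORIES",
    "HEPATOCELLULAR",
    "MIXED",
    "CHOLESTATIC",
    "UNASSIGNED",
    "RScoreRules",
    "DEFAULT_SEVERITY_MAP",
    "CausalTree",
    "PatientRecord",
    "StratificationResult",
    "build_tree",
    "exclude_drug_entities",
    "r_score",
    "classify_pattern",
    "stratify_patient",
    "concordance",
    "reference_causal_table",
    "reference_category_assignments",
    "reference_clinical_lexicon",
    "reference_clinical_tree",
]

ACG_CATEGORIES = (
    "Liver Enzymes",
    "Concomitant diseases",
    "History of other liver disorder",
    "Physical findings",
    "Laboratory results",
    "Symptoms and signs",
    "Clinical outcome",
)

HEPATOCELLULAR = "hepatocellular"
MIXED = "mixed"
CHOLESTATIC = "cholestatic"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RScoreRules:
    """R thresholds for DILI pattern: hepatocellular above, cholestatic below.

    Boundary values (R exactly at a threshold) are folded into ``mixed``.
    """

    hepatocellular_above: float = 5.0
    cholestatic_below: float = 2.0


#: Ordinal severity levels (1+ mild .. 5+ fatal) assigned to matched
#: clinical-outcome terms; a patient's bucket is the maximum over matches,
#: lowest (1) when nothing matches.  Fully configurable.
DEFAULT_SEVERITY_MAP: dict[str, int] = {
    "acute liver failure": 5,
    "hepatic failure": 4,
    "liver failure": 4,
    "cirrhosis": 3,
    "sinusoidal obstruction syndrome": 3,
    "jaundice": 2,
    "hypersensitivity": 2,
    "skin rash": 1,
    "rash": 1,
}


@dataclass(frozen=True)
class CausalTree:
    """Per-category enriched-term lists plus lab rules and severity levels."""

    category_map: Mapping[str, tuple[str, ...]]
    lab_rules: RScoreRules = field(default_factory=RScoreRules)
    severity_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SEVERITY_MAP))
    unassigned: tuple[str, ...] = ()

    def terms(self) -> set[str]:
        return {t for terms in self.category_map.values() for t in terms}

    def category_of(self, entity_id: str) -> str | None:
        for category, terms in self.category_map.items():
            if entity_id in terms:
                return category
        return None


@dataclass(frozen=True)
class PatientRecord:
    """One case report: free text plus ALT/AST labs and optional expert labels."""

    id: str
    report_text: str
    alt: float | None = None
    ast: float | None = None
    expert_pattern: str | None = None
    expert_severity: int | None = None

    def __post_init__(self) -> None:
        for name, value in (("alt", self.alt), ("ast", self.ast)):
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive when present, got {value}")


@dataclass(frozen=True)
class StratificationResult:
    """Pattern, R score, matched tree terms and severity bucket for one patient."""

    patient_id: str
    r: float | None
    pattern: str | None
    matched_terms: Mapping[str, tuple[str, ...]]
    severity_bucket: int


def build_tree(
    table: CausalTable,
    category_assignments: Mapping[str, str],
    lab_rules: RScoreRules | None = None,
    severity_map: Mapping[str, int] | None = None,
) -> CausalTree:
    """Assemble the causal tree from an enrichment table and category labels.

    Every enriched term must be assigned to an ACG category or explicitly
    marked ``unassigned`` (kept in an audit list, excluded from the tree).
    Terms are listed per category by z descending.
    """
    enriched = sorted(table.enriched, key=lambda r: (-r.z, r.entity_id))
    categories: dict[str, list[str]] = {c: [] for c in ACG_CATEGORIES}
    unassigned: list[str] = []
    for record in enriched:
        category = category_assignments.get(record.entity_id)
        if category is None:
            raise ValueError(f"enriched term {record.entity_id!r} has no category assignment")
        if category == UNASSIGNED:
            unassigned.append(record.entity_id)
        elif category in categories:
            categories[category].append(record.entity_id)
        else:
            raise ValueError(f"unknown category {category!r} for {record.entity_id!r}")
    return CausalTree(
        category_map={c: tuple(terms) for c, terms in categories.items()},
        lab_rules=lab_rules or RScoreRules(),
        severity_map=dict(severity_map) if severity_map is not None else dict(DEFAULT_SEVERITY_MAP),
        unassigned=tuple(unassigned),
    )


def exclude_drug_entities(table: CausalTable, drug_ids: Iterable[str]) -> CausalTable:
    """Drop listed drug entities from the enriched set (records are kept).

    Used to remove dose-dependent hepatotoxicants (e.g. acetaminophen) that
    are not idiosyncratic causal factors.  Excluding an id that is not
    currently enriched is a no-op with a warning.
    """
    enriched_now = table.enriched_ids()
    excluded = dict(table.excluded)
    for eid in drug_ids:
        if eid not in enriched_now:
            warnings.warn(f"entity {eid!r} is not enriched; exclusion is a no-op", stacklevel=2)
            continue
        excluded[eid] = "drug entity excluded from causal-factor set"
    return replace(table, excluded=excluded)


def r_score(alt: float, ast: float) -> float:
    """R = ALT / AST (both in U/L)."""
    if ast <= 0:
        raise ValueError(f"AST must be positive, got {ast}")
    if alt <= 0:
        raise ValueError(f"ALT must be positive, got {alt}")
    return alt / ast


def r_score_uln(alt: float, alt_uln: float, alp: float, alp_uln: float) -> float:
    """Clinical-standard R: (ALT/ULN_ALT) / (ALP/ULN_ALP).  Off by default."""
    if min(alt, alt_uln, alp, alp_uln) <= 0:
        raise ValueError("all lab values and upper limits must be positive")
    return (alt / alt_uln) / (alp / alp_uln)


def classify_pattern(r: float, rules: RScoreRules | None = None) -> str:
    """Map an R score to hepatocellular / mixed / cholestatic."""
    if r < 0:
        raise ValueError(f"R score must be non-negative, got {r}")
    rules = rules or RScoreRules()
    if r > rules.hepatocellular_above:
        return HEPATOCELLULAR
    if r < rules.cholestatic_below:
        return CHOLESTATIC
    return MIXED


def stratify_patient(
    patient: PatientRecord,
    tree: CausalTree,
    lexicon: EntityLexicon,
) -> StratificationResult:
    """Stratify one patient: R pattern from labs, tree-term matches from text.

    With missing labs the pattern is omitted but term matching still runs.
    The severity bucket is the maximum severity level among matched terms
    (via the tree's severity map, keyed by entity id), lowest otherwise.
    """
    tokens = tokenize(patient.report_text)
    tree_terms = tree.terms()
    mentioned = {
        eid
        for eid in _extract_from_tokens(tokens, lexicon._index(), lexicon.entries)
        if eid in tree_terms
    }
    matched: dict[str, tuple[str, ...]] = {}
    for category, terms in tree.category_map.items():
        hits = tuple(t for t in terms if t in mentioned)
        if hits:
            matched[category] = hits
    if patient.alt is not None and patient.ast is not None:
        r = r_score(patient.alt, patient.ast)
        pattern = classify_pattern(r, tree.lab_rules)
    else:
        r = None
        pattern = None
    severity = max((tree.severity_map.get(t, 1) for t in mentioned), default=1)
    return StratificationResult(
        patient_id=patient.id,
        r=r,
        pattern=pattern,
        matched_terms=matched,
        severity_bucket=severity,
    )


def save_patients(patients: Sequence[PatientRecord], path: str | Path) -> None:
    """Write patient records as line-delimited JSON."""
    import json

    with open(path, "w") as fh:
        for p in patients:
            fh.write(
                json.dumps(
                    {
                        "id": p.id,
                        "report_text": p.report_text,
                        "alt": p.alt,
                        "ast": p.ast,
                        "expert_pattern": p.expert_pattern,
                        "expert_severity": p.expert_severity,
                    }
                )
                + "\n"
            )


def load_patients(path: str | Path) -> list[PatientRecord]:
    """Read line-delimited JSON patient records; optional fields may be absent."""
    import json

    patients = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            patients.append(
                PatientRecord(
                    id=str(rec["id"]),
                    report_text=rec["report_text"],
                    alt=rec.get("alt"),
                    ast=rec.get("ast"),
                    expert_pattern=rec.get("expert_pattern"),
                    expert_severity=rec.get("expert_severity"),
                )
            )
    return patients


def concordance(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation between two equally long, non-constant vectors."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("constant vector has no defined correlation")
    return float(pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# Reference clinical enrichment (LiverTox iDILI case study)
# ---------------------------------------------------------------------------

#: (entity id, ACG category, z, mean DO, mean NOT-DO) for the 18 clinical
#: terms enriched in the LiverTox idiosyncratic-DILI analysis; serves as a
#: canonical worked-example input for tree building and stratification.
REFERENCE_ENRICHED_TERMS: tuple[tuple[str, str, float, float, float], ...] = (
    ("alkaline phosphatase", "Liver Enzymes", 3.772, 0.398, 0.244),
    ("alt", "Liver Enzymes", 2.561, 0.307, 0.244),
    ("tuberculosis", "Concomitant diseases", 2.470, 0.382, 0.244),
    ("rheumatoid arthritis", "Concomitant diseases", 1.759, 0.334, 0.244),
    ("cholestasis", "History of other liver disorder", 4.827, 0.547, 0.244),
    ("cholestatic hepatitis", "History of other liver disorder", 3.653, 0.499, 0.244),
    ("fever", "Physical findings", 6.508, 0.383, 0.241),
    ("pain", "Physical findings", 2.377, 0.395, 0.244),
    ("lactic acidosis", "Laboratory results", 3.181, 0.460, 0.244),
    ("hypersensitivity", "Symptoms and signs", 3.966, 0.383, 0.243),
    ("skin rash", "Symptoms and signs", 2.066, 0.333, 0.244),
    ("jaundice", "Symptoms and signs", 1.773, 0.274, 0.244),
    ("stevens johnson syndrome", "Symptoms and signs", 1.669, 0.335, 0.245),
    ("hepatic failure", "Clinical outcome", 4.119, 0.437, 0.244),
    ("cirrhosis", "Clinical outcome", 2.944, 0.391, 0.244),
    ("liver failure", "Clinical outcome", 2.905, 0.366, 0.244),
    ("sinusoidal obstruction syndrome", "Clinical outcome", 2.490, 0.403, 0.244),
    ("acute liver failure", "Clinical outcome", 1.669, 0.326, 0.244),
)


def reference_causal_table(alpha: float = 0.05) -> CausalTable:
    """Causal table populated with the reference clinical enrichment results.

    p-values are back-computed from the recorded z statistics and re-adjusted
    (Benjamini-Hochberg) across the 18 terms.
    """
    from scipy.stats import norm

    from .causal import adjust_pvalues

    pvalues = [float(norm.sf(z)) for _, _, z, _, _ in REFERENCE_ENRICHED_TERMS]
    adjusted = adjust_pvalues(pvalues)
    records = tuple(
        sorted(
            (
                CausalRecord(
                    entity_id=eid,
                    category="disease",
                    z=z,
                    p_value=p,
                    adjusted_p=adj,
                    mean_do=mean_do,
                    mean_not_do=mean_not_do,
                    n_do=0,
                    n_not_do=0,
                )
                for (eid, _, z, mean_do, mean_not_do), p, adj in zip(
                    REFERENCE_ENRICHED_TERMS, pvalues, adjusted
                )
            ),
            key=lambda r: (-r.z, r.entity_id),
        )
    )
    return CausalTable(records=records, alpha=alpha)


def reference_category_assignments() -> dict[str, str]:
    """Entity id -> ACG category for the reference clinical terms."""
    return {eid: category for eid, category, *_ in REFERENCE_ENRICHED_TERMS}


def reference_clinical_lexicon() -> EntityLexicon:
    """Lexicon whose surface forms are the reference clinical term names."""
    lexicon = EntityLexicon()
    for eid, *_ in REFERENCE_ENRICHED_TERMS:
        lexicon.add(eid, eid, "disease")
    return lexicon


def reference_clinical_tree() -> CausalTree:
    """The reference knowledge-based causal tree (18 terms, 7 ACG categories)."""
    return build_tree(reference_causal_table(), reference_category_assignments())
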