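"""End-to-end pipeline: simulate -> split -> fit -> predict -> NER -> causal
-> robustness -> stratification, with a written manifest for reproducibility.

A pipeline *run* fits the classifier on the stratified training set (early
stopping on held-out loss), scores every instance of the full corpus, and
feeds the prediction table and the frequency-filtered entity occurrences to
the do-calculus engine.  Robustness mode repeats the run with different
classifier seeds (three by default, everything else fixed) and summarizes
the stability of the enriched sets.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy

from . import __version__
from .causal import CausalTable, infer_causal_terms
from .classifier import (
    PredictionTable,
    TrainingConfig,
    evaluate,
    fit_default_classifier,
    predict_corpus,
)
from .corpus import Corpus, stratified_split
from .ner import EntityLexicon, build_occurrence, frequency_filter
from .robustness import DEFAULT_L_MAX, RobustnessReport, evaluate_runs
from .synthetic import (
    GeneratorConfig,
    GroundTruth,
    generate_cohort,
    generate_corpus,
    recovery_metrics,
)
from .tree import (
    concordance,
    r_score,
    reference_clinical_lexicon,
    reference_clinical_tree,
    save_patients,
    stratify_patient,
)

__all__ = ["RunConfig", "PipelineResult", "single_run", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible pipeline invocation depends on."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    corpus_path: str | None = None
    lexicon_path: str | None = None
    train_fraction: float = 0.9
    alpha: float = 0.05
    freq_threshold: int = 50
    min_group: int = 5
    adjustment_method: str = "fdr_bh"
    l_max: int = DEFAULT_L_MAX
    runs: int = 3
    n_patients: int = 175
    seed: int = 0


@dataclass(frozen=True)
class PipelineResult:
    """Artifacts of a full pipeline invocation."""

    tables: tuple[CausalTable, ...]
    robustness: RobustnessReport | None
    precision: float | None
    recall: float | None
    r_concordance: float
    pattern_agreement: float
    severity_agreement: float
    test_metrics: dict[str, float]


def single_run(
    corpus: Corpus,
    lexicon: EntityLexicon,
    config: RunConfig,
    classifier_seed: int,
) -> tuple[CausalTable, dict[str, float]]:
    """One classifier fit + do-calculus pass; returns the causal table and
    held-out evaluation metrics."""
    split = stratified_split(corpus, config.train_fraction, seed=config.seed)
    training = replace(config.training, seed=classifier_seed)
    model = fit_default_classifier(split.train, config=training, eval_corpus=split.test)
    test_preds = predict_corpus(model, split.test)
    metrics = evaluate(test_preds, split.test.labels())
    preds = predict_corpus(model, corpus)
    occ = frequency_filter(build_occurrence(corpus, lexicon), config.freq_threshold)
    table = infer_causal_terms(
        corpus,
        preds,
        occ,
        alpha=config.alpha,
        min_group=config.min_group,
        method=config.adjustment_method,
    )
    return table, {
        "accuracy": metrics.accuracy,
        "precision": metrics.precision,
        "recall": metrics.recall,
        "f1": metrics.f1,
        "loss": metrics.loss,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Reruns with the same config are identical except manifest timestamps.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth: GroundTruth | None = None
    if config.corpus_path is not None:
        if config.lexicon_path is None:
            raise FileNotFoundError("lexicon stage: no lexicon path supplied alongside corpus")
        corpus = Corpus.from_jsonl(config.corpus_path)
        lexicon = EntityLexicon.from_tsv(config.lexicon_path)
    else:
        generator = replace(config.generator, seed=config.seed)
        corpus, lexicon, truth = generate_corpus(generator)
        corpus.to_jsonl(out / "corpus.jsonl")
        lexicon.to_tsv(out / "lexicon.tsv")

    tables = []
    eval_metrics: dict[str, float] = {}
    for run_index in range(config.runs):
        table, metrics = single_run(corpus, lexicon, config, classifier_seed=config.seed + run_index)
        table.to_tsv(out / f"causal_table_run{run_index}.tsv")
        tables.append(table)
        if run_index == 0:
            eval_metrics = metrics

    robustness = None
    if len(tables) >= 2 and all(t.enriched for t in tables):
        robustness = evaluate_runs(tables, l_max=config.l_max)
        robustness.to_tsv(out / "robustness.tsv")

    precision = recall = None
    if truth is not None:
        precision, recall = recovery_metrics(tables[0].enriched_ids(), truth)

    # stratification demo on a generated cohort under the clinical tree
    clinical_tree = reference_clinical_tree()
    clinical_lexicon = reference_clinical_lexicon()
    cohort = generate_cohort(config.n_patients, clinical_tree, seed=config.seed, lexicon=clinical_lexicon)
    save_patients(cohort, out / "cohort.jsonl")
    results = [stratify_patient(p, clinical_tree, clinical_lexicon) for p in cohort]
    computed_r = [res.r for res in results]
    expert_r = [r_score(p.alt, p.ast) for p in cohort]
    r_conc = concordance(computed_r, expert_r)
    pattern_agreement = float(
        np.mean([res.pattern == p.expert_pattern for res, p in zip(results, cohort)])
    )
    severity_agreement = float(
        np.mean([res.severity_bucket == p.expert_severity for res, p in zip(results, cohort)])
    )
    with open(out / "stratification.tsv", "w") as fh:
        fh.write("patient_id\tr\tpattern\tseverity_bucket\texpert_pattern\texpert_severity\n")
        for res, p in zip(results, cohort):
            fh.write(
                f"{res.patient_id}\t{res.r:.6g}\t{res.pattern}\t{res.severity_bucket}\t"
                f"{p.expert_pattern}\t{p.expert_severity}\n"
            )

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "seed": config.seed,
        "classifier_seeds": [config.seed + i for i in range(config.runs)],
        "config": _config_dict(config),
        "enriched_per_run": [sorted(t.enriched_ids()) for t in tables],
        "test_metrics": eval_metrics,
        "recovery": {"precision": precision, "recall": recall},
        "robustness": None
        if robustness is None
        else {"average_pot": robustness.average_pot, "commonality": robustness.commonality},
        "stratification": {
            "r_concordance": r_conc,
            "pattern_agreement": pattern_agreement,
            "severity_agreement": severity_agreement,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        tables=tuple(tables),
        robustness=robustness,
        precision=precision,
        recall=recall,
        r_concordance=r_conc,
        pattern_agreement=pattern_agreement,
        severity_agreement=severity_agreement,
        test_metrics=eval_metrics,
    )


def _config_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        return obj

    return convert(config)
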