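"""End-to-end analysis plumbing.

Two entry points:

* :func:`evaluate_cohort` — run every discrimination method (the 43-index
  registry plus any rule sets) over a labeled cohort and tabulate the full
  accuracy suite per method;
* :func:`reconstructed_method_profiles` — rebuild each published method's
  confusion matrix from its reported Youden/accuracy summary (class sizes
  708/470), from which the complete measure set follows exactly.  This is
  how the published accuracy tables are made re-derivable without the
  undeposited patient data.

Either route yields per-method profiles for the similarity meta-analysis
(:func:`similarity_analysis`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from io import StringIO
from typing import Mapping, Sequence

import pandas as pd

from . import metrics as M
from .cohort import BTT, IDA, PatientRecord
from .indices import IndexDefinition, builtin_registry, classify_cohort
from .similarity import (
    KSelection,
    MethodMap,
    Dendrogram,
    classical_mds,
    complete_linkage,
    profile_matrix,
    select_k_majority,
)
from .tree_rules import RuleSet, RuleSetError, cruise_ruleset, predict_ruleset

__all__ = [
    "reported_summary",
    "reconstructed_method_profiles",
    "evaluate_cohort",
    "similarity_analysis",
    "SimilarityResult",
    "metrics_report",
]

REPORT_COLUMNS = (
    "sensitivity", "specificity", "fpr", "fnr", "ppv", "npv",
    "youden", "accuracy", "plr", "nlr", "dor", "f_measure", "auc",
)


@lru_cache(maxsize=1)
def reported_summary() -> pd.DataFrame:
    """Published per-method Youden/accuracy summary (percent), 52 methods."""
    text = resources.files("microcyte.data").joinpath(
        "reported_summary.csv"
    ).read_text("utf-8")
    return pd.read_csv(StringIO(text))


def reconstructed_method_profiles(
    n_pos: int = 708, n_neg: int = 470
) -> tuple[dict[str, M.MetricSet], pd.DataFrame]:
    """Confusion matrices and full measure sets for every published method.

    Uses the best-fit integer reconstruction; the returned frame carries the
    matrix cells and the residuals (published minus re-derived, percentage
    points) so imperfectly reconstructable rows are visible, not hidden.
    """
    summary = reported_summary()
    metric_sets: dict[str, M.MetricSet] = {}
    rows = []
    for _, row in summary.iterrows():
        cm, dj, da = M.recover_confusion_best(
            row["youden"], row["accuracy"], n_pos, n_neg
        )
        ms = M.metric_set(cm)
        metric_sets[row["method"]] = ms
        rows.append({
            "method": row["method"], "kind": row["kind"],
            "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
            "youden_residual": dj, "accuracy_residual": da,
            **ms.as_dict(),
        })
    return metric_sets, pd.DataFrame(rows).set_index("method")


def evaluate_cohort(
    cohort: Sequence[PatientRecord],
    registry: Sequence[IndexDefinition] | None = None,
    rulesets: Sequence[RuleSet] | None = None,
    with_cis: bool = False,
    ci_seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, M.MetricSet]]:
    """Classify a labeled cohort with every method and tabulate accuracy.

    Index predictions come from the registry; rule sets (the published
    CRUISE rules by default) are applied through the rule engine.  Records a
    method cannot score are dropped from that method's confusion matrix.
    """
    registry = builtin_registry() if registry is None else list(registry)
    rulesets = [cruise_ruleset()] if rulesets is None else list(rulesets)
    truth = [r.label for r in cohort]
    if not set(truth) >= {IDA, BTT}:
        raise ValueError("cohort must contain both IDA and BTT records")
    predictions = classify_cohort(registry, cohort)
    metric_sets: dict[str, M.MetricSet] = {}
    rows = []
    for name in predictions.index:
        preds = predictions.loc[name]
        mask = ~preds.str.startswith("NA:")
        cm = M.confusion(
            [t for t, ok in zip(truth, mask) if ok], list(preds[mask])
        )
        metric_sets[name] = M.metric_set(cm)
        rows.append((name, cm, int(mask.sum())))
    for rules in rulesets:
        preds, kept_truth = [], []
        for record in cohort:
            try:
                preds.append(predict_ruleset(rules, record))
                kept_truth.append(record.label)
            except RuleSetError:
                continue
        cm = M.confusion(kept_truth, preds)
        metric_sets[rules.name] = M.metric_set(cm)
        rows.append((rules.name, cm, len(preds)))
    table_rows = []
    for name, cm, n_eval in rows:
        ms = metric_sets[name]
        entry = {"method": name, "n_evaluable": n_eval,
                 "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                 **ms.as_dict()}
        if with_cis:
            for measure, (lo, hi) in M.metric_cis(cm, seed=ci_seed).items():
                entry[f"{measure}_lo"] = lo
                entry[f"{measure}_hi"] = hi
        table_rows.append(entry)
    table = pd.DataFrame(table_rows).set_index("method")
    ordered = ["n_evaluable", "tp", "fp", "fn", "tn", *REPORT_COLUMNS]
    if with_cis:
        for c in REPORT_COLUMNS:
            ordered += [f"{c}_lo", f"{c}_hi"]
    return table.reindex(columns=[c for c in ordered if c in table.columns]), metric_sets


def metrics_report(table: pd.DataFrame, path) -> None:
    """Write the per-method metrics table as CSV (report column order)."""
    table.to_csv(path)


@dataclass
class SimilarityResult:
    profiles: pd.DataFrame
    distances: pd.DataFrame
    embedding: MethodMap
    dendrogram: Dendrogram
    selection: KSelection
    clusters: dict[str, int]


def similarity_analysis(
    metric_sets: Mapping[str, M.MetricSet],
    k_candidates: Sequence[int] = range(2, 9),
    cap_percentile: float | None = 99.0,
) -> SimilarityResult:
    """Standardized profiles -> Euclidean distances -> classical MDS +
    complete-linkage clustering with majority-vote group-count selection.

    ``cap_percentile`` handles degenerate methods (a perfectly sensitive
    index has infinite PLR) by capping non-finite profile entries; pass None
    to make such entries a hard error instead.
    """
    profiles, distances = profile_matrix(metric_sets, cap_percentile=cap_percentile)
    embedding = classical_mds(distances, k=2)
    dendrogram = complete_linkage(distances)
    selection = select_k_majority(profiles, distances, k_candidates=k_candidates)
    clusters = dendrogram.cut_k(selection.k)
    return SimilarityResult(
        profiles, distances, embedding, dendrogram, selection, clusters
    )
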