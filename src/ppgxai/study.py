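"""Model-comparison study drivers.

Two analyses are assembled here from the lower-level modules:

* :func:`compare_models` — the per-model x per-saliency-method grid of the
  four explainability metrics (Pixel / Sectional / Interval Annotation
  Classification AUROC and Congruence), plus :func:`summarize_differences`
  for its summary arithmetic.
* :func:`explainability_performance_study` — train many models on varying
  fractions of the data, measure performance (accuracy, NPV, specificity)
  and explainability per model, and correlate the two families with Pearson
  r / p, reporting a Bonferroni-adjusted significance column.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import scipy.stats

from .core import LabeledDataset
from .metrics import (
    DegenerateAurocError,
    UndefinedCongruenceError,
    annotation_classification,
    congruence_dataset,
)
from .models import PpgCnnClassifier, TrainConfig, evaluate, train
from .saliency import METHODS, AttentionExtractor

__all__ = [
    "METRIC_COLUMNS",
    "compare_models",
    "summarize_differences",
    "pearson",
    "explainability_performance_study",
    "explainability_row",
    "render_markdown",
]

logger = logging.getLogger("ppgxai")

METRIC_COLUMNS = ("pixel", "sectional", "interval", "congruence")

#: (explainability metric, performance metric) pairs reported by the
#: correlation study.
STUDY_PAIRS = (
    ("congruence", "accuracy"),
    ("sectional", "accuracy"),
    ("interval", "accuracy"),
    ("pixel", "accuracy"),
    ("pixel", "npv"),
    ("pixel", "specificity"),
)

_PRETTY = {
    "congruence": "Congruence",
    "pixel": "Pixel Classification",
    "sectional": "Sectional Classification",
    "interval": "Interval Classification",
    "accuracy": "Testing Accuracy",
    "npv": "NPV",
    "specificity": "Specificity",
}


def explainability_row(
    model,
    dataset: LabeledDataset,
    method: str,
    interval_len_s: float = 5.0,
    attention_maps: np.ndarray | None = None,
    **extractor_kwargs,
) -> dict:
    """All four explainability metrics of one model with one saliency method.

    Only annotated (artifactual) records enter the metrics; precomputed
    ``attention_maps`` for those records may be supplied to bypass saliency
    extraction (e.g. synthetic attention with known ground truth).
    """
    annotated = dataset.annotated()
    if len(annotated) == 0:
        raise ValueError("explainability metrics require annotated records")
    dropped = len(dataset) - len(annotated)
    if dropped:
        logger.info("excluding %d unannotated record(s) from explainability metrics", dropped)
    if attention_maps is None:
        attention_maps = AttentionExtractor(
            model=model, method=method, **extractor_kwargs
        ).transform(annotated.X)
    pairs = list(zip(attention_maps, annotated.masks))
    row: dict[str, float] = {}
    for variant in ("pixel", "sectional", "interval"):
        try:
            row[variant] = annotation_classification(
                pairs, variant, fs=annotated.fs, interval_len_s=interval_len_s
            )
        except DegenerateAurocError:
            logger.warning("%s AUROC degenerate for method %s", variant, method)
            row[variant] = math.nan
    try:
        row["congruence"] = congruence_dataset(pairs)
    except UndefinedCongruenceError:
        logger.warning("congruence undefined for every record with method %s", method)
        row["congruence"] = math.nan
    return row


def compare_models(
    models: dict,
    dataset: LabeledDataset,
    methods: tuple[str, ...] = METHODS,
    interval_len_s: float = 5.0,
    **extractor_kwargs,
) -> pd.DataFrame:
    """Explainability-metrics grid over models x saliency methods.

    Returns a DataFrame indexed by (model, method) with columns
    ``pixel, sectional, interval, congruence``; degenerate cells are NaN
    (flagged by a logged warning), leaving the grid incomplete.
    """
    rows = {}
    for model_name, model in models.items():
        for method in methods:
            rows[(model_name, method)] = explainability_row(
                model, dataset, method, interval_len_s, **extractor_kwargs
            )
    table = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_COLUMNS)]
    table.index = pd.MultiIndex.from_tuples(table.index, names=["model", "method"])
    return table


def summarize_differences(table: pd.DataFrame, model_a: str, model_b: str) -> dict:
    """Summary arithmetic over a complete metrics grid.

    Returns
    -------
    dict with keys
        ``mean_congruence_diff`` — mean over saliency methods of
        (Congruence_a - Congruence_b);
        ``mean_ac_diff`` — mean over methods x the three Annotation
        Classification variants of (a - b);
        ``per_variant_means`` — mean of each variant over both models and
        all methods;
        ``per_model_mean_congruence`` — mean congruence over methods, per
        model.
    """
    a = table.loc[model_a]
    b = table.loc[model_b]
    both = pd.concat([a, b])
    if both[list(METRIC_COLUMNS)].isna().any().any():
        raise ValueError("metrics grid is incomplete (NaN cells present)")
    ac = ["pixel", "sectional", "interval"]
    return {
        "mean_congruence_diff": float((a["congruence"] - b["congruence"]).mean()),
        "mean_ac_diff": float((a[ac] - b[ac]).to_numpy().mean()),
        "per_variant_means": {v: float(both[v].mean()) for v in ac},
        "per_model_mean_congruence": {
            model_a: float(a["congruence"].mean()),
            model_b: float(b["congruence"].mean()),
        },
    }


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value (n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def explainability_performance_study(
    base_dataset: LabeledDataset,
    test_dataset: LabeledDataset,
    fractions: tuple[float, ...] = (0.05, 0.10, 0.20, 0.40, 0.50),
    reps: int = 5,
    config: TrainConfig | None = None,
    seed: int = 0,
    method: str = "integrated_gradients",
    interval_len_s: float = 5.0,
    alpha: float = 0.05,
    **extractor_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate explainability with performance across many trained models.

    For each dataset fraction, ``reps`` models are trained on stratified
    subsamples of ``base_dataset`` (per-rep seeds derived from the master
    seed), then evaluated on ``test_dataset`` for performance (accuracy,
    NPV, specificity at threshold 0.5) and explainability (all four metrics
    with the chosen saliency method). Pearson r / p is computed for each
    reported (explainability, performance) pair over all models, with a
    Bonferroni-adjusted significance column at ``alpha / n_rows``.

    Returns ``(correlation_report, per_model_records)`` as DataFrames.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(seed)
    y = base_dataset.y
    records = []
    for fraction in fractions:
        for rep in range(reps):
            rep_seed = int(rng.integers(2**31 - 1))
            rep_rng = np.random.default_rng(rep_seed)
            idx = _stratified_fraction(y, fraction, rep_rng)
            subset = base_dataset.subset(idx)
            rep_config = TrainConfig(**{**config.__dict__, "seed": rep_seed})
            try:
                clf, _ = train(subset, None, rep_config)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                logger.warning(
                    "training failed for fraction %.2f rep %d: %s", fraction, rep, exc
                )
                continue
            perf = evaluate(clf, test_dataset)
            expl = explainability_row(
                clf, test_dataset, method, interval_len_s, **extractor_kwargs
            )
            records.append(
                {
                    "fraction": fraction,
                    "rep": rep,
                    "seed": rep_seed,
                    "n_train": len(idx),
                    "accuracy": perf.accuracy,
                    "npv": perf.npv,
                    "specificity": perf.specificity,
                    **expl,
                }
            )
    columns = ["fraction", "rep", "seed", "n_train", "accuracy", "npv",
               "specificity", *METRIC_COLUMNS]
    per_model = pd.DataFrame(records, columns=columns)

    rows = []
    m = len(STUDY_PAIRS)
    for expl_metric, perf_metric in STUDY_PAIRS:
        sub = per_model[[expl_metric, perf_metric]].dropna()
        n = len(sub)
        try:
            r, p = pearson(sub[expl_metric], sub[perf_metric])
            note = ""
        except ValueError as exc:
            r, p, note = math.nan, math.nan, str(exc)
        rows.append(
            {
                "metric_1": _PRETTY[expl_metric],
                "metric_2": _PRETTY[perf_metric],
                "pearson_r": r,
                "p_value": p,
                "n": n,
                "bonferroni_alpha": alpha / m,
                "significant_bonferroni": bool(p < alpha / m) if not math.isnan(p) else False,
                "note": note,
            }
        )
    report = pd.DataFrame(rows)
    return report, per_model


def _stratified_fraction(y: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Per-class stratified subsample indices; at least 2 records per class."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    keep = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        k = max(2, int(round(fraction * idx.size)))
        keep.extend(rng.permutation(idx)[:k])
    return np.sort(keep)


def render_markdown(frame: pd.DataFrame, title: str = "", floatfmt: str = "%.4f") -> str:
    """Render a result grid as a small Markdown table."""
    out = frame.reset_index() if isinstance(frame.index, pd.MultiIndex) else frame
    lines = []
    if title:
        lines += [f"### {title}", ""]
    header = list(out.columns)
    lines.append("| " + " | ".join(str(h) for h in header) + " |")
    lines.append("|" + "---|" * len(header))
    for _, row in out.iterrows():
        cells = [
            floatfmt % v if isinstance(v, float) and not math.isnan(v) else str(v)
            for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
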