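"""End-to-end discovery and validation orchestration.

``run_discover`` executes the full marker-discovery chain on one dataset:
train/test split -> abundance filter (training samples only) -> ratio
features for network-connected pairs -> univariate screen -> repeated
genetic algorithm -> top-k frequency markers -> SVC training -> held-out
test evaluation.  ``run_validate`` applies a frozen model to an external
dataset: marker ratios are computed directly (a fixed panel is not
re-filtered on validation data), scored and evaluated at the frozen
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import (
    EvalReport,
    ModelBundle,
    evaluate,
    risk_score,
    score_report,
    split_train_test,
    train_model,
)
from .features import (
    ExpressionMatrix,
    FeatureMatrix,
    Unit,
    compute_errmir,
    errmir_pair_values,
    filter_low_expression,
)
from .io import RunConfig
from .network import MiRNAInteractionNetwork
from .screening import (
    FrequencyTable,
    GAConfig,
    repeat_ga,
    top_k_markers,
    univariate_screen,
)

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryBundle:
    retained: set[str]
    univariate: pd.DataFrame
    candidates: list[str]
    frequency: FrequencyTable
    markers: list[str]
    marker_pairs: list[tuple[str, str]]
    model: ModelBundle
    test_report: EvalReport
    manifest: dict


def select_markers(
    values: pd.DataFrame,
    labels: np.ndarray,
    config: RunConfig,
    fallback: str = "error",
) -> tuple[pd.DataFrame, list[str], FrequencyTable, list[str]]:
    """Univariate screen + repeated GA + top-k on any feature table.

    ``fallback="top_p"`` makes an empty candidate set fall back to the
    ``top_k`` smallest univariate p-values instead of raising, so
    comparison models on noisier feature spaces still get a panel.
    """
    if config.skip_univariate:
        table = pd.DataFrame({"feature_id": list(values.columns)})
        candidates = list(values.columns)
    else:
        table, candidates = univariate_screen(
            values,
            labels,
            alpha=config.univariate_alpha,
            fc_min=config.univariate_fc_min,
            test=config.univariate_test,
        )
    if not candidates:
        if fallback == "top_p":
            logger.warning(
                "no feature passes the univariate filter; falling back to the "
                "%d smallest p-values", config.top_k,
            )
            candidates = (
                table.sort_values(["p", "feature_id"])["feature_id"]
                .head(max(config.top_k, 2))
                .tolist()
            )
        else:
            raise ValueError(
                "no candidate features pass the univariate filter; "
                "relax alpha/fc_min or use skip_univariate"
            )
    logger.info("%d candidate features enter the GA", len(candidates))
    freq = repeat_ga(values[candidates], labels, config.ga)
    markers = top_k_markers(freq, k=config.top_k)
    return table, candidates, freq, markers


def run_discover(
    config: RunConfig,
    network: MiRNAInteractionNetwork,
    expression: ExpressionMatrix,
) -> DiscoveryBundle:
    """Full marker discovery on one (training) dataset."""
    if expression.unit is not Unit.RPM:
        raise ValueError("discovery expects RPM-normalised expression")

    features_all = compute_errmir(expression, network)
    train_fm, test_fm = split_train_test(features_all, config.split)

    # abundance filter on training samples only, frozen thereafter
    train_expr = ExpressionMatrix(
        values=expression.values.loc[train_fm.values.index],
        metadata=expression.metadata.loc[train_fm.values.index],
        unit=Unit.RPM,
    )
    retained = filter_low_expression(
        train_expr, threshold=config.filter_threshold, agg=config.filter_agg
    )
    train_features = compute_errmir(train_expr, network, retained)

    table, candidates, freq, markers = select_markers(
        train_features.values, train_features.labels, config
    )
    marker_pairs = [tuple(m.split("|")) for m in markers]

    model = train_model(
        train_features.values[markers],
        train_features.labels,
        C=config.classifier_C,
        threshold_policy=config.threshold_policy,
        seed=config.seed,
    )
    test_vals = errmir_pair_values(
        ExpressionMatrix(
            values=expression.values.loc[test_fm.values.index],
            metadata=expression.metadata.loc[test_fm.values.index],
            unit=Unit.RPM,
        ),
        marker_pairs,
    )
    test_report = evaluate(model, test_vals, test_fm.labels)

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_samples": len(expression.sample_ids),
        "n_mirnas": len(expression.mirna_ids),
        "n_edges": network.n_edges,
        "n_retained": len(retained),
        "n_candidates": len(candidates),
        "markers": markers,
    }
    return DiscoveryBundle(
        retained=retained,
        univariate=table,
        candidates=candidates,
        frequency=freq,
        markers=markers,
        marker_pairs=marker_pairs,
        model=model,
        test_report=test_report,
        manifest=manifest,
    )


def run_validate(
    model: ModelBundle,
    expression: ExpressionMatrix,
) -> EvalReport:
    """Score a frozen marker panel on an external dataset."""
    pairs = [tuple(m.split("|")) for m in model.markers]
    values = errmir_pair_values(expression, pairs)
    return evaluate(model, values, expression.labels)


def cross_batch_contrast(
    network: MiRNAInteractionNetwork,
    train_batch: ExpressionMatrix,
    valid_batch: ExpressionMatrix,
    config: RunConfig,
) -> dict[str, float]:
    """Held-out-batch AUC of ratio-feature markers vs raw-miRNA markers.

    Both marker panels are discovered on ``train_batch`` with the same
    screening procedure (univariate + repeated GA + top-k); models are then
    evaluated on ``valid_batch``, which the per-sample library factors and
    the per-miRNA protocol bias make a different measurement regime.
    """
    retained = filter_low_expression(
        train_batch, threshold=config.filter_threshold, agg=config.filter_agg
    )
    ratio_train = compute_errmir(train_batch, network, retained)
    _, _, _, ratio_markers = select_markers(
        ratio_train.values, train_batch.labels, config, fallback="top_p"
    )
    ratio_model = train_model(
        ratio_train.values[ratio_markers],
        train_batch.labels,
        C=config.classifier_C,
        threshold_policy=config.threshold_policy,
        seed=config.seed,
    )
    pairs = [tuple(m.split("|")) for m in ratio_markers]
    ratio_auc = evaluate(
        ratio_model, errmir_pair_values(valid_batch, pairs), valid_batch.labels
    ).auc

    raw_train = train_batch.values[sorted(retained)]
    _, _, _, raw_markers = select_markers(
        raw_train, train_batch.labels, config, fallback="top_p"
    )
    raw_model = train_model(
        raw_train[raw_markers],
        train_batch.labels,
        C=config.classifier_C,
        threshold_policy=config.threshold_policy,
        seed=config.seed,
    )
    raw_auc = evaluate(
        raw_model, valid_batch.values[raw_markers], valid_batch.labels
    ).auc

    return {
        "errmir_auc": float(ratio_auc),
        "raw_auc": float(raw_auc),
        "errmir_markers": ratio_markers,
        "raw_markers": raw_markers,
    }


def recovery_experiment(
    seed: int,
    sim_config=None,
    ga: GAConfig | None = None,
    fc_min: float = 0.5,
    alpha: float = 0.05,
    top: int = 10,
) -> dict:
    """Planted-pair recovery on one synthetic study.

    Simulates a study, runs abundance filtering, ratio features, the
    univariate screen and the repeated GA, and checks whether every
    planted pair ranks in the top ``top`` of the frequency table.  The
    univariate fold-change gate is set at half the planted effect (a
    selection threshold placed at the expected effect size itself would
    have only ~50% power per feature), and the GA uses a small
    subset-size penalty so that among AUC-equivalent subsets the sparser,
    stronger one wins.
    """
    from .simulate import SimConfig, simulate_study

    cfg = sim_config or SimConfig(seed=seed)
    study = simulate_study(cfg)
    pooled = study.pooled()
    retained = filter_low_expression(pooled)
    fm = compute_errmir(pooled, study.network, retained)
    _, candidates = univariate_screen(fm.values, fm.labels, alpha=alpha, fc_min=fc_min)
    ga = ga or GAConfig(
        population_size=30, generations=15, n_repeats=10,
        max_subset_penalty=0.05, seed=seed,
    )
    freq = repeat_ga(fm.values[candidates], fm.labels, ga)
    ranked = top_k_markers(freq, k=top)
    planted = set(study.truth.planted_feature_ids())
    return {
        "planted": sorted(planted),
        "top": ranked,
        "n_candidates": len(candidates),
        "recovered": planted <= set(ranked),
        "n_features": fm.values.shape[1],
    }
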