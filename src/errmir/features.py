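"""Expression normalisation and ERRmiR ratio features.

The ERRmiR feature for a network-connected pair (a, b) is the within-sample
ratio

    ERRmiR(a, b) = expr(a) / (expr(b) + 1)

on the RPM scale; the +1 offset keeps the divisor positive when miRNA_b is
undetected.  Because both expressions are measured in the same library, any
per-sample scale factor (sequencing depth, library-prep yield) cancels
almost exactly: scaling a sample by c moves log2 ERRmiR by
log2((b+1)/(b+1/c)), which is at most ~0.05 for b >= 100 and c in [1/4, 4].
That cancellation — contrasted with the full |log2 c| shift suffered by raw
expression — is what makes these features usable across batches without an
explicit batch-correction step, and is quantified by
:func:`batch_stability_report`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MiRNAInteractionNetwork

logger = logging.getLogger(__name__)

#: offset added before log2 of ratio features (ratios can be exactly 0)
LOG2_EPSILON = 2.0 ** -20


class Unit(enum.Enum):
    COUNTS = "counts"
    RPM = "rpm"


@dataclass
class ExpressionMatrix:
    """Samples x miRNAs nonnegative abundance with per-sample metadata.

    ``values``: DataFrame indexed by sample id, columns = miRNA ids.
    ``metadata``: DataFrame indexed by sample id with columns ``label``
    (0 = control, 1 = disease) and ``batch``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    unit: Unit = Unit.COUNTS

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("sample and miRNA ids must be unique")
        missing = self.values.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"metadata missing for samples: {list(missing)[:5]}")
        self.metadata = self.metadata.loc[self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def labels(self) -> np.ndarray:
        return self.metadata["label"].to_numpy()


@dataclass(frozen=True)
class ERRmiRFeature:
    numerator: str
    denominator: str
    mediators: frozenset[str]

    @property
    def feature_id(self) -> str:
        return f"{self.numerator}|{self.denominator}"


@dataclass
class FeatureMatrix:
    """Samples x ERRmiR features (raw ratio values, always finite and >= 0)."""

    values: pd.DataFrame
    features: list[ERRmiRFeature]
    metadata: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return self.metadata["label"].to_numpy()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class StabilityReport:
    """Cross-batch location shifts of raw vs ratio features (log2 scale).

    ``raw_shift`` / ``feature_shift``: per-item max absolute difference of
    per-batch medians on the log2 scale.  ``raw_quartiles`` /
    ``feature_quartiles``: per-batch 25/50/75% quantiles of the pooled
    per-sample value distributions (the quartile-plot summaries).
    """

    raw_shift: pd.Series
    feature_shift: pd.Series
    raw_quartiles: pd.DataFrame
    feature_quartiles: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        qs = [0.25, 0.5, 0.75, 0.9, 1.0]
        return pd.DataFrame(
            {
                "raw": self.raw_shift.quantile(qs),
                "errmir": self.feature_shift.quantile(qs),
            }
        )


def counts_to_rpm(
    matrix: ExpressionMatrix, totals: pd.Series | None = None
) -> ExpressionMatrix:
    """Convert counts to reads-per-million using per-sample mapped totals.

    When ``totals`` is None the per-sample sums of the matrix itself are
    used, so each sample's RPM values then sum to 1e6.  Idempotent on
    already-normalised data under that convention.
    """
    if totals is None:
        totals = matrix.values.sum(axis=1)
    else:
        totals = totals.loc[matrix.values.index]
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero/negative mapped-read total for sample(s): {list(zero.index)}")
    values = matrix.values.mul(1e6 / totals, axis=0)
    return ExpressionMatrix(values=values, metadata=matrix.metadata, unit=Unit.RPM)


def filter_low_expression(
    matrix: ExpressionMatrix,
    threshold: float = 100.0,
    agg: str = "median",
) -> set[str]:
    """miRNAs whose aggregate RPM across (training) samples >= threshold.

    The aggregation rule — median (default), mean or min — decides what
    "expression value smaller than 100" means for a vector of samples.
    """
    if matrix.unit is not Unit.RPM:
        raise ValueError("low-expression filter requires RPM-normalised data")
    if agg not in ("median", "mean", "min"):
        raise ValueError(f"unknown aggregation {agg!r}")
    stat = getattr(matrix.values, agg)(axis=0)
    retained = set(stat.index[stat >= threshold])
    if not retained:
        raise ValueError(
            f"no miRNA passes the {threshold} RPM filter; lower the threshold"
        )
    return retained


def compute_errmir(
    matrix: ExpressionMatrix,
    network: MiRNAInteractionNetwork,
    retained: set[str] | None = None,
) -> FeatureMatrix:
    """ERRmiR(a, b) = expr(a) / (expr(b) + 1) for every eligible edge.

    One feature per network edge whose endpoints are both retained (and
    present in the matrix); features ordered lexicographically by (a, b).
    """
    from .network import connected_pairs

    if retained is None:
        retained = set(matrix.mirna_ids)
    else:
        extra = retained - set(matrix.mirna_ids)
        if extra:
            raise ValueError(f"retained ids absent from matrix: {sorted(extra)[:5]}")
    pairs = connected_pairs(network, retained)
    if not pairs:
        raise ValueError("no network edge has both endpoints retained")
    feats = [ERRmiRFeature(a, b, tfs) for a, b, tfs in pairs]
    vals = matrix.values
    data = {
        f.feature_id: vals[f.numerator].to_numpy() / (vals[f.denominator].to_numpy() + 1.0)
        for f in feats
    }
    df = pd.DataFrame(data, index=vals.index)
    return FeatureMatrix(values=df, features=feats, metadata=matrix.metadata)


def errmir_pair_values(
    matrix: ExpressionMatrix, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Ratio values for an explicit marker pair list (fixed-panel scoring).

    Used on validation data, where the trained panel is applied directly
    without re-running the abundance filter.
    """
    missing = {m for pair in pairs for m in pair} - set(matrix.mirna_ids)
    if missing:
        raise ValueError(f"marker miRNAs absent from matrix: {sorted(missing)}")
    vals = matrix.values
    return pd.DataFrame(
        {
            f"{a}|{b}": vals[a].to_numpy() / (vals[b].to_numpy() + 1.0)
            for a, b in pairs
        },
        index=vals.index,
    )


def log2_ratio(values, eps: float = LOG2_EPSILON):
    """log2(ratio + eps); eps guards ratios that are exactly zero."""
    return np.log2(values + eps)


def batch_stability_report(
    matrices: list[ExpressionMatrix],
    network: MiRNAInteractionNetwork,
    threshold: float = 100.0,
    agg: str = "median",
) -> StabilityReport:
    """Compare cross-batch stability of raw expression vs ERRmiR features.

    The matrices (one or more batches; batch ids come from their metadata)
    are pooled to compute the retained miRNA set, then for every shared
    miRNA the absolute spread of per-batch medians of log2(RPM + 1), and
    for every ERRmiR feature the spread of per-batch medians of
    log2(ratio), are reported together with per-batch quartiles.
    """
    pooled_vals = pd.concat([m.values for m in matrices], axis=0, join="inner")
    pooled_meta = pd.concat([m.metadata for m in matrices], axis=0).loc[pooled_vals.index]
    batches = pooled_meta["batch"]
    if batches.nunique() < 2:
        raise ValueError("stability report needs >= 2 batches")
    for b, cnt in batches.value_counts().items():
        if cnt < 3:
            logger.warning("batch %r has only %d samples; medians will be noisy", b, cnt)

    pooled = ExpressionMatrix(values=pooled_vals, metadata=pooled_meta, unit=Unit.RPM)
    retained = filter_low_expression(pooled, threshold=threshold, agg=agg)
    fm = compute_errmir(pooled, network, retained)

    raw_log = np.log2(pooled_vals + 1.0)
    feat_log = log2_ratio(fm.values)

    def shifts(log_df: pd.DataFrame) -> pd.Series:
        med = log_df.groupby(batches).median()
        return (med.max(axis=0) - med.min(axis=0)).abs()

    def quartiles(log_df: pd.DataFrame) -> pd.DataFrame:
        rows = {}
        for b, idx in log_df.groupby(batches).groups.items():
            flat = log_df.loc[idx].to_numpy().ravel()
            rows[b] = np.quantile(flat, [0.25, 0.5, 0.75])
        return pd.DataFrame(rows, index=["q25", "q50", "q75"]).T

    return StabilityReport(
        raw_shift=shifts(raw_log[sorted(retained)]),
        feature_shift=shifts(feat_log),
        raw_quartiles=quartiles(raw_log[sorted(retained)]),
        feature_quartiles=quartiles(feat_log),
    )
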