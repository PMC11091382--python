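"""Synthetic regulatory networks and multi-batch expression data.

Emulates the structure of multi-center small-RNA-seq studies: a two-layer
regulation network (mature miRNA -> TF, TF -> precursor miRNA) composed
into a TF-mediated miRNA-miRNA network, and per-batch two-group RPM-scale
expression matrices with known ground truth.  The expression model is
log-normal:

    log2 x[i, j] = baseline[j] + biology noise
                 + label[i] * effect          (numerators of planted pairs)
                 + log2 library_factor[i]     (per-sample; cancels in ratios)
                 + protocol_bias[j, batch]    (per-miRNA per-batch; does not)

The two batch components mirror real library-preparation effects: a global
per-sample yield/depth factor, which within-sample ratios cancel, and a
smaller miRNA-specific protocol bias, which they do not.  Planted pairs are
network edges whose numerator miRNA is shifted in the disease group, so the
corresponding ratio feature carries the group signal while each individual
miRNA remains exposed to the batch terms.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import ExpressionMatrix, Unit
from .network import (
    Layer,
    MiRNAInteractionNetwork,
    NetworkCompositionError,
    RegulationRecord,
    compose_network,
    map_to_mature,
)

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    n_mirnas: int = 200
    n_tfs: int = 40
    edge_prob_mirna2tf: float = 0.015
    edge_prob_tf2mirna: float = 0.015
    n_batches: int = 2
    samples_per_group_per_batch: int = 30
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    bio_noise_sd: float = 0.5
    library_factor_range: tuple[float, float] = (0.25, 4.0)
    protocol_bias_sd: float = 0.1
    planted_pairs: int = 5
    effect_size_log2: float = 1.0
    effect_mode: str = "split"  # "split": +e/2 numerator, -e/2 denominator; "numerator": +e numerator
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.edge_prob_mirna2tf, self.edge_prob_tf2mirna):
            if not 0 <= p <= 1:
                raise ValueError("edge probabilities must be in [0, 1]")
        for sd in (self.baseline_log2_sd, self.bio_noise_sd, self.protocol_bias_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        lo, hi = self.library_factor_range
        if not 0 < lo <= hi:
            raise ValueError("library_factor_range must be positive and ordered")
        if self.n_mirnas < 1 or self.n_tfs < 1:
            raise ValueError("need at least one miRNA and one TF")
        if self.effect_mode not in ("split", "numerator"):
            raise ValueError("effect_mode must be 'split' or 'numerator'")


@dataclass
class GroundTruth:
    """What the generator planted; the recovery targets for the pipeline."""

    planted_pairs: list[tuple[str, str]]
    library_factors: dict[str, float]
    protocol_bias: dict[str, dict[str, float]]  # batch -> mirna -> log2 bias

    def planted_feature_ids(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self.planted_pairs]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_pairs": [list(p) for p in self.planted_pairs],
                "library_factors": self.library_factors,
                "protocol_bias": self.protocol_bias,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            planted_pairs=[tuple(p) for p in d["planted_pairs"]],
            library_factors=d["library_factors"],
            protocol_bias=d["protocol_bias"],
        )


def _mature_id(i: int) -> str:
    return f"miR-{i + 1}-5p"


def _precursor_id(i: int) -> str:
    return f"mir-{i + 1}"


def simulate_network(
    config: SimConfig, rng: np.random.Generator | None = None, max_retries: int = 20
) -> tuple[list[RegulationRecord], list[RegulationRecord], dict[str, list[str]]]:
    """Draw the two regulation layers and the precursor map.

    Layer 1 names mature miRNAs (miRNA -> TF, Bernoulli edges); layer 2
    names precursors (TF -> miRNA), each mapping 1:1 to its mature form in
    the precursor map.  Redraws until the composed mature network has at
    least ``planted_pairs`` edges with pairwise-disjoint endpoints.
    """
    rng = rng or np.random.default_rng(config.seed)
    matures = [_mature_id(i) for i in range(config.n_mirnas)]
    precursors = [_precursor_id(i) for i in range(config.n_mirnas)]
    tfs = [f"TF{j + 1}" for j in range(config.n_tfs)]
    pmap = {p: [m] for p, m in zip(precursors, matures)}

    for attempt in range(max_retries):
        m2t = [
            RegulationRecord(matures[i], tfs[j], Layer.MIRNA_TO_TF)
            for i in range(config.n_mirnas)
            for j in range(config.n_tfs)
            if rng.random() < config.edge_prob_mirna2tf
        ]
        t2m = [
            RegulationRecord(tfs[j], precursors[i], Layer.TF_TO_MIRNA)
            for j in range(config.n_tfs)
            for i in range(config.n_mirnas)
            if rng.random() < config.edge_prob_tf2mirna
        ]
        if not m2t or not t2m:
            continue
        try:
            net = map_to_mature(compose_network(m2t, t2m), pmap)
        except NetworkCompositionError:
            continue
        if len(_disjoint_pairs(net, config.planted_pairs)) >= config.planted_pairs:
            return m2t, t2m, pmap
    raise RuntimeError(
        f"could not realise {config.planted_pairs} disjoint composable edges in "
        f"{max_retries} draws; increase the edge probabilities"
    )


def _disjoint_pairs(
    network: MiRNAInteractionNetwork, want: int
) -> list[tuple[str, str]]:
    """Edges with pairwise-disjoint endpoints, preferring isolated ones.

    An expression shift on a planted endpoint leaks into every other ratio
    that endpoint takes part in, so pairs are planted greedily on the
    edges whose endpoints have the least additional connectivity — this
    keeps the planted feature the attributable carrier of the group
    signal instead of one of several statistically equivalent ratios.
    """
    if want <= 0:
        return []
    degree: dict[str, int] = {}
    for a, b in network.edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    ranked = sorted(
        network.edges, key=lambda e: (degree[e[0]] + degree[e[1]], e[0], e[1])
    )
    used: set[str] = set()
    chosen: list[tuple[str, str]] = []
    for a, b in ranked:
        if a in used or b in used:
            continue
        chosen.append((a, b))
        used.update((a, b))
        if len(chosen) == want:
            break
    return sorted(chosen)


def simulate_expression(
    config: SimConfig,
    network: MiRNAInteractionNetwork,
    rng: np.random.Generator | None = None,
) -> tuple[list[ExpressionMatrix], GroundTruth]:
    """Per-batch two-group RPM-scale matrices with planted ratio signals.

    Baselines are drawn once (shared across batches).  The disease effect
    on each planted pair totals ``effect_size_log2`` on the log2 ratio: in
    the default ``"split"`` mode it is applied as +e/2 to the numerator and
    -e/2 to the denominator, which makes the planted pair itself the
    strongest differential ratio (other ratios sharing one endpoint carry
    only half the effect, so exact-pair recovery is well posed); the
    ``"numerator"`` mode puts the whole shift on the numerator, in which
    case every ratio sharing that numerator is equally differential.
    Planted endpoints have their baselines floored two log2 units above
    the 100-RPM detection filter so the planted signal is never removed by
    abundance filtering by construction.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    rng = rng or np.random.default_rng(config.seed)
    mirnas = sorted(network.nodes)
    n_m = len(mirnas)

    planted = _disjoint_pairs(network, config.planted_pairs)
    if len(planted) < config.planted_pairs:
        raise ValueError(
            f"network supports only {len(planted)} disjoint planted pairs, "
            f"{config.planted_pairs} requested"
        )
    numerators = {a for a, _ in planted}
    denominators = {b for _, b in planted}
    e = config.effect_size_log2
    if config.effect_mode == "split":
        effect_vec = np.array(
            [e / 2 if m in numerators else (-e / 2 if m in denominators else 0.0) for m in mirnas]
        )
    else:
        effect_vec = np.array([e if m in numerators else 0.0 for m in mirnas])

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_m)
    # keep planted endpoints clear of the 100-RPM abundance filter
    planted_members = numerators | denominators
    floor = math.log2(100.0) + 2.0
    baseline = np.array(
        [max(b, floor) if m in planted_members else b for m, b in zip(mirnas, baseline)]
    )

    lo, hi = config.library_factor_range
    matrices: list[ExpressionMatrix] = []
    lib_factors: dict[str, float] = {}
    bias_by_batch: dict[str, dict[str, float]] = {}
    n_per = config.samples_per_group_per_batch
    for b in range(config.n_batches):
        batch_id = f"batch{b + 1}"
        bias = rng.normal(0.0, config.protocol_bias_sd, size=n_m)
        bias_by_batch[batch_id] = dict(zip(mirnas, bias.tolist()))
        sample_ids, labels, rows = [], [], []
        for label in (0, 1):
            for s in range(n_per):
                sid = f"{batch_id}_g{label}_s{s + 1}"
                lib = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
                lib_factors[sid] = lib
                log2x = (
                    baseline
                    + rng.normal(0.0, config.bio_noise_sd, size=n_m)
                    + label * effect_vec
                    + math.log2(lib)
                    + bias
                )
                rows.append(2.0 ** log2x)
                sample_ids.append(sid)
                labels.append(label)
        values = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=mirnas)
        meta = pd.DataFrame({"label": labels, "batch": batch_id}, index=sample_ids)
        matrices.append(ExpressionMatrix(values=values, metadata=meta, unit=Unit.RPM))

    truth = GroundTruth(
        planted_pairs=planted,
        library_factors=lib_factors,
        protocol_bias=bias_by_batch,
    )
    return matrices, truth


@dataclass
class SimulatedStudy:
    """One complete synthetic study: tables, network, batches, truth."""

    config: SimConfig
    mirna_to_tf: list[RegulationRecord]
    tf_to_mirna: list[RegulationRecord]
    precursor_map: dict[str, list[str]]
    network: MiRNAInteractionNetwork
    batches: list[ExpressionMatrix]
    truth: GroundTruth

    def pooled(self) -> ExpressionMatrix:
        values = pd.concat([m.values for m in self.batches], axis=0)
        meta = pd.concat([m.metadata for m in self.batches], axis=0)
        return ExpressionMatrix(values=values, metadata=meta, unit=Unit.RPM)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Network + expression in one deterministic draw from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    m2t, t2m, pmap = simulate_network(config, rng)
    network = map_to_mature(compose_network(m2t, t2m), pmap)
    batches, truth = simulate_expression(config, network, rng)
    return SimulatedStudy(
        config=config,
        mirna_to_tf=m2t,
        tf_to_mirna=t2m,
        precursor_map=pmap,
        network=network,
        batches=batches,
        truth=truth,
    )
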