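import numpy as np
import pandas as pd
import pytest

from errmir.features import ExpressionMatrix, Unit
from errmir.network import Layer, MiRNAInteractionNetwork, RegulationRecord
from errmir.simulate import SimConfig, simulate_study


def rec(reg, tgt, layer=Layer.MIRNA_TO_TF):
    return RegulationRecord(reg, tgt, layer)


def make_network(edges: dict[tuple[str, str], set[str]]) -> MiRNAInteractionNetwork:
    nodes = {n for ab in edges for n in ab}
    return MiRNAInteractionNetwork(
        nodes=nodes, edges={k: frozenset(v) for k, v in edges.items()}
    )


def make_expression(values: dict[str, list[float]], labels=None, batch="b1") -> ExpressionMatrix:
    """values: mirna_id -> per-sample vector."""
    df = pd.DataFrame(values)
    df.index = [f"s{i + 1}" for i in range(len(df))]
    n = len(df)
    meta = pd.DataFrame(
        {
            "label": labels if labels is not None else [0] * n,
            "batch": [batch] * n if isinstance(batch, str) else batch,
        },
        index=df.index,
    )
    return ExpressionMatrix(values=df, metadata=meta, unit=Unit.RPM)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared by read-only tests."""
    cfg = SimConfig(
        n_mirnas=50,
        n_tfs=14,
        edge_prob_mirna2tf=0.06,
        edge_prob_tf2mirna=0.06,
        samples_per_group_per_batch=10,
        planted_pairs=2,
        seed=11,
    )
    return simulate_study(cfg)


def random_regulation_layers(rng, n_mirnas=30, n_tfs=10, p1=0.15, p2=0.15):
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    tfs = [f"t{j}" for j in range(n_tfs)]
    l1 = [
        rec(m, t, Layer.MIRNA_TO_TF)
        for m in mirnas
        for t in tfs
        if rng.random() < p1
    ]
    l2 = [
        rec(t, m, Layer.TF_TO_MIRNA)
        for t in tfs
        for m in mirnas
        if rng.random() < p2
    ]
    return l1, l2


def brute_force_join(l1, l2):
    """Exhaustive (a, t, b) triple-loop oracle for network composition."""
    edges: dict[tuple[str, str], set[str]] = {}
    for r1 in l1:
        for r2 in l2:
            if r1.target == r2.regulator and r1.regulator != r2.target:
                edges.setdefault((r1.regulator, r2.target), set()).add(r1.target)
    return {k: frozenset(v) for k, v in edges.items()}
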