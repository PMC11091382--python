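"""Readers, writers and run configuration for all interchange files.

Everything is plain text: tab-separated tables for regulation layers,
networks, expression/feature matrices and screening outputs; JSON for
models, evaluation reports and ground truth; YAML for the run
configuration.  Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import EvalReport, ModelBundle, SplitConfig
from .features import ExpressionMatrix, FeatureMatrix, Unit
from .network import Layer, MiRNAInteractionNetwork, RegulationRecord
from .screening import FrequencyTable, GAConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# regulation tables and precursor map

def read_regulation_table(path, layer: Layer) -> list[RegulationRecord]:
    """TSV with header ``regulator<TAB>target[<TAB>source]``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"regulator", "target"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    has_src = "source" in df.columns
    return [
        RegulationRecord(
            r.regulator, r.target, layer, getattr(r, "source", None) if has_src else None
        )
        for r in df.itertuples(index=False)
    ]


def write_regulation_table(records: list[RegulationRecord], path) -> None:
    df = pd.DataFrame(
        {
            "regulator": [r.regulator for r in records],
            "target": [r.target for r in records],
            "source": [r.source or "" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_precursor_map(path) -> dict[str, list[str]]:
    """TSV ``precursor_id<TAB>mature_id``; repeated precursor rows allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["precursor_id", "mature_id"]:
        raise ValueError(f"{path}: expected columns precursor_id, mature_id")
    pmap: dict[str, list[str]] = {}
    for pre, mat in zip(df["precursor_id"], df["mature_id"]):
        pmap.setdefault(pre, [])
        if mat not in pmap[pre]:
            pmap[pre].append(mat)
    return pmap


def write_precursor_map(pmap: dict[str, list[str]], path) -> None:
    rows = [(p, m) for p in sorted(pmap) for m in pmap[p]]
    pd.DataFrame(rows, columns=["precursor_id", "mature_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network

def write_network(network: MiRNAInteractionNetwork, path) -> None:
    """TSV ``source_mirna<TAB>target_mirna<TAB>mediators`` (comma-joined)."""
    rows = [
        (a, b, ",".join(sorted(tfs)))
        for (a, b), tfs in sorted(network.edges.items())
    ]
    pd.DataFrame(rows, columns=["source_mirna", "target_mirna", "mediators"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path) -> MiRNAInteractionNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["source_mirna", "target_mirna", "mediators"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    edges = {
        (r.source_mirna, r.target_mirna): frozenset(r.mediators.split(","))
        for r in df.itertuples(index=False)
    }
    nodes = {n for ab in edges for n in ab}
    return MiRNAInteractionNetwork(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# expression / feature matrices

def read_expression(expr_path, meta_path, unit: Unit = Unit.RPM) -> ExpressionMatrix:
    """Expression TSV (rows = miRNAs, first column ``mirna_id``, columns =
    samples) plus metadata TSV ``sample_id<TAB>label<TAB>batch``."""
    values = pd.read_csv(expr_path, sep="\t", index_col="mirna_id").T
    if values.empty:
        raise ValueError(f"{expr_path}: empty expression matrix")
    meta = read_metadata(meta_path)
    missing = values.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"{meta_path}: metadata missing for samples {list(missing)[:5]}")
    return ExpressionMatrix(values=values, metadata=meta.loc[values.index], unit=unit)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    for col in ("sample_id", "label", "batch"):
        if col not in meta.columns:
            raise ValueError(f"{path}: metadata missing required column {col!r}")
    bad = set(meta["label"]) - {0, 1}
    if bad:
        raise ValueError(f"{path}: labels must be 0/1, found {sorted(bad)}")
    return meta.set_index("sample_id")


def write_expression(matrix: ExpressionMatrix, expr_path, meta_path) -> None:
    out = matrix.values.T
    out.index.name = "mirna_id"
    out.to_csv(expr_path, sep="\t")
    meta = matrix.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    out = fm.values.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_feature_values(path) -> pd.DataFrame:
    """Feature TSV back as a samples x features frame (metadata separate)."""
    return pd.read_csv(path, sep="\t", index_col="feature_id").T


# ---------------------------------------------------------------------------
# screening outputs

def write_univariate(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_frequency_table(table: FrequencyTable, path) -> None:
    s = table.as_series()
    df = pd.DataFrame({"feature_id": s.index, "count": s.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_frequency_table(path, n_repeats: int) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t")
    return FrequencyTable(
        counts=dict(zip(df["feature_id"], df["count"].astype(int))), n_repeats=n_repeats
    )


# ---------------------------------------------------------------------------
# model / report JSON

def model_to_json(bundle: ModelBundle) -> str:
    d = {
        "markers": bundle.markers,
        "log2_eps": bundle.log2_eps,
        "center": bundle.center.tolist(),
        "scale": bundle.scale.tolist(),
        "gamma": bundle.gamma,
        "support_vectors": bundle.support_vectors.tolist(),
        "dual_coef": bundle.dual_coef.tolist(),
        "intercept": bundle.intercept,
        "platt_a": bundle.platt_a,
        "platt_b": bundle.platt_b,
        "threshold": bundle.threshold,
        "C": bundle.C,
    }
    return json.dumps(d, indent=1)


def model_from_json(text: str) -> ModelBundle:
    d = json.loads(text)
    return ModelBundle(
        markers=list(d["markers"]),
        log2_eps=float(d["log2_eps"]),
        center=np.array(d["center"]),
        scale=np.array(d["scale"]),
        gamma=float(d["gamma"]),
        support_vectors=np.array(d["support_vectors"]),
        dual_coef=np.array(d["dual_coef"]),
        intercept=float(d["intercept"]),
        platt_a=float(d["platt_a"]),
        platt_b=float(d["platt_b"]),
        threshold=float(d["threshold"]),
        C=float(d["C"]),
    )


def save_model(bundle: ModelBundle, path) -> None:
    Path(path).write_text(model_to_json(bundle))


def load_model(path) -> ModelBundle:
    return model_from_json(Path(path).read_text())


def save_report(report: EvalReport, path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=1))


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Every tunable of the discovery pipeline, in one YAML-loadable bag."""

    seed: int = 0
    log_level: str = "INFO"
    join_mode: str = "chain"
    filter_threshold: float = 100.0
    filter_agg: str = "median"
    univariate_alpha: float = 0.05
    univariate_fc_min: float = 1.0
    univariate_test: str = "mannwhitney"
    skip_univariate: bool = False
    top_k: int = 3
    classifier_C: float = 1.0
    threshold_policy: str = "youden"
    split: SplitConfig = field(default_factory=SplitConfig)
    ga: GAConfig = field(default_factory=GAConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        kwargs = {}
        for sub_name, sub_cls in (("split", SplitConfig), ("ga", GAConfig)):
            if sub_name in raw:
                sub_raw = raw.pop(sub_name)
                unknown = set(sub_raw) - {f.name for f in dataclasses.fields(sub_cls)}
                if unknown:
                    raise ValueError(f"unknown {sub_name} config key(s): {sorted(unknown)}")
                kwargs[sub_name] = sub_cls(**sub_raw)
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
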