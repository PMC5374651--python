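"""Consensus features from repeated GA runs.

Single GA runs on profiles with hundreds of features are unstable: two seeds
select substantially different subsets.  The remedy is frequency pooling:
run each method N times (default 30; both methods pooled gives up to 60
runs), count how often each feature is selected (N_i), compute the mean mu
and standard deviation sigma of the counts, and keep feature i as a
*consensus candidate* when N_i >= mu - sigma.  Final models are then rebuilt
by the same GA restricted to the candidate columns.

Whether mu and sigma should include the (typically many) never-selected
features is ambiguous; counting them drags mu - sigma below zero and the
rule keeps everything.  The default scope is therefore the ever-selected
features; ``rule_scope="all_features"`` is available for comparison.
Population (divide-by-count) standard deviation is used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ga_select import GAConfig, ModelRecord, run_ga
from .profiles import FeatureMatrix

RULE_SCOPES = ("ever_selected", "all_features")


@dataclass
class ConsensusResult:
    counts: dict  # feature_id -> N_i
    mu: float
    sigma: float
    candidates: set
    n_runs: int
    rule_scope: str = "ever_selected"

    def __post_init__(self) -> None:
        self.candidates = set(self.candidates)
        bad = [
            f for f in self.candidates
            if self.counts.get(f, 0) < 1 or f not in self.counts
        ]
        if bad:
            raise ValueError(f"candidates without positive counts: {sorted(bad)}")

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["candidates"] = sorted(self.candidates)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ConsensusResult":
        with open(path) as fh:
            payload = json.load(fh)
        payload["candidates"] = set(payload["candidates"])
        return cls(**payload)

    def write_report_tsv(self, path) -> None:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        pd.DataFrame(
            [(f, n, f in self.candidates) for f, n in rows],
            columns=["feature_id", "n_selected", "candidate"],
        ).to_csv(path, sep="\t", index=False)


def count_selections(
    runs: Sequence[ModelRecord], feature_ids: Sequence[str] | None = None
) -> dict:
    """N_i = number of runs whose selected set contains feature i.

    With ``feature_ids`` (the full matrix schema) given, never-selected
    features appear with count 0; runs selecting a feature outside the schema
    are rejected as a schema mismatch.
    """
    if not runs:
        raise ValueError("no runs to count")
    counts: dict = {f: 0 for f in feature_ids} if feature_ids is not None else {}
    known = set(counts) if feature_ids is not None else None
    for rec in runs:
        for f in set(rec.feature_ids):
            if known is not None and f not in known:
                raise ValueError(
                    f"run (seed={rec.seed}) selected feature {f!r} outside the "
                    "matrix schema"
                )
            counts[f] = counts.get(f, 0) + 1
    return counts


def consensus_candidates(
    counts: dict, rule_scope: str = "ever_selected", n_runs: int | None = None
) -> ConsensusResult:
    """Apply the N_i >= mu - sigma rule over the chosen feature scope."""
    if rule_scope not in RULE_SCOPES:
        raise ValueError(f"rule_scope must be one of {RULE_SCOPES}")
    if not counts:
        raise ValueError("empty counts")
    if not any(v >= 1 for v in counts.values()):
        raise ValueError("no feature was ever selected")
    if rule_scope == "ever_selected":
        scope = {f: n for f, n in counts.items() if n >= 1}
    else:
        scope = dict(counts)
    values = np.array(list(scope.values()), dtype=float)
    mu = float(values.mean())
    sigma = float(values.std())  # population form
    threshold = mu - sigma
    candidates = {f for f, n in counts.items() if n >= 1 and n >= threshold}
    return ConsensusResult(
        counts=dict(counts),
        mu=mu,
        sigma=sigma,
        candidates=candidates,
        n_runs=int(n_runs) if n_runs is not None else int(max(counts.values())),
        rule_scope=rule_scope,
    )


def run_ensemble(
    X: FeatureMatrix,
    y: np.ndarray,
    methods: Sequence[str],
    cfg: GAConfig,
    n_runs: int = 30,
    base_seed: int | None = None,
) -> list[ModelRecord]:
    """Run each method ``n_runs`` times; ensemble run r uses seed
    base_seed + r (continuing across methods so every run is distinct)."""
    seed0 = cfg.seed if base_seed is None else base_seed
    records: list[ModelRecord] = []
    offset = 0
    for method in methods:
        for r in range(n_runs):
            records.append(
                run_ga(X, y, method, replace(cfg, seed=seed0 + offset + r))
            )
        offset += n_runs
    return records


def build_final_model(
    X: FeatureMatrix,
    y: np.ndarray,
    result: ConsensusResult,
    method: str,
    cfg: GAConfig,
) -> ModelRecord:
    """Re-run the GA restricted to consensus-candidate columns."""
    candidates = [f for f in X.feature_ids if f in result.candidates]
    if len(candidates) < cfg.min_features:
        raise ValueError(
            f"only {len(candidates)} consensus candidates; need at least "
            f"{cfg.min_features}. Consider rule_scope='all_features' or pooling "
            "more runs."
        )
    Xc = X.subset_features(candidates)
    record = run_ga(Xc, y, method, cfg)
    assert set(record.feature_ids) <= set(candidates)
    return record
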