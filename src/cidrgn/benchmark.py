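"""Monte Carlo evaluation of responsive-subnetwork identification.

Runs repeated synthetic scenarios, applies the permutation tests (SAM-GS,
GSCA, CIdrgn.1, CIdrgn.2 — all sharing the same data and permutation draws
within a replicate), and scores the decisions against ground truth.
Responsive subnetworks are the positive class (6 per replicate), common
subnetworks the negative class (4 per replicate); metrics are computed from
counts pooled across replicates (micro-average).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import METHODS, CIdrgn
from .simulate import (
    ScenarioConfig,
    ScenarioTruth,
    generate_sample_specific_scenario,
    generate_scenario,
)

__all__ = ["EvaluationReport", "confusion_metrics", "run_benchmark"]

METRICS = ("recall", "precision", "tnr", "f_measure", "accuracy")


@dataclass
class EvaluationReport:
    """Pooled benchmark metrics plus the per-replicate decision log."""

    table: pd.DataFrame  # index (scenario, method), columns METRICS + counts
    decision_log: pd.DataFrame
    n_replicates: int
    subnetwork_size: int
    mode: str

    def metric(self, scenario: int, method: str, name: str) -> float:
        return float(self.table.loc[(scenario, method), name])

    def to_tsv(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)


def _metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    total = tp + fp + tn + fn
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    tnr = tn / (tn + fp) if tn + fp else float("nan")
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else float("nan")
    )
    acc = (tp + tn) / total if total else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "tnr": tnr,
        "f_measure": f,
        "accuracy": acc,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def confusion_metrics(
    decisions: pd.DataFrame | Sequence, truth: ScenarioTruth
) -> dict[str, float]:
    """Score one replicate's decisions against its ground truth.

    `decisions` is the DataFrame returned by ``CIdrgnResults.decisions``
    (indexed by subnetwork name) or a sequence of TestDecision. Must cover
    exactly the truth's subnetworks.
    """
    if not isinstance(decisions, pd.DataFrame):
        decisions = pd.DataFrame(
            {"responsive": [d.responsive for d in decisions]},
            index=[d.subnetwork for d in decisions],
        )
    names = [s.name for s in truth.subnetworks]
    if sorted(decisions.index) != sorted(names):
        raise ValueError("decisions do not cover the truth's subnetworks")
    truth_pos = {n: l == "responsive" for n, l in zip(names, truth.labels)}
    called = decisions["responsive"]
    tp = sum(bool(called[n]) and truth_pos[n] for n in names)
    fp = sum(bool(called[n]) and not truth_pos[n] for n in names)
    fn = sum(not called[n] and truth_pos[n] for n in names)
    tn = sum(not called[n] and not truth_pos[n] for n in names)
    return _metrics_from_counts(tp, fp, tn, fn)


def run_benchmark(
    scenarios: Sequence[int] = (1, 2, 3, 4),
    subnetwork_size: int = 10,
    methods: Sequence[str] = METHODS,
    n_replicates: int = 50,
    n_permutations: int = 100,
    kappa: float = 0.05,
    mode: str = "bulk",
    p: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    lambda_rule="universal",
    edge_threshold: float = 0.0,
    bandwidth: float | None = None,
    **scenario_kwargs,
) -> EvaluationReport:
    """Replicate the simulation benchmark for a grid of scenarios.

    Each replicate generates fresh data (bulk or sample-specific per `mode`),
    fits the permutation test once, and extracts all requested methods'
    decisions from the shared permutation ensemble.
    """
    bad = [m for m in methods if m not in METHODS]
    if bad:
        raise ValueError(f"unknown methods {bad}")
    needs_networks = any(m.startswith("cidrgn") for m in methods)
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rows = []
    log_rows = []
    for scenario, sc_seed in zip(scenarios, root.spawn(len(scenarios))):
        counts = {m: np.zeros(4, dtype=int) for m in methods}  # tp fp tn fn
        for rep, rep_seed in enumerate(sc_seed.spawn(n_replicates)):
            data_seed, fit_seed = rep_seed.spawn(2)
            cfg = ScenarioConfig(
                scenario_id=scenario,
                subnetwork_size=subnetwork_size,
                p=p,
                seed=data_seed,
                **scenario_kwargs,
            )
            if mode == "sample_specific":
                dataset, truth = generate_sample_specific_scenario(cfg)
            else:
                dataset, truth = generate_scenario(cfg)
            model = CIdrgn(
                dataset,
                truth.subnetworks,
                mode=mode,
                n_permutations=n_permutations,
                kappa=kappa,
                lambda_rule=lambda_rule,
                edge_threshold=edge_threshold,
                bandwidth=bandwidth,
                compute_network_stats=needs_networks,
            )
            res = model.fit(seed=fit_seed)
            for m in methods:
                dec = res.decisions(m)
                cm = confusion_metrics(dec, truth)
                counts[m] += np.array([cm["tp"], cm["fp"], cm["tn"], cm["fn"]])
                for name, row in dec.iterrows():
                    log_rows.append(
                        {
                            "scenario": scenario,
                            "replicate": rep,
                            "method": m,
                            "subnetwork": name,
                            "p_value": row["p_value"],
                            "responsive": bool(row["responsive"]),
                            "truth": truth.labels[
                                [s.name for s in truth.subnetworks].index(name)
                            ],
                        }
                    )
        for m in methods:
            tp, fp, tn, fn = counts[m]
            rows.append(
                {"scenario": scenario, "method": m}
                | _metrics_from_counts(int(tp), int(fp), int(tn), int(fn))
            )
    table = pd.DataFrame(rows).set_index(["scenario", "method"])
    return EvaluationReport(
        table=table,
        decision_log=pd.DataFrame(log_rows),
        n_replicates=n_replicates,
        subnetwork_size=subnetwork_size,
        mode=mode,
    )
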