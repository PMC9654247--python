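"""Result serialization for the command-line workflow.

Writes, into an output directory:

* ``comparison.csv`` — one row per fitted (family, J): criterion value,
  delta, Akaike weight and (for converged fits) goodness-of-fit;
* ``mcmc_trace.csv`` — the post-burn-in chain of the selected model;
* ``summary.json`` — the selected model, parameter posterior summaries,
  goodness-of-fit and sampler diagnostics;
* ``imputed_point.csv`` / ``imputed_draws.csv`` — completed datasets
  when imputation was requested (long format with a draw index and an
  imputed-cell flag).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import MCMCTrace, summarize
from .posterior import GofResult, ImputationDraws
from .selection import ModelComparison

__all__ = ["write_report"]


def _comparison_frame(comparison: ModelComparison) -> pd.DataFrame:
    frame = comparison.to_frame()
    family = [label.rsplit("-", 1)[0] for label in comparison.labels]
    mixture = [int(label.rsplit("-", 1)[1]) for label in comparison.labels]
    frame.insert(0, "Distribution", family)
    frame.insert(1, "Mixture", mixture)
    frame = frame.drop(columns=["label"])
    frame = frame.rename(
        columns={
            comparison.criterion: comparison.criterion,
            "delta": f"Delta{comparison.criterion}",
            "weight": "AkaikeWeight",
        }
    )
    return frame


def _imputation_frame(imp: ImputationDraws) -> pd.DataFrame:
    n_draws, n = imp.completed_datasets.shape
    rows = []
    for d in range(n_draws):
        rows.append(
            pd.DataFrame(
                {
                    "draw": d,
                    "row": np.arange(1, n + 1),
                    "value": imp.completed_datasets[d],
                    "imputed": imp.unq_mask.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_report(
    out_dir,
    comparison: ModelComparison,
    selected_label: str,
    trace: MCMCTrace | None = None,
    gof_result: GofResult | None = None,
    imputations: ImputationDraws | None = None,
    extra: dict | None = None,
) -> dict:
    """Write the report files; returns the summary dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _comparison_frame(comparison).to_csv(out / "comparison.csv", index=False)

    summary: dict = {
        "selected_model": selected_label,
        "criterion": comparison.criterion,
        "weights": {
            label: float(w) for label, w in zip(comparison.labels, comparison.weights)
        },
    }
    if trace is not None:
        trace.to_frame().to_csv(out / "mcmc_trace.csv", index=False)
        table = summarize(trace)
        summary["posterior"] = {
            name: {col: float(table.loc[name, col]) for col in table.columns}
            for name in table.index
        }
        summary["acceptance_rate"] = float(trace.acceptance_rate)
        summary["burn_in"] = int(trace.burn_in)
        summary["n_iter"] = int(trace.n_iter)
    if gof_result is not None:
        summary["gof"] = float(gof_result.p_value)
    if imputations is not None:
        name = "imputed_point.csv" if imputations.mode == "point" else "imputed_draws.csv"
        _imputation_frame(imputations).to_csv(out / name, index=False)
        summary["imputation"] = {
            "mode": imputations.mode,
            "n_draws": int(imputations.completed_datasets.shape[0]),
            "n_imputed_cells": int(imputations.unq_mask.sum()),
            "file": name,
        }
    if extra:
        summary.update(extra)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
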