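"""Cohort-level tables: learning curves, condition contrasts, report bundles.

The headline cohort views are (i) the learning curve — mean total
transfer entropy TE(A->B) + TE(B->A) per trial index averaged over
pairs, which rises as dyads entrain — and (ii) per-condition contrasts
of mean total TE.  ``export_report`` writes every table as TSV plus a
machine-readable JSON summary; each table embeds the estimator settings
(m, n, k) it was computed with, so nothing in a report is ambiguous
about its estimator.
"""

from __future__ import annotations

import json
import pathlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import EstimatorConfig
from .te import TEResult, results_to_frame

__all__ = ["learning_curve", "condition_contrast", "export_report", "plot_learning_curve"]


def learning_curve(te_results: Sequence[TEResult]) -> pd.DataFrame:
    """Mean total TE per trial index across the cohort.

    Returns columns ``trial, mean_total_bits, sd_total_bits, n`` with one
    row per trial index (sorted ascending).
    """
    if not te_results:
        raise ValueError("no TE results given")
    frame = results_to_frame(te_results)
    grouped = frame.groupby("trial")["total_bits"]
    out = pd.DataFrame(
        {
            "mean_total_bits": grouped.mean(),
            "sd_total_bits": grouped.std(ddof=1),
            "n": grouped.size(),
        }
    ).reset_index()
    return out.sort_values("trial").reset_index(drop=True)


def condition_contrast(
    te_results: Sequence[TEResult], condition_labels: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Mean and SD of total TE per condition label (descriptive only).

    ``condition_labels`` optionally remaps pair_id -> label; otherwise
    each trial's own condition field is used.
    """
    if not te_results:
        return pd.DataFrame(columns=["condition", "mean_total_bits", "sd_total_bits", "n"])
    frame = results_to_frame(te_results)
    if condition_labels is not None:
        frame["condition"] = frame["pair_id"].map(condition_labels).fillna(frame["condition"])
    grouped = frame.groupby("condition")["total_bits"]
    return pd.DataFrame(
        {
            "mean_total_bits": grouped.mean(),
            "sd_total_bits": grouped.std(ddof=1),
            "n": grouped.size(),
        }
    ).reset_index()


def export_report(
    out_dir: str | pathlib.Path,
    *,
    config: EstimatorConfig,
    te_table: pd.DataFrame | None = None,
    learning: pd.DataFrame | None = None,
    conditions: pd.DataFrame | None = None,
    surrogate_table: pd.DataFrame | None = None,
    roles_table: pd.DataFrame | None = None,
    performance_table: pd.DataFrame | None = None,
    error_vs_te: pd.DataFrame | None = None,
    make_plots: bool = False,
) -> dict:
    """Write the report bundle (TSVs + JSON summary [+ optional plots]).

    Missing inputs are allowed; the JSON manifest lists which tables were
    written and which were absent.  Deterministic given its inputs.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "te_results": te_table,
        "learning_curve": learning,
        "condition_contrast": conditions,
        "surrogates": surrogate_table,
        "roles": roles_table,
        "performance": performance_table,
        "error_vs_te": error_vs_te,
    }
    estimator = {"m": config.m, "n": config.n, "k": config.k,
                 "delay": config.delay, "units": config.units,
                 "discard_samples": config.discard_samples}
    written, missing = [], []
    for name, tab in tables.items():
        if tab is None:
            missing.append(name)
            continue
        path = out / f"{name}.tsv"
        tab = tab.copy()
        with open(path, "w") as fh:
            fh.write("# estimator: " + json.dumps(estimator, sort_keys=True) + "\n")
            tab.to_csv(fh, sep="\t", index=False)
        written.append(name)
    manifest = {"estimator": estimator, "written": written, "missing": missing}
    with open(out / "report.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if make_plots and learning is not None:
        plot_learning_curve(learning, out / "learning_curve.svg")
    return manifest


def read_report_table(path: str | pathlib.Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`export_report`."""
    return pd.read_csv(path, sep="\t", comment="#")


def plot_learning_curve(learning: pd.DataFrame, path: str | pathlib.Path) -> None:
    """Plot mean total TE per trial with +-1 SD shading (convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    t = learning["trial"]
    mu = learning["mean_total_bits"]
    sd = learning["sd_total_bits"].fillna(0.0)
    ax.plot(t, mu, "o-", color="tab:blue")
    ax.fill_between(t, mu - sd, mu + sd, alpha=0.2, color="tab:blue")
    ax.set_xlabel("trial")
    ax.set_ylabel("mean total TE (bits)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
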