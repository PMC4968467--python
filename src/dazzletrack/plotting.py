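"""Figure builders: cell-mean plots and fitted-model curves.

Conventions follow the experiment's figures: one line per coloration x
contrast condition, solid lines for maximal contrast and dashed for the
lower contrast, with within-subject 95% confidence bars.
"""

from __future__ import annotations

import pandas as pd

from .stats import ModelFit, ModelSpec, build_design, within_subject_ci

__all__ = ["fig_cell_means", "fig_fitted_model"]

_COLORS = {"parallel": "tab:red", "orthogonal": "tab:blue", "binary": "tab:green"}
_STYLES = {"high": "-", "low": "--"}


def _agg_conditions(cells: pd.DataFrame, value: str) -> pd.DataFrame:
    ci = within_subject_ci(cells, value=value)
    return ci


def fig_cell_means(cells: pd.DataFrame, value: str = "mean_error_px"):
    """Participant-mean tracking error against group size, per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ci = _agg_conditions(cells, value)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for (col, con), sub in ci.groupby(["coloration", "contrast"]):
        sub = sub.sort_values("set_size")
        ax.errorbar(sub["set_size"], sub["mean"], yerr=sub["ci_halfwidth"],
                    color=_COLORS[col], linestyle=_STYLES[con],
                    marker="o" if con == "high" else "^", markersize=4,
                    capsize=2, label=f"{col}, {con} contrast")
    ax.set_xlabel("number of squares")
    ax.set_ylabel("mean tracking error (px)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def fig_fitted_model(fit: ModelFit, cells: pd.DataFrame):
    """Fitted log-error curves of a main-effects model across group size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # Predict on the rows the model was fitted to (so the orthogonal
    # polynomial basis is identical), then collapse to unique conditions.
    X, names = build_design(cells, fit.spec or ModelSpec())
    if names != fit.param_names:
        raise ValueError("fit and data design columns do not match")
    grid = cells[["set_size", "coloration", "contrast"]].copy()
    grid["fitted_log_error"] = X @ fit.params
    grid = grid.drop_duplicates(ignore_index=True)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for (col, con), sub in grid.groupby(["coloration", "contrast"]):
        sub = sub.sort_values("set_size")
        ax.plot(sub["set_size"], sub["fitted_log_error"], color=_COLORS[col],
                linestyle=_STYLES[con], label=f"{col}, {con} contrast")
    ci = within_subject_ci(cells, value="log_error")
    for (col, con), sub in ci.groupby(["coloration", "contrast"]):
        sub = sub.sort_values("set_size")
        ax.errorbar(sub["set_size"], sub["mean"], yerr=sub["ci_halfwidth"],
                    fmt="o" if con == "high" else "^", markersize=3,
                    color=_COLORS[col], capsize=2, alpha=0.6)
    ax.set_xlabel("number of squares")
    ax.set_ylabel("log tracking error")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
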