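"""Figures for Monte-Carlo sweeps: mdFDR control and power comparison."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_mdfdr", "plot_power"]

_LABELS = {
    "bonferroni": "Bonferroni (two-step)",
    "holm": "Holm (two-step)",
    "hochberg": "Hochberg (two-step)",
    "simple_bh": "simple B-H (pooled)",
}


def plot_mdfdr(sweep: pd.DataFrame, ax=None):
    """mdFDR against the number of false-null sets, one line per method/rho."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for (method, rho), grp in sweep.groupby(["method", "rho"]):
        grp = grp.sort_values("n_false_sets")
        label = _LABELS.get(method, method)
        if sweep["rho"].nunique() > 1:
            label += f", rho={rho:g}"
        ax.errorbar(
            grp["n_false_sets"], grp["mdfdr"], yerr=grp["se_mdfdr"], marker="o", label=label
        )
    alpha = sweep["alpha"].iloc[0]
    ax.axhline(alpha, color="grey", linestyle="--", linewidth=1, label=f"alpha = {alpha:g}")
    ax.set_xlabel("number of false-null sets")
    ax.set_ylabel("mdFDR")
    ax.legend(fontsize=8)
    return ax


def plot_power(sweep: pd.DataFrame, which: str = "power_i", ax=None):
    """Power (I) or (II) against the number of false-null sets."""
    if which not in ("power_i", "power_ii"):
        raise ValueError("which must be 'power_i' or 'power_ii'")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    data = sweep[sweep["n_false_sets"] > 0]
    for method, grp in data.groupby("method"):
        grp = grp.sort_values("n_false_sets")
        ax.errorbar(
            grp["n_false_sets"], grp[which], yerr=grp[f"se_{which}"],
            marker="o", label=_LABELS.get(method, method),
        )
    ax.set_xlabel("number of false-null sets")
    ax.set_ylabel("power (I)" if which == "power_i" else "power (II)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax
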