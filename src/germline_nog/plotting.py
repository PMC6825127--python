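"""Publication-style figures: Kaplan-Meier curves and group boxplots."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from ._typing import HIGH, LOW  # noqa: E402

GROUP_COLORS = {LOW: "#2166ac", HIGH: "#b2182b"}


def plot_km_curves(curves: dict[str, pd.DataFrame], path, p_value: float | None = None):
    """Step-function survival curves per risk group (low blue, high red)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in curves.items():
        ax.step(curve.index, curve.iloc[:, 0], where="post", label=group,
                color=GROUP_COLORS.get(group))
    ax.set_xlabel("Disease-free survival (months)")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.05)
    if p_value is not None:
        ax.text(0.05, 0.08, f"P = {p_value:.3g}", transform=ax.transAxes)
    ax.legend(title="risk group", frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_group_boxes(feature_matrix: pd.DataFrame, calls, path, max_features: int = 12):
    """Side-by-side low/high boxplots per feature row (metagenes, burden...)."""
    call = calls["call"] if isinstance(calls, pd.DataFrame) else pd.Series(calls)
    lo = [s for s in feature_matrix.columns if call.get(s) == LOW]
    hi = [s for s in feature_matrix.columns if call.get(s) == HIGH]
    feats = list(feature_matrix.index[:max_features])
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(feats)), 4))
    positions, data, colors = [], [], []
    for i, f in enumerate(feats):
        data += [feature_matrix.loc[f, lo].dropna(), feature_matrix.loc[f, hi].dropna()]
        positions += [3 * i, 3 * i + 1]
        colors += [GROUP_COLORS[LOW], GROUP_COLORS[HIGH]]
    boxes = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
    for patch, color in zip(boxes["boxes"], colors):
        patch.set_facecolor(color)
        patch.set_alpha(0.6)
    ax.set_xticks([3 * i + 0.5 for i in range(len(feats))])
    ax.set_xticklabels(feats, rotation=45, ha="right")
    ax.set_ylabel("value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
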