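"""Matplotlib figures: complexity-entropy plane, step responses, ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ari import StepResponse
from .complexity import ComplexityPoint
from .stats import RocResult


def complexity_entropy_plane(points_by_group: dict[str, list[ComplexityPoint]], ax=None):
    """Scatter of (H_norm, C) per group with one marker style per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    markers = ["o", "^", "s", "d", "v"]
    for (label, points), marker in zip(points_by_group.items(), markers):
        hs = [p.H_norm for p in points]
        cs = [p.C for p in points]
        ax.scatter(hs, cs, marker=marker, label=label, alpha=0.8)
    ax.set_xlabel("normalized entropy $H$")
    ax.set_ylabel("statistical complexity $C$")
    ax.legend()
    return ax


def step_responses(responses: list[StepResponse], ax=None):
    """Overlay normalized flow responses to the negative pressure step."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for resp in responses:
        t, v = resp.post_step()
        label = f"grade {resp.grade}" if resp.grade is not None else "model"
        ax.plot(t, v, label=label, lw=1)
    ax.set_xlabel("time after step [s]")
    ax.set_ylabel("normalized BFV")
    ax.legend(fontsize=7, ncol=2)
    return ax


def roc_curves(rocs: dict[str, RocResult], ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for label, roc in rocs.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{label} (AUC={roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    return ax
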