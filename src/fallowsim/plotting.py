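"""Optional renderings of experiment reports (box plots, index pies).

Plots are presentation only; nothing downstream consumes them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_ua_box(reports, ax=None):
    """Box plot of the output distributions of one or more experiments."""
    ax = ax or plt.gca()
    data, labels = [], []
    for rep in reports:
        if rep.evaluated is None:
            raise ValueError(f"report {rep.config.name} carries no raw outputs")
        data.append(rep.evaluated.mc_sample)
        labels.append(rep.config.name)
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("fallow area (map units)")
    return ax


def plot_index_pies(report, axes=None):
    """Side-by-side pies of the S shares (with the interaction share) and
    the normalized ST shares."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 4))
    sens = report.sens
    s = sens.S.clip(min=0)
    labels = list(sens.factor_names)
    i_share = max(sens.I, 0.0)
    axes[0].pie(list(s) + [i_share], labels=labels + ["I"], autopct="%.0f%%")
    axes[0].set_title("first-order shares S")
    st = sens.ST.clip(min=0)
    axes[1].pie(st, labels=labels, autopct="%.0f%%")
    axes[1].set_title("total effects ST (normalized)")
    return axes
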