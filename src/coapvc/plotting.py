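"""Plot hooks for TACs and validation results (optional convenience)."""

from __future__ import annotations

from .tac import TimeActivityCurve

__all__ = ["plot_tacs"]


def plot_tacs(curves: dict[str, TimeActivityCurve], ax=None, title: str | None = None):
    """Plot labelled TACs against frame midpoints; returns the axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for label, tac in curves.items():
        ax.plot(tac.midpoints, tac.values, marker="o", ms=3, label=label)
    ax.set_xlabel("time (s)")
    units = {t.unit for t in curves.values()}
    ax.set_ylabel(" / ".join(sorted(units)))
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
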