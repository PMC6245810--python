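"""Convenience plotting of cumulative-risk curves (optional extra).

Requires matplotlib (install the ``plot`` extra). Step curves are drawn
with post-steps, smooth parametric curves as lines, each with a shaded
95% confidence band.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .nonparametric import RiskCurve

__all__ = ["plot_risk_curves"]


def plot_risk_curves(
    curves: Iterable[RiskCurve],
    labels: Optional[Sequence[str]] = None,
    ax=None,
    shade: bool = True,
):
    """Plot one or more risk curves with confidence bands.

    Returns the matplotlib Axes. Nonparametric curves render as
    right-continuous steps, parametric ones as smooth lines.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    curves = list(curves)
    if labels is None:
        labels = [c.kind for c in curves]
    for curve, label in zip(curves, labels):
        step = curve.kind == "nonparametric"
        kwargs = {"where": "post"} if step else {}
        draw = ax.step if step else ax.plot
        (line,) = draw(curve.times, curve.risk, label=label, **kwargs)
        if shade:
            fill = {"step": "post"} if step else {}
            ax.fill_between(
                curve.times,
                curve.cl_lower,
                curve.cl_upper,
                alpha=0.18,
                color=line.get_color(),
                **fill,
            )
    ax.set_xlabel("years of follow-up")
    ax.set_ylabel("cumulative risk")
    ax.set_ylim(bottom=0)
    ax.legend()
    return ax
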