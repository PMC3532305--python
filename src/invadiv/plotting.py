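"""Figure helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .pst import PstCurve

__all__ = ["plot_pst_curve"]


def plot_pst_curve(curve: PstCurve, ax=None):
    """P_ST (with 95% CI band) against the c/h^2 ratio, the F_ST upper
    bound as a horizontal line and the c = h^2 null as a vertical line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.ratios, curve.pst, "k-", label="$P_{ST}$")
    ax.plot(curve.ratios, curve.lower, "k--", lw=0.8)
    ax.plot(curve.ratios, curve.upper, "k--", lw=0.8, label="95% CI")
    ax.axhline(curve.fst_interval[1], color="red",
               label="$F_{ST}$ upper 95% CI")
    ax.axvline(1.0, color="red", ls="--", lw=0.8, label="$c = h^2$")
    if curve.critical_ratio is not None:
        ax.axvline(curve.critical_ratio, color="grey", ls=":",
                   label=f"critical $c/h^2$ = {curve.critical_ratio:.2f}")
    ax.set_xlabel("$c/h^2$")
    ax.set_ylabel("$P_{ST}$")
    title = curve.trait if curve.sex is None else f"{curve.trait} ({curve.sex})"
    ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
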