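"""Plot helpers: the HR-by-age curve and curve/profile overlays.

Colour convention: red for ages significant at p < alpha, green otherwise;
the dotted line marks the female reference (HR = 1) and the dashed line the
pooled unstratified male HR when supplied.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .curves import AgeProfile, HRCurve  # noqa: E402

__all__ = ["plot_hr_curve", "plot_overlay"]


def plot_hr_curve(curve: HRCurve, pooled_hr: float | None = None, ax=None,
                  path=None):
    """Per-age HR with CI bars, significance-coloured."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4.5))
    d = curve.frame[curve.defined]
    sig = d["significant"].astype(bool)
    for mask, color, label in ((sig, "red", "significant"),
                               (~sig, "green", "not significant")):
        sub = d[mask]
        ax.errorbar(sub["age"], sub["hr"],
                    yerr=[sub["hr"] - sub["lo"], sub["hi"] - sub["hr"]],
                    fmt="o", ms=3, color=color, ecolor=color, alpha=0.8,
                    elinewidth=0.7, label=label)
    ax.axhline(1.0, ls=":", color="k", lw=1)
    if pooled_hr is not None:
        ax.axhline(pooled_hr, ls="--", color="k", lw=1,
                   label=f"pooled HR {pooled_hr:.3f}")
    ax.set_xlabel("age at diagnosis (years)")
    ax.set_ylabel("male vs female HR")
    ax.legend(loc="upper right", fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_overlay(curve: HRCurve, profile: AgeProfile, path=None):
    """Double-y overlay of the HR curve and one variable's age profile."""
    fig, ax = plt.subplots(figsize=(9, 4.5))
    d = curve.frame[curve.defined]
    ax.plot(d["age"], d["hr"], color="red", lw=1.5, label="HR")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("male vs female HR", color="red")
    ax2 = ax.twinx()
    ax2.plot(profile.ages, profile.values, color="green", lw=1.5,
             label=f"{profile.variable} ({profile.sex})")
    ax2.set_ylabel(f"{profile.variable}, per-age median", color="green")
    fig.legend(loc="upper right", fontsize=8)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax, ax2
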