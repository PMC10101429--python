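"""Best-effort effect plots (requires the optional matplotlib dependency)."""

from __future__ import annotations

from .model import APCFit


def plot_effects(fit: APCFit, ax=None):
    """Age curve plus period/cohort relative risks with 95% CI ribbons.

    Returns the three axes; never used by the analysis itself.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, axes = plt.subplots(1, 3, figsize=(12, 4))
    else:
        axes = ax
    panels = (
        (fit.age_curve, "rate_per_100000", "age midpoint", "rate per 100,000", None),
        (fit.period_rr, "rr", "period midpoint", "relative risk", 1.0),
        (fit.cohort_rr, "rr", "cohort midpoint", "relative risk", 1.0),
    )
    for a, (df, col, xlab, ylab, hline) in zip(axes, panels):
        a.plot(df["midpoint"], df[col], color="C0")
        a.fill_between(df["midpoint"], df["lo95"], df["hi95"], alpha=0.25, color="C0")
        if hline is not None:
            a.axhline(hline, color="grey", lw=0.8, ls="--")
        a.set_xlabel(xlab)
        a.set_ylabel(ylab)
        a.set_yscale("log")
    axes[0].set_title(f"{fit.label} (drift {fit.drift:.4f})")
    return axes
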