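"""Optional matplotlib helpers for slope-vs-radius summaries."""

from __future__ import annotations


def plot_slope_vs_radius(summaries, ax=None):
    """Median standardized slope vs radius per diversity form.

    Error bars span the 25th-75th percentiles; whisker caps mark the
    2.5th/97.5th. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    forms = sorted({s.form for s in summaries})
    offsets = {f: (i - (len(forms) - 1) / 2) * 0.04 for i, f in enumerate(forms)}
    for form in forms:
        ss = sorted((s for s in summaries if s.form == form), key=lambda s: s.radius_km)
        r = [s.radius_km * (1 + offsets[form]) for s in ss]
        med = [s.slope_percentiles[50] for s in ss]
        lo = [s.slope_percentiles[50] - s.slope_percentiles[25] for s in ss]
        hi = [s.slope_percentiles[75] - s.slope_percentiles[50] for s in ss]
        ax.errorbar(r, med, yerr=[lo, hi], marker="o", capsize=3, label=form)
    ax.axhline(0.0, color="grey", lw=0.8, ls=":")
    ax.set_xscale("log")
    ax.set_xlabel("neighbourhood radius (km)")
    ax.set_ylabel("standardized slope (SD of diversity per m of elevation SD)")
    ax.legend(title="diversity form")
    return ax
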