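"""Figure helpers for the standard diagnostics and trend surfaces.

Kept deliberately small: each function draws one canonical figure onto a
matplotlib Axes and returns it, so scripts can compose or save them.
"""

from __future__ import annotations

from .diagnostics import KdeSurface, Semivariogram


def plot_trend_surfaces(surfaces, ax=None, label_years=True):
    """Predicted date vs elevation with 95% bands, one line per year.

    ``surfaces`` is the output of :func:`snowphen.trend.trend_surfaces`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for year, g in surfaces.groupby("year"):
        g = g.sort_values("elevation")
        line, = ax.plot(g.elevation, g["mean"],
                        label=f"{year:.0f}" if label_years else None)
        ax.fill_between(g.elevation, g.lower, g.upper, alpha=0.2,
                        color=line.get_color())
    ax.set_xlabel("elevation (m asl)")
    ax.set_ylabel("day of year")
    if label_years:
        ax.legend(title="year")
    return ax


def plot_kde_comparison(observer: KdeSurface, brood: KdeSurface, ax=None):
    """95% highest-density contours of observer vs brood distributions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for surf, color, label in ((observer, "tab:grey", "observers"),
                               (brood, "tab:orange", "broods")):
        ax.contour(surf.x_grid, surf.y_grid, surf.density,
                   levels=[surf.hdr_threshold], colors=[color])
        ax.plot([], [], color=color, label=label)
    ax.set_xlabel("day of year")
    ax.set_ylabel("elevation (m asl)")
    ax.legend()
    return ax


def plot_semivariogram(sv: Semivariogram, ax=None):
    """Average semi-variance per distance class with the pooled sill."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = sv.counts > 0
    ax.plot(sv.midpoints[ok], sv.gamma[ok], "o-")
    ax.axhline(sv.sill, ls="--", color="grey", label="sill")
    ax.set_xlabel("distance (km)")
    ax.set_ylabel("semi-variance (days$^2$)")
    ax.set_ylim(bottom=0)
    ax.legend()
    return ax


def plot_partial_effect(curve, variable: str, unit: str = "", ax=None):
    """Partial-effect curve with its 95% compatibility band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.value, curve["mean"], color="tab:blue")
    ax.fill_between(curve.value, curve.lower, curve.upper, alpha=0.25,
                    color="tab:blue")
    xlabel = f"{variable} ({unit})" if unit else variable
    ax.set_xlabel(xlabel)
    ax.set_ylabel("hatching date (day of year)")
    return ax


def save_axes(ax, path) -> None:
    import matplotlib.pyplot as plt

    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
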