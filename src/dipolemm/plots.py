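"""Plot helpers for the analysis products (heat-capacity curves, RDFs,
probe-distance time series, hydrogen-bond histograms)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_heat_capacity(curve, path, per_molecule: int = 0):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    cv = curve.per_molecule(per_molecule) if per_molecule else curve.cv
    ax.plot(curve.temperatures, cv, "o-", ms=4)
    ax.axvline(curve.peak_temperature, ls="--", color="grey", lw=1)
    ax.set_xlabel("T (K)")
    ax.set_ylabel("C$_V$ (kcal mol$^{-1}$ K$^{-1}$"
                  + (" per molecule)" if per_molecule else ")"))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rdf_windows(results, path):
    """Overlay RDFResult objects from successive time windows."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for res in results:
        ax.plot(res.r, res.g, lw=1,
                label=f"{res.window[0]:g}-{res.window[1]:g} ps")
    ax.set_xlabel("r (Å)")
    ax.set_ylabel("g(r)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_probe_series(times, values, path, r_probe: float = 3.65):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(times, values, "o-", ms=4)
    ax.set_xlabel("t (ps)")
    ax.set_ylabel(f"g({r_probe:g} Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_hb_histogram(hist, path):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    centers = 0.5 * (hist.edges[:-1] + hist.edges[1:])
    ax.bar(centers, hist.counts, width=hist.edges[1] - hist.edges[0],
           align="center")
    ax.axvline(hist.cutoff, ls="--", color="red", lw=1)
    ax.set_xlabel("r(N···H$_O$) (Å)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
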