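"""Figure helpers: degree histograms, local restitution curves,
space-time sections and voltage snapshots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .link_topology import LinkSet, degree_histogram  # noqa: E402

__all__ = ["plot_degree_histogram", "plot_restitution_curves",
           "plot_space_time", "plot_snapshot"]


def plot_degree_histogram(links: LinkSet, ax=None, **meta_label):
    """Fraction of fibroblast units per attachment count."""
    ax = ax or plt.figure(figsize=(4, 3)).add_subplot()
    hist = degree_histogram(links)
    ax.bar(list(hist.keys()), list(hist.values()), color="tab:blue")
    ax.set_xlabel("attached grid points per unit")
    ax.set_ylabel("fraction of units")
    lam = links.meta.get("lambda")
    lmax = links.meta.get("lmax_mm")
    if lam is not None:
        ax.set_title(f"$\\lambda$ = {lam}, $L_{{max}}$ = {lmax} mm")
    return ax


def plot_restitution_curves(curves, ax=None, cl_col="cl_n",
                            apd_col="apd_next"):
    """Local CL_n vs APD_{n+1} curves, one line per sampling-line cell."""
    ax = ax or plt.figure(figsize=(4.5, 3.5)).add_subplot()
    for cell, sub in curves.groupby("cell"):
        sub = sub.sort_values(cl_col)
        color = "tab:red" if sub["in_border_zone"].iloc[0] else "0.6"
        ax.plot(sub[cl_col], sub[apd_col], color=color, lw=0.8, alpha=0.7)
    ax.set_xlabel("$CL_n$ (ms)")
    ax.set_ylabel("$APD_{n+1}$ (ms)")
    return ax


def plot_space_time(t, section, dx_mm=0.25, ax=None):
    """Voltage along the sampling line vs time (space-time section)."""
    ax = ax or plt.figure(figsize=(6, 3)).add_subplot()
    section = np.asarray(section)
    im = ax.imshow(section.T, aspect="auto", origin="lower",
                   extent=[t[0], t[-1], 0, section.shape[1] * dx_mm],
                   cmap="turbo", vmin=-90, vmax=40)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("position along line (mm)")
    plt.colorbar(im, ax=ax, label="V (mV)")
    return ax


def plot_snapshot(v_field, dx_mm=0.25, ax=None, t_ms=None):
    ax = ax or plt.figure(figsize=(4, 4)).add_subplot()
    n, m = v_field.shape
    im = ax.imshow(v_field, origin="lower", cmap="turbo", vmin=-90, vmax=40,
                   extent=[0, m * dx_mm, 0, n * dx_mm])
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if t_ms is not None:
        ax.set_title(f"t = {t_ms:.0f} ms")
    plt.colorbar(im, ax=ax, label="V (mV)")
    return ax
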