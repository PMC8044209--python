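"""Matplotlib helpers for the standard figures of a fuzzy-complex analysis."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np


def plot_profile(profile_df, value: str, err: str | None = None, ax=None, **kwargs):
    """Per-residue bar profile (CSP, SSP delta, T1/T2, PRE ratio...)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    x = profile_df["residue_index"]
    ax.bar(x, profile_df[value],
           yerr=profile_df[err] if err else None, width=0.8, **kwargs)
    ax.set_xlabel("residue")
    ax.set_ylabel(value)
    return ax


def plot_energy_boxes(scan, term: str = "pre_ten_lowest", ax=None):
    """Box plot of ensemble energies vs. number of states.

    Boxes span the 25th-75th percentile with a median midline; whiskers extend
    at most 1.5×IQR beyond the box.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    sizes = sorted(scan.models)
    key = {"total": "total_energy", "pre": "pre_energy",
           "pre_ten_lowest": "pre_energy"}[term]
    data = []
    for s in sizes:
        vals = np.array([getattr(m, key) for m in scan.models[s]])
        if term == "pre_ten_lowest":
            vals = np.sort(vals)[:10]
        data.append(vals)
    ax.boxplot(data, tick_labels=[str(s) for s in sizes], whis=1.5)
    ax.set_xlabel("ensemble members")
    ax.set_ylabel(f"{term} energy")
    ax.set_yscale("log")
    return ax
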