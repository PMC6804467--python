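"""Static summary figures: CI distributions and genome-wide LOD tracks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["ci_boxplot", "lod_plot"]


def ci_boxplot(ci_table: pd.DataFrame, ax=None, path=None):
    """Boxplots of combination-index values per dose pair across cell lines.

    ``ci_table`` is the TSV written by the pipeline (columns dose1, dose2,
    ci). The horizontal line at CI = 1 separates synergy (below) from
    antagonism (above).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sub = ci_table.dropna(subset=["ci"])
    groups = sub.groupby(["dose1", "dose2"], sort=True)["ci"]
    labels = [f"{d1:g}+{d2:g}" for (d1, d2), _ in groups]
    ax.boxplot([g.to_numpy() for _, g in groups], tick_labels=labels)
    ax.axhline(1.0, color="red", lw=1)
    ax.set_xlabel("dose pair (µM)")
    ax.set_ylabel("combination index")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def lod_plot(scan_table: pd.DataFrame, lod_threshold: float = 3.0, ax=None,
             path=None):
    """LOD score along the genome, one panel-wide track with chromosome
    boundaries and the reporting threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    offset = 0.0
    for chrom, sub in scan_table.groupby("chromosome"):
        pos = sub["position_cM"].to_numpy()
        ax.plot(pos + offset, sub["lod"].to_numpy(), lw=1,
                label=f"chr {chrom}")
        offset += pos.max() + 10.0
        ax.axvline(offset - 5.0, color="0.8", lw=0.5)
    ax.axhline(lod_threshold, color="red", lw=1, ls="--")
    ax.set_xlabel("genome position (cM, chromosomes concatenated)")
    ax.set_ylabel("LOD")
    ax.set_ylim(bottom=0)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
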