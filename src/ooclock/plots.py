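"""Figure writers: Manhattan plot of the aging EWAS and cross-tissue sector plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datamodel import CpGAnnotation


def manhattan_plot(ewas: pd.DataFrame, annotation: CpGAnnotation, path,
                   p_threshold: float = 1e-4) -> None:
    """−log10(p) by genomic position; gains red, losses blue."""
    df = annotation.df.set_index("probe_id").join(ewas, how="inner").dropna(subset=["p"])
    chroms = sorted(df["chromosome"].unique(), key=lambda c: (len(c), c))
    offset, xs, ticks = 0, [], []
    fig, ax = plt.subplots(figsize=(10, 3.2))
    for chrom in chroms:
        sub = df[df["chromosome"] == chrom].sort_values("position")
        x = offset + sub["position"].to_numpy()
        colors = np.where(sub["z"] > 0, "tab:red", "tab:blue")
        ax.scatter(x, -np.log10(sub["p"]), s=4, c=colors, linewidths=0)
        ticks.append((offset + x[-1]) / 2 if len(x) else offset)
        offset = x[-1] + 1 if len(x) else offset
    ax.axhline(-np.log10(p_threshold), color="red", ls=":", lw=1)
    ax.set_xticks(ticks, chroms, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sector_plot(ewas_blood: pd.DataFrame, ewas_oocyte: pd.DataFrame, path,
                p_threshold: float = 1e-4) -> None:
    """Blood Z vs oocyte Z; divergent significant probes highlighted."""
    z = pd.DataFrame(
        {"blood": ewas_blood["z"], "oocyte": ewas_oocyte["z"].reindex(ewas_blood.index),
         "pb": ewas_blood["p"], "po": ewas_oocyte["p"].reindex(ewas_blood.index)}
    ).dropna()
    from scipy import stats

    zcrit = stats.norm.isf(p_threshold / 2)
    div = (z["pb"] < p_threshold) & (z["po"] < p_threshold) & (
        np.sign(z["blood"]) != np.sign(z["oocyte"])
    )
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(z["blood"], z["oocyte"], s=4, c="0.6", linewidths=0)
    ax.scatter(z.loc[div, "blood"], z.loc[div, "oocyte"], s=10, c="tab:blue")
    for v in (-zcrit, zcrit):
        ax.axvline(v, color="red", lw=0.8)
        ax.axhline(v, color="red", lw=0.8)
    ax.set_xlabel("blood Z")
    ax.set_ylabel("oocyte Z")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
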