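"""Matplotlib renderings of the QQ and Manhattan data tables."""

from __future__ import annotations


def plot_qq(qq_table, ax=None):
    """Observed-vs-expected -log10 p with the 95% null band shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x = qq_table["expected_neglog10"]
    ax.fill_between(
        x, qq_table["band_low_neglog10"], qq_table["band_high_neglog10"],
        color="0.85", label="95% null band",
    )
    lim = max(x.max(), qq_table["observed_neglog10"].max())
    ax.plot([0, lim], [0, lim], color="k", lw=1)
    ax.plot(x, qq_table["observed_neglog10"], ".", ms=3, color="C0")
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    return ax


def plot_manhattan(man_table, ax=None, genomewide_p=5e-8, suggestive_p=5e-6):
    import numpy as np
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    for i, (_, sub) in enumerate(man_table.groupby("chrom", sort=True)):
        ax.plot(sub["cum_pos"], sub["neglog10_p"], ".", ms=2, color=f"C{i % 2}")
    for p, style in ((genomewide_p, "-"), (suggestive_p, "--")):
        ax.axhline(-np.log10(p), color="r", ls=style, lw=0.8)
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax
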