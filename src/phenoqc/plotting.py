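"""Heatmap of the signed-significance grid.

One panel per symptom domain; rows are the data-quality covariates,
columns the lag in weeks.  Cell colour encodes the signed -log10
p-value (blue positive, red negative); unadjusted significance at
p < 0.05 gets a dashed border, FDR-adjusted significance a solid one.
"""

from __future__ import annotations

import numpy as np

COVARIATE_LABELS = {"A": "Acc", "G": "GPS", "V": "View", "C": "Sub", "T": "Comp"}


def plot_significance_grid(grid, vmax: float | None = None, figsize=None):
    """Render a :class:`~phenoqc.model.SignificanceGrid`; returns the figure."""
    import matplotlib.pyplot as plt

    frame = grid.frame
    domains = sorted(frame["domain"].dropna().unique())
    lags = sorted(frame["lag"].dropna().unique())
    covs = [c for c in COVARIATE_LABELS if c in set(frame["covariate"])]
    covs += sorted(set(frame["covariate"]) - set(covs))
    if vmax is None:
        vmax = max(float(np.nanmax(np.abs(frame["signed_neglog10p"]))), 1.0)

    fig, axes = plt.subplots(
        1, max(len(domains), 1), figsize=figsize or (3 * len(domains) + 1, 3), squeeze=False
    )
    for ax, domain in zip(axes[0], domains):
        sub = frame[frame["domain"] == domain]
        mat = np.full((len(covs), len(lags)), np.nan)
        for _, row in sub.iterrows():
            mat[covs.index(row["covariate"]), lags.index(row["lag"])] = row[
                "signed_neglog10p"
            ]
        im = ax.imshow(mat, cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto")
        for _, row in sub.iterrows():
            if not (row["significant_raw"] or row["significant_fdr"]):
                continue
            i, j = covs.index(row["covariate"]), lags.index(row["lag"])
            style = "solid" if row["significant_fdr"] else "dashed"
            ax.add_patch(
                plt.Rectangle(
                    (j - 0.5, i - 0.5), 1, 1, fill=False, edgecolor="black",
                    linestyle=style, linewidth=1.5,
                )
            )
        ax.set_title(domain)
        ax.set_xticks(range(len(lags)), [str(l) for l in lags])
        ax.set_yticks(range(len(covs)), [COVARIATE_LABELS.get(c, c) for c in covs])
        ax.set_xlabel("lag (weeks)")
    fig.colorbar(im, ax=axes[0], shrink=0.8, label="signed $-\\log_{10} p$")
    return fig
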