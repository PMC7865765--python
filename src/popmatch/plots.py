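"""Visual inspection: congener scatter with blank reference lines, similarity
heatmap, and PCA projection of normalized patterns."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from sklearn.decomposition import PCA

from popmatch.preprocessing import BlankStats, NormalizedProfile
from popmatch.profiles import CongenerProfile, ProfileValidationError


def plot_patterns(
    profiles: Sequence[CongenerProfile],
    stats: BlankStats,
    path: str | Path,
    kind: str = "concentration",
) -> Path:
    """Per-congener scatter of sample values with two blank reference lines.

    The red line is the per-congener maximum over the blank collection; the
    magenta line is mean + multiplier x SD (the censoring threshold).
    """
    idx = stats.lookup(profiles[0].congeners)
    if kind == "concentration":
        ref_max, ref_thr = stats.conc_max[idx], stats.conc_threshold[idx]
        ylabel = "Concentration (pg/g)"
    else:
        ref_max, ref_thr = stats.teq_max[idx], stats.teq_threshold[idx]
        ylabel = "TEQ (pg-TEQ/g)"

    x = np.arange(len(profiles[0].congeners))
    fig, ax = plt.subplots(figsize=(max(8, 0.5 * len(x)), 5))
    for p in profiles:
        y = p.concentration if kind == "concentration" else p.teq
        ax.scatter(x, y, s=18, alpha=0.7, label=p.sample_id)
    ax.plot(x, ref_max, color="red", lw=1.5, label="blank max")
    ax.plot(
        x, ref_thr, color="magenta", lw=1.5,
        label=f"blank mean + {stats.censor_multiplier:g} SD",
    )
    ax.set_xticks(x)
    ax.set_xticklabels(profiles[0].congeners, rotation=90, fontsize=7)
    ax.set_ylabel(ylabel)
    if len(profiles) <= 12:
        ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_heatmap(
    matrix: pd.DataFrame,
    path: str | Path,
    cmap: str = "RdYlGn",
) -> Path:
    """Heatmap of an all-vs-all similarity matrix."""
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(matrix)),) * 2)
    sns.heatmap(
        matrix, vmin=0.0, vmax=1.0, cmap=cmap, square=True,
        annot=len(matrix) <= 12, fmt=".2f", ax=ax,
        cbar_kws={"label": "similarity score"},
    )
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def pca_projection(
    profiles: Sequence[NormalizedProfile],
    image_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> pd.DataFrame:
    """First two principal components of the normalized pattern matrix.

    The matrix is centered but not re-scaled (every pattern already lives on
    [0, 1]).  Returns a DataFrame indexed by sample id with columns
    ``PC1``/``PC2``; optionally writes the scatter and coordinates.
    """
    if len(profiles) < 3:
        raise ProfileValidationError("PCA projection needs at least 3 profiles")
    X = np.vstack([p.values for p in profiles])
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    df = pd.DataFrame(
        coords, columns=["PC1", "PC2"], index=[p.sample_id for p in profiles]
    )
    df.index.name = "sample_id"

    if csv_path is not None:
        df.to_csv(csv_path)
    if image_path is not None:
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(df["PC1"], df["PC2"], s=30)
        for sid, row in df.iterrows():
            ax.annotate(sid, (row["PC1"], row["PC2"]), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
        var = pca.explained_variance_ratio_
        ax.set_xlabel(f"PC1 ({var[0]:.0%} variance)")
        ax.set_ylabel(f"PC2 ({var[1]:.0%} variance)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return df
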