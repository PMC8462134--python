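"""Static figures and the misclassification back-mapping report.

Every figure function also writes the data table behind the plot as CSV
(next to the figure file), so the computation is testable and reusable
without comparing pixels.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import AlignmentError, ParameterError
from .segments import AXIS_NAMES, SegmentDataset, order_by_label
from .selection import SelectionResult

__all__ = [
    "selection_accuracy_figure",
    "grouped_feature_figure",
    "misclassification_report",
    "embed_2d",
    "embedding_figure",
]


def _companion_csv(path: Path) -> Path:
    return path.with_suffix(".csv")


def selection_accuracy_figure(sel: SelectionResult, path: str | Path) -> pd.DataFrame:
    """Bar/line figure of the stepwise-forward-selection accuracy trajectory.

    Gray bars show each selected feature's *individual* accuracy (its
    round-1, single-feature score); the red line shows the *cumulative* best
    accuracy per round.  A plateau in the line indicates that further
    features add little.  Returns (and writes as CSV) the underlying table.
    """
    if not sel.selected:
        raise ParameterError("selection result holds no selected features")
    path = Path(path)
    table = pd.DataFrame(
        {
            "round": np.arange(1, len(sel.selected) + 1),
            "feature": sel.selected,
            "individual_accuracy": sel.individual_accuracies(),
            "cumulative_accuracy": sel.best_per_round,
        }
    )
    fig, ax = plt.subplots(figsize=(1.2 * len(sel.selected) + 2, 4))
    ax.bar(table["round"], table["individual_accuracy"], color="0.7", label="individual")
    ax.plot(
        table["round"],
        table["cumulative_accuracy"],
        "o-",
        color="crimson",
        label="cumulative",
    )
    ax.set_xticks(table["round"])
    ax.set_xticklabels(table["feature"], rotation=45, ha="right")
    ax.set_ylabel("overall accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    table.to_csv(_companion_csv(path), index=False)
    return table


def grouped_feature_figure(
    ft: pd.DataFrame,
    labels: Sequence[str],
    feature: str,
    path: str | Path,
) -> pd.DataFrame:
    """Boxplot of one feature grouped by behavior (behaviors ordered
    lexicographically).  Returns the long-format data table."""
    if feature not in ft.columns:
        raise KeyError(f"unknown feature {feature!r}")
    if len(labels) != len(ft):
        raise AlignmentError(f"{len(ft)} feature rows but {len(labels)} labels")
    path = Path(path)
    table = pd.DataFrame({"label": [str(l) for l in labels], feature: ft[feature]})
    groups = sorted(table["label"].unique())
    data = [table.loc[table["label"] == g, feature].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    ax.boxplot(data, tick_labels=groups, whis=1.5)
    ax.set_ylabel(feature)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    table.to_csv(_companion_csv(path), index=False)
    return table


def misclassification_report(
    ds: SegmentDataset,
    cv: pd.DataFrame,
    path: str | Path,
) -> pd.DataFrame:
    """Map cross-validation errors back onto the raw acceleration traces.

    The dataset is ordered by observed label; the figure draws all axes over
    the flattened sample sequence with dashed lines at behavior-block
    boundaries and a shaded dotted marker over every misclassified segment,
    annotated with the predicted behavior.  Returns the machine-readable
    bout table (one row per misclassified segment) and writes it, plus a
    block-boundary table, as CSVs next to the figure.
    """
    if len(cv) != ds.n_segments:
        raise AlignmentError(
            f"{ds.n_segments} segments but {len(cv)} cross-validation rows"
        )
    for col in ("observed", "predicted"):
        if col not in cv.columns:
            raise AlignmentError(f"cross-validation table lacks column {col!r}")
    path = Path(path)
    obs = cv["observed"].to_numpy(dtype=object)
    if not np.array_equal(obs, ds.labels.astype(object)):
        raise AlignmentError(
            "cross-validation observed labels do not match the dataset labels"
        )
    order = np.argsort(ds.labels.astype(str), kind="stable")
    sorted_ds = order_by_label(ds)
    sorted_cv = cv.iloc[order].reset_index(drop=True)
    seg_len = sorted_ds.seg_len

    labels_sorted = sorted_ds.labels.astype(str)
    block_rows = []
    start = 0
    for i in range(1, len(labels_sorted) + 1):
        if i == len(labels_sorted) or labels_sorted[i] != labels_sorted[start]:
            block_rows.append(
                {
                    "label": labels_sorted[start],
                    "first_segment": start,
                    "last_segment": i - 1,
                    "n_segments": i - start,
                }
            )
            start = i
    blocks = pd.DataFrame(block_rows)

    wrong = sorted_cv.index[
        sorted_cv["observed"].astype(str) != sorted_cv["predicted"].astype(str)
    ]
    bout_rows = [
        {
            "position": int(i),
            "segment_index": int(order[i]),
            "observed": str(sorted_cv.loc[i, "observed"]),
            "predicted": str(sorted_cv.loc[i, "predicted"]),
            "sample_start": int(i) * seg_len,
            "sample_end": (int(i) + 1) * seg_len,  # half-open span
        }
        for i in wrong
    ]
    bouts = pd.DataFrame(
        bout_rows,
        columns=[
            "position",
            "segment_index",
            "observed",
            "predicted",
            "sample_start",
            "sample_end",
        ],
    )

    axes_view = sorted_ds.axis_view()
    n_samples = sorted_ds.n_segments * seg_len
    xs = np.arange(n_samples)
    fig, ax = plt.subplots(figsize=(12, 4))
    for a in range(sorted_ds.n_axes):
        ax.plot(xs, axes_view[:, :, a].reshape(-1), lw=0.4, label=AXIS_NAMES[a])
    for _, row in blocks.iterrows():
        ax.axvline(row["first_segment"] * seg_len, color="k", ls="--", lw=0.8)
        ax.text(
            (row["first_segment"] + row["n_segments"] / 2) * seg_len,
            ax.get_ylim()[0],
            row["label"],
            ha="center",
            va="bottom",
            fontsize=7,
        )
    for _, row in bouts.iterrows():
        ax.axvspan(
            row["sample_start"], row["sample_end"], color="red", alpha=0.15
        )
        ax.axvline(row["sample_start"], color="gray", ls=":", lw=0.8)
        ax.text(
            (row["sample_start"] + row["sample_end"]) / 2,
            ax.get_ylim()[1],
            row["predicted"],
            ha="center",
            va="top",
            fontsize=6,
            rotation=90,
        )
    ax.set_xlabel("sample (segments ordered by observed behavior)")
    ax.set_ylabel("acceleration (g)")
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    bouts.to_csv(path.with_name(path.stem + "_bouts.csv"), index=False)
    blocks.to_csv(path.with_name(path.stem + "_blocks.csv"), index=False)
    return bouts


def embed_2d(
    ft: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
) -> np.ndarray:
    """Seeded 2-D UMAP embedding of a standardized feature table.

    Columns are standardized to zero mean and unit variance; constant
    columns carry no information and are dropped with a warning.  With a
    fixed seed the embedding is deterministic.  Behaviors that form isolated
    clusters in the embedding are likely to classify well.
    """
    if len(ft) < 10:
        raise ParameterError(f"need at least 10 segments to embed, got {len(ft)}")
    X = ft.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        dropped = [c for c, s in zip(ft.columns, sd) if s == 0]
        warnings.warn(
            f"dropping constant feature column(s) before embedding: {dropped}",
            stacklevel=2,
        )
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    X = (X - X.mean(axis=0)) / sd
    import umap  # deferred: umap-learn import is slow

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; that
        # trade is deliberate here
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        return np.asarray(reducer.fit_transform(X), dtype=float)


def embedding_figure(
    ft: pd.DataFrame,
    labels: Sequence[str],
    path: str | Path,
    seed: int = 0,
    **umap_kwargs,
) -> pd.DataFrame:
    """Scatter a 2-D embedding colored by behavior; returns the coordinate
    table (also written as CSV)."""
    if len(labels) != len(ft):
        raise AlignmentError(f"{len(ft)} feature rows but {len(labels)} labels")
    path = Path(path)
    coords = embed_2d(ft, seed=seed, **umap_kwargs)
    table = pd.DataFrame(
        {"umap1": coords[:, 0], "umap2": coords[:, 1], "label": [str(l) for l in labels]}
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in sorted(table["label"].unique()):
        part = table[table["label"] == g]
        ax.scatter(part["umap1"], part["umap2"], s=8, label=g, alpha=0.7)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    table.to_csv(_companion_csv(path), index=False)
    return table
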