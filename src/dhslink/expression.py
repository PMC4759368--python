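"""Expression-matrix processing for the microarray arm of the study.

Columns of the input matrix are samples named ``<condition>:<time>:<rep>``
(e.g. ``OIM:d1:2``). The pipeline averages replicates, expresses each
(condition, time) mean relative to the gene's average over the whole time
course (or over a reference condition), takes log2, selects the
most-changed genes and cuts an average-linkage hierarchy into k groups.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def parse_sample(label: str) -> tuple[str, str, str]:
    parts = label.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"sample label {label!r} is not '<condition>:<time>:<replicate>'"
        )
    return parts[0], parts[1], parts[2]


def validate_matrix(matrix: pd.DataFrame) -> None:
    labels = [parse_sample(c) for c in matrix.columns]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (condition, time, replicate) sample labels")
    if not np.isfinite(matrix.to_numpy()).all():
        bad = matrix.index[~np.isfinite(matrix).all(axis=1)]
        raise ValueError(f"non-finite intensity for genes {list(bad[:5])}")


def replicate_average(matrix: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over replicates; columns become '<condition>:<time>'."""
    validate_matrix(matrix)
    groups: dict[str, list[str]] = {}
    for c in matrix.columns:
        cond, time, _rep = parse_sample(c)
        groups.setdefault(f"{cond}:{time}", []).append(c)
    means = pd.DataFrame(
        {key: matrix[cols].mean(axis=1) for key, cols in groups.items()},
        index=matrix.index,
    )
    return means


def relative_log2_ratio(
    means: pd.DataFrame,
    ref: str = "timecourse",
    ref_condition: str | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """log2 of each mean over the gene's reference level.

    ``ref='timecourse'`` divides by the gene's average across all columns
    (so the pre-log ratios average to 1 per gene by construction);
    ``ref='control'`` divides by the gene's mean over the columns of
    ``ref_condition``. Zero or negative means are rejected unless a
    positive ``pseudocount`` is supplied.
    """
    values = means + pseudocount
    if (values.to_numpy() <= 0).any():
        raise ValueError(
            "non-positive expression mean: log ratio undefined "
            "(use a pseudocount to proceed)"
        )
    if ref == "timecourse":
        denom = values.mean(axis=1)
    elif ref == "control":
        if ref_condition is None:
            raise ValueError("ref='control' requires ref_condition")
        cols = [c for c in values.columns if c.split(":")[0] == ref_condition]
        if not cols:
            raise ValueError(f"no columns for reference condition {ref_condition!r}")
        denom = values[cols].mean(axis=1)
    else:
        raise ValueError(f"unknown ref {ref!r}")
    return np.log2(values.div(denom, axis=0))


def select_top_genes(
    ratio_matrix: pd.DataFrame, fold_threshold: float = 5.0, n: int = 135
) -> list[str]:
    """Genes whose peak |log2 ratio| reaches the fold threshold, top n.

    Ranked by that maximum descending; ties broken by gene id so the
    selection is reproducible.
    """
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    cutoff = np.log2(fold_threshold)
    peak = ratio_matrix.abs().max(axis=1)
    qualifying = peak[peak >= cutoff]
    order = sorted(qualifying.index, key=lambda g: (-qualifying[g], g))
    return order[:n]


def cluster_genes(ratio_matrix: pd.DataFrame, k: int = 6) -> pd.Series:
    """Cut an average-linkage Euclidean hierarchy into k gene groups.

    Returns group labels (1..k) indexed by gene id. Duplicated rows land in
    the same group (zero distance); the partition does not depend on row
    order beyond distance ties.
    """
    n_genes = ratio_matrix.shape[0]
    if k > n_genes:
        raise ValueError(f"k={k} exceeds number of genes ({n_genes})")
    if k == n_genes:
        return pd.Series(
            np.arange(1, n_genes + 1), index=ratio_matrix.index, name="group"
        )
    dist = pdist(ratio_matrix.to_numpy(), metric="euclidean")
    tree = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=ratio_matrix.index, name="group")
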