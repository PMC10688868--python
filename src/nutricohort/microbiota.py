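"""Genus-level microbiota comparison utilities.

Abundance tables (samples x taxa, semicolon lineage strings) are filtered
at a 5000-read depth floor, aggregated to genus, converted to relative
abundances, compared with Bray-Curtis dissimilarity, and embedded with
classical principal-coordinates analysis (metric MDS on the double-
centered squared distance matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .synthetic import AbundanceTable

__all__ = [
    "AbundanceTable", "Ordination", "read_abundance_tsv", "filter_low_depth",
    "aggregate_to_genus", "relative_abundance", "bray_curtis", "pcoa",
    "merge_cohorts",
]


@dataclass
class Ordination:
    """PCoA result: sample coordinates, eigenvalues, variance proportions."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray    # all, nonincreasing
    proportion_explained: np.ndarray  # over the positive eigenvalue mass


def read_abundance_tsv(path, groups_path=None) -> AbundanceTable:
    """Read abundance.tsv (rows taxa: taxon_id, lineage, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "lineage" not in df.columns:
        raise ValidationError("abundance.tsv must carry a 'lineage' column")
    lineages = df["lineage"].fillna("")
    lineages.index.name = None
    counts = df.drop(columns=["lineage"]).T
    counts.index.name = None
    counts.columns.name = None
    groups = pd.Series("", index=counts.index)
    if groups_path is not None:
        g = pd.read_csv(groups_path, index_col="sample_id")["study_label"]
        groups = g.reindex(counts.index).fillna("")
    return AbundanceTable(counts=counts, lineages=lineages, groups=groups)


def filter_low_depth(table: AbundanceTable, min_reads: float = 5000,
                     ) -> tuple[AbundanceTable, AbundanceTable]:
    """Split samples into (kept, removed) at the read-depth floor.

    Removal is strict "less than": a sample totalling exactly ``min_reads``
    is kept.  Undefined for relative-abundance tables.
    """
    if table.is_relative:
        raise ValidationError("read depth undefined for relative abundances")
    totals = table.counts.sum(axis=1)
    keep = totals >= min_reads
    def _sub(mask):
        return AbundanceTable(counts=table.counts.loc[mask],
                              lineages=table.lineages,
                              groups=table.groups.loc[mask],
                              is_relative=False)
    return _sub(keep), _sub(~keep)


def genus_of(lineage: str) -> str:
    """Genus field of a lineage; empty genus pools to unclassified_<family>."""
    parts = str(lineage).split(";")
    if len(parts) == 1:  # already a bare genus name
        return parts[0] or "unclassified_unknown"
    genus = parts[5].strip() if len(parts) > 5 else ""
    if genus:
        return genus
    family = parts[4].strip() if len(parts) > 4 else "unknown"
    return f"unclassified_{family or 'unknown'}"


def aggregate_to_genus(table: AbundanceTable) -> AbundanceTable:
    """Sum columns sharing a genus; conserves per-sample totals."""
    genera = table.lineages.reindex(table.counts.columns).map(genus_of)
    agg = table.counts.T.groupby(genera.values).sum().T
    agg = agg[sorted(agg.columns)]
    lineages = pd.Series({g: g for g in agg.columns})
    return AbundanceTable(counts=agg, lineages=lineages, groups=table.groups,
                          is_relative=table.is_relative)


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample by its total; rows then sum to 1."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])[:5]
        raise ValidationError(f"zero-total sample(s): {bad}")
    rel = table.counts.div(totals, axis=0)
    return AbundanceTable(counts=rel, lineages=table.lineages,
                          groups=table.groups, is_relative=True)


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities, sum|x-y| / sum(x+y).

    Absent taxa count as 0; any zero-total sample makes the statistic
    undefined and raises.
    """
    X = table.counts.to_numpy(dtype=float)
    if (X.sum(axis=1) == 0).any():
        raise ValidationError("Bray-Curtis undefined for zero-total samples")
    ids = list(table.counts.index)
    if len(ids) < 2:
        return pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    d = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(d, index=ids, columns=ids)


def pcoa(dist: pd.DataFrame, k: int = 2,
         negative_eigenvalue_correction: bool = False) -> Ordination:
    """Classical metric MDS of a distance matrix.

    Double-centers -1/2 D^2, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues.  Negative eigenvalues
    are reported but not corrected unless the Lingoes correction is
    requested; fewer than k positive eigenvalues yields fewer axes with a
    warning.
    """
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be square and symmetric")
    n = D.shape[0]
    if negative_eigenvalue_correction:
        # Lingoes: add constant to squared off-diagonal distances
        B = _double_center(D)
        lam_min = np.linalg.eigvalsh(B).min()
        if lam_min < 0:
            D2 = D ** 2 - 2 * lam_min * (1 - np.eye(n))
            D = np.sqrt(np.maximum(D2, 0))
    B = _double_center(D)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10 * max(abs(eigval[0]), 1.0), 0.0)
    n_pos = int((eigval > tol).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(f"only {k_eff} positive eigenvalue(s); returning "
                      f"{k_eff} axes instead of {k}")
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    pos_mass = eigval[eigval > tol].sum()
    prop = (eigval[:k_eff] / pos_mass) if pos_mass > 0 else np.zeros(k_eff)
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=dist.index,
            columns=[f"PCo{i + 1}" for i in range(k_eff)]),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


def _double_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


def merge_cohorts(tables: Mapping[str, AbundanceTable]) -> AbundanceTable:
    """Outer-join genus-level relative tables from several studies.

    Sample ids are prefixed with their study label; genera absent from a
    study are zero-filled (no renormalization needed: per-sample totals are
    unchanged).  Count tables are converted to relative abundances with a
    warning.
    """
    frames, groups = [], []
    for label, tab in tables.items():
        t = aggregate_to_genus(tab)
        if not t.is_relative:
            warnings.warn(f"{label}: converting counts to relative abundances")
            t = relative_abundance(t)
        c = t.counts.copy()
        c.index = [f"{label}:{s}" for s in c.index]
        frames.append(c)
        groups.append(pd.Series(label, index=c.index))
    merged = pd.concat(frames, axis=0).fillna(0.0)
    merged = merged[sorted(merged.columns)]
    return AbundanceTable(
        counts=merged,
        lineages=pd.Series({g: g for g in merged.columns}),
        groups=pd.concat(groups),
        is_relative=True,
    )
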