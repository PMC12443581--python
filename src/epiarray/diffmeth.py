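"""Two-group differential testing, BH correction, classification, clustering.

Transcripts are compared between the two sample groups on the log2-scale
normalized values (m6A quantity or expression level).  The log2 fold change
is mean(group 2) - mean(group 1); with the default group order taken from
the sample sheet this means "up" = higher in the second (involuting) group.
Significance uses a two-sided unpaired t-test; the pooled-variance form is
the default because it is exactly calibrated for a handful of replicates per
group, with the Welch form available for unequal variances.  Calls require
both a linear fold change strictly beyond the threshold (default 1.5) and a
p-value below the cutoff (default 0.05, unadjusted); BH-adjusted p-values
are always reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .normalize import NormalizedProfile

logger = logging.getLogger(__name__)

#: RNA-class pooling used in summary tables: mRNA and lncRNA stand alone,
#: the four small classes pool into "sncRNA".
CLASS_GROUPS = {
    "mRNA": "mRNA",
    "lncRNA": "lncRNA",
    "pri-miRNA": "sncRNA",
    "pre-miRNA": "sncRNA",
    "snoRNA": "sncRNA",
    "snRNA": "sncRNA",
}

_SMALLEST_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class DiffThresholds:
    """Significance thresholds for differential calls."""

    fc_cut: float = 1.5
    p_cut: float = 0.05
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if not self.fc_cut > 1:
            raise ValidationError(f"fc_cut={self.fc_cut} must be > 1")
        if not 0 < self.p_cut < 1:
            raise ValidationError(f"p_cut={self.p_cut} must be in (0, 1)")


# ---------------------------------------------------------------------------
# Per-transcript test
# ---------------------------------------------------------------------------

def two_group_test(
    values: np.ndarray, groups: np.ndarray, group_order: tuple, equal_var: bool = True
) -> tuple[float, float]:
    """Log2 fold change and two-sided t-test p for one transcript.

    ``values`` are log2-scale per-sample measures; ``groups`` the matching
    group labels.  Returns ``(log2fc, p)`` where log2fc = mean(group 2) -
    mean(group 1).  Fewer than two finite values in a group gives p = NaN.
    Zero variance in both groups: p = 1 for equal means, else the smallest
    positive float (flagged in the log).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == group_order[0]]
    b = values[groups == group_order[1]]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        if a.size and b.size:
            return float(b.mean() - a.mean()), float("nan")
        return float("nan"), float("nan")
    log2fc = float(b.mean() - a.mean())
    if a.std() == 0.0 and b.std() == 0.0:
        if log2fc == 0.0:
            return log2fc, 1.0
        logger.warning("zero within-group variance with unequal means; p set to minimum")
        return log2fc, float(_SMALLEST_P)
    _, p = stats.ttest_ind(b, a, equal_var=equal_var)
    return log2fc, float(p)


def diff_test(
    profile: NormalizedProfile,
    measure: str = "m6a",
    thresholds: DiffThresholds = DiffThresholds(),
    group_order: tuple | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Vectorized per-transcript differential table for one measure.

    Returns a DataFrame indexed by transcript_id with columns
    ``rna_class, measure, log2fc, fc, p, p_adj, class``.
    """
    data = profile.measure(measure)
    groups = profile.samples["group"].to_numpy()
    if group_order is None:
        group_order = profile.group_names
    mat = data.to_numpy(dtype=float)
    mask_a = groups == group_order[0]
    mask_b = groups == group_order[1]
    if not mask_a.any() or not mask_b.any():
        raise ValidationError(f"group_order {group_order} does not match the sample sheet")

    def _group_stats(mask):
        sub = mat[:, mask]
        finite = np.isfinite(sub)
        n = finite.sum(axis=1)
        s = np.where(finite, sub, 0.0)
        mean = np.divide(s.sum(axis=1), n, out=np.full(len(sub), np.nan), where=n > 0)
        dev = np.where(finite, sub - mean[:, None], 0.0)
        ss = (dev**2).sum(axis=1)
        var = np.divide(ss, n - 1, out=np.full(len(sub), np.nan), where=n > 1)
        return n, mean, var

    n1, m1, v1 = _group_stats(mask_a)
    n2, m2, v2 = _group_stats(mask_b)
    log2fc = m2 - m1

    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            df = n1 + n2 - 2.0
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            se2_1, se2_2 = v1 / n1, v2 / n2
            se = np.sqrt(se2_1 + se2_2)
            df = (se2_1 + se2_2) ** 2 / (
                se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
            )
        t = log2fc / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

    testable = (n1 >= 2) & (n2 >= 2)
    zero_var = testable & (v1 == 0) & (v2 == 0)
    p = np.where(zero_var & (log2fc == 0), 1.0, p)
    n_degen = int((zero_var & (log2fc != 0)).sum())
    if n_degen:
        logger.warning("%d transcripts with zero variance and unequal means", n_degen)
    p = np.where(zero_var & (log2fc != 0), _SMALLEST_P, p)
    p = np.where(testable, p, np.nan)
    n_untestable = int((~testable).sum())
    if n_untestable:
        logger.info("%d transcripts with <2 finite values in a group: p undefined", n_untestable)

    out = pd.DataFrame(
        {
            "rna_class": profile.transcripts["rna_class"].to_numpy(),
            "measure": measure,
            "log2fc": log2fc,
            "fc": np.exp2(log2fc),
            "p": p,
        },
        index=data.index,
    )
    out["p_adj"] = bh_adjust_with_nan(out["p"].to_numpy())
    return classify(out, thresholds)


# ---------------------------------------------------------------------------
# BH step-up correction
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_adjust_with_nan(pvalues) -> np.ndarray:
    """BH over the finite entries only; NaN p-values stay NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        out[finite] = bh_adjust(p[finite])
    return out


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------

def classify(results: pd.DataFrame, thresholds: DiffThresholds = DiffThresholds()) -> pd.DataFrame:
    """Assign up/down/ns classes from fold change and p-value.

    ``up`` iff fc strictly > fc_cut and p < p_cut; ``down`` iff fc strictly
    < 1/fc_cut and p < p_cut; everything else (including missing p) is ``ns``.
    """
    p_col = "p_adj" if thresholds.use_adjusted else "p"
    fc = results["fc"].to_numpy(dtype=float)
    p = results[p_col].to_numpy(dtype=float)
    sig = p < thresholds.p_cut  # False for NaN
    cls = np.where(sig & (fc > thresholds.fc_cut), "up",
                   np.where(sig & (fc < 1.0 / thresholds.fc_cut), "down", "ns"))
    out = results.copy()
    out["class"] = cls
    return out


def summarize_counts(results: pd.DataFrame) -> pd.DataFrame:
    """Counts of up/down/ns per pooled RNA-class group (mRNA, lncRNA, sncRNA)."""
    pooled = results["rna_class"].map(CLASS_GROUPS)
    table = (
        pd.crosstab(pooled, results["class"])
        .reindex(columns=["up", "down", "ns"], fill_value=0)
        .rename_axis(index="class_group", columns=None)
    )
    table["total"] = table.sum(axis=1)
    return table


# ---------------------------------------------------------------------------
# Sample clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Hierarchical clustering of samples on a transcript x sample matrix."""

    linkage: np.ndarray           # scipy linkage matrix
    sample_ids: list
    labels: pd.Series             # sample -> cluster id at the k=2 cut
    newick: str


def _to_newick(node, leaf_names) -> str:
    if node.is_leaf():
        return leaf_names[node.id]
    left = _to_newick(node.get_left(), leaf_names)
    right = _to_newick(node.get_right(), leaf_names)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hier_cluster(matrix: pd.DataFrame, k: int = 2) -> ClusterResult:
    """Cluster samples with distance 1 - Pearson correlation, average linkage.

    ``matrix`` is transcripts x samples (e.g. the m6A quantities of the
    significantly changed transcripts).  A sample pair whose correlation is
    undefined (a constant vector) gets distance 1 with a logged warning.
    Returns the k-cut labels (default k=2) and a Newick rendering of the
    dendrogram.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples to cluster")
    if matrix.shape[0] < 1:
        raise ValidationError("need at least 1 transcript to cluster")
    data = matrix.to_numpy(dtype=float).T          # samples x transcripts
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    dist = 1.0 - corr
    if np.isnan(dist).any():
        logger.warning("undefined sample correlations (constant vector); distance set to 1")
        dist = np.where(np.isnan(dist), 1.0, dist)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = hierarchy.fcluster(z, t=k, criterion="maxclust")
    sample_ids = list(matrix.columns)
    tree = hierarchy.to_tree(z)
    newick = _to_newick(tree, sample_ids) + ";"
    return ClusterResult(
        linkage=z,
        sample_ids=sample_ids,
        labels=pd.Series(cut, index=sample_ids, name="cluster"),
        newick=newick,
    )
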