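"""Joint m6A x expression analysis: quadrant classes and global association.

A transcript enters a quadrant only when *both* its methylation and its
expression change pass the fold-change and p-value thresholds; the quadrant
name combines the methylation direction (hyper/hypo) with the expression
direction (up/down).  The IGF1 pattern of the involuting contrast — m6A up,
expression down — is "hyper-down"; IGF2's coordinated loss is "hypo-down".
The global association is the Pearson (and Spearman) correlation between the
m6A and expression log2 fold changes across joined transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import DiffThresholds
from .errors import ConsistencyError, ValidationError

QUADRANTS = ("hyper-up", "hyper-down", "hypo-up", "hypo-down", "ns")


def join_and_classify(
    m6a: pd.DataFrame,
    expr: pd.DataFrame,
    thresholds: DiffThresholds = DiffThresholds(),
) -> pd.DataFrame:
    """Inner-join differential tables on transcript_id and assign quadrants.

    Both inputs are diffmeth result tables (indexed by transcript_id with
    ``fc``, ``p``, ``p_adj``, ``log2fc`` columns).  Output columns:
    ``m6a_log2fc, m6a_fc, m6a_p, m6a_p_adj, expr_log2fc, expr_fc, expr_p,
    expr_p_adj, quadrant``.
    """
    for name, frame in (("m6a", m6a), ("expression", expr)):
        if not frame.index.is_unique:
            dup = frame.index[frame.index.duplicated()][0]
            raise ConsistencyError(f"duplicate transcript_id {dup!r} in {name} results")
    cols = ["log2fc", "fc", "p", "p_adj"]
    joined = m6a[cols].add_prefix("m6a_").join(expr[cols].add_prefix("expr_"), how="inner")

    p_suffix = "p_adj" if thresholds.use_adjusted else "p"
    def _sig(prefix: str) -> np.ndarray:
        fc = joined[f"{prefix}_fc"].to_numpy(dtype=float)
        p = joined[f"{prefix}_{p_suffix}"].to_numpy(dtype=float)
        return (p < thresholds.p_cut) & (
            (fc > thresholds.fc_cut) | (fc < 1.0 / thresholds.fc_cut)
        )

    both = _sig("m6a") & _sig("expr")
    hyper = joined["m6a_log2fc"].to_numpy() > 0
    up = joined["expr_log2fc"].to_numpy() > 0
    quadrant = np.where(
        both,
        np.where(hyper, "hyper-", "hypo-") + np.where(up, "up", "down"),
        "ns",
    )
    joined["quadrant"] = quadrant
    return joined


@dataclass(frozen=True)
class AssociationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "n": self.n,
        }


def global_association(
    joined: pd.DataFrame, only_significant: bool = False
) -> AssociationResult:
    """Correlation between m6A and expression log2 fold changes.

    By default all joined transcripts contribute; ``only_significant``
    restricts to quadrant-classified (non-ns) transcripts.
    """
    sub = joined[joined["quadrant"] != "ns"] if only_significant else joined
    x = sub["m6a_log2fc"].to_numpy(dtype=float)
    y = sub["expr_log2fc"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError(
            f"global association needs >= 3 transcripts with finite fold changes, got {x.size}"
        )
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return AssociationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n=int(x.size),
    )
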