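"""MeRIP-qPCR %input and the 2^-ddCt relative-expression method.

Both calculators assume perfect amplification efficiency (a doubling per
cycle), so a quantity q maps to Ct = const - log2(q).  The %input of a MeRIP
fraction follows from the paired MeRIP and supernatant Ct values::

    %input = 2^-Ct_MeRIP / (2^-Ct_MeRIP + 2^-Ct_Sup) * 100

and relative expression versus a reference gene and calibrator condition is
2^-ddCt with ddCt = (Ct_target - Ct_ref) - (Ct_target_cal - Ct_ref_cal).
Duplicate wells are averaged on the Ct scale before either formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

PLATE_COLUMNS = ("target_id", "fraction", "condition", "ct")


def percent_input(ct_merip, ct_sup):
    """MeRIP enrichment as a percentage of total (MeRIP + supernatant) signal.

    Accepts scalars or arrays; strictly increasing in (ct_sup - ct_merip) and
    symmetric: percent_input(a, b) + percent_input(b, a) = 100.
    """
    ct_merip = np.asarray(ct_merip, dtype=float)
    ct_sup = np.asarray(ct_sup, dtype=float)
    if not (np.all(np.isfinite(ct_merip)) and np.all(np.isfinite(ct_sup))):
        raise ValidationError("Ct values must be finite")
    # 2^-a / (2^-a + 2^-b) = 1 / (1 + 2^(a-b)): overflow-safe form
    out = 100.0 / (1.0 + np.exp2(ct_merip - ct_sup))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCt relative quantity of one target in one condition."""

    target_id: str
    condition: str
    ddct: float
    rel_expr: float
    reference_gene: str = "U6"


def ddct(
    ct_target: float,
    ct_ref: float,
    ct_target_cal: float,
    ct_ref_cal: float,
    *,
    target_id: str = "",
    condition: str = "",
    reference_gene: str = "U6",
) -> RelativeExpression:
    """Relative expression of a target versus reference gene and calibrator.

    All four inputs are mean Ct values (duplicate wells already averaged on
    the Ct scale).  Invariant to adding a constant to every Ct.
    """
    cts = (ct_target, ct_ref, ct_target_cal, ct_ref_cal)
    if not all(np.isfinite(c) for c in cts):
        raise ValidationError("all four mean Ct values must be finite")
    d = (ct_target - ct_ref) - (ct_target_cal - ct_ref_cal)
    return RelativeExpression(
        target_id=target_id,
        condition=condition,
        ddct=float(d),
        rel_expr=float(2.0 ** -d),
        reference_gene=reference_gene,
    )


# ---------------------------------------------------------------------------
# Plate-level helpers
# ---------------------------------------------------------------------------

def _check_plate(plate: pd.DataFrame) -> None:
    for col in PLATE_COLUMNS:
        if col not in plate.columns:
            raise ValidationError(f"plate table is missing column {col!r}")


def average_duplicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (target, fraction, condition) across duplicate wells."""
    _check_plate(plate)
    return (
        plate.groupby(["target_id", "fraction", "condition"], as_index=False)["ct"]
        .mean()
    )


def percent_input_table(plate: pd.DataFrame) -> pd.DataFrame:
    """%input per target and condition from paired MeRIP/Supernatant wells."""
    means = average_duplicates(plate)
    wide = means.pivot_table(
        index=["target_id", "condition"], columns="fraction", values="ct"
    )
    for frac in ("MeRIP", "Supernatant"):
        if frac not in wide.columns:
            raise ValidationError(f"plate has no {frac!r} fraction wells")
    wide = wide.dropna(subset=["MeRIP", "Supernatant"])
    out = wide.reset_index()[["target_id", "condition"]]
    out["pct_input"] = percent_input(
        wide["MeRIP"].to_numpy(), wide["Supernatant"].to_numpy()
    )
    return out


def relative_expression_table(
    plate: pd.DataFrame, reference: str = "U6", calibrator: str | None = None
) -> pd.DataFrame:
    """2^-ddCt for every target/condition versus the reference and calibrator.

    Uses expression wells (fraction == "none").  The calibrator defaults to
    the first condition in plate order; by construction its rel_expr is 1.
    """
    means = average_duplicates(plate)
    means = means[means["fraction"] == "none"]
    if means.empty:
        raise ValidationError("plate has no expression (fraction='none') wells")
    if calibrator is None:
        calibrator = plate.loc[plate["fraction"] == "none", "condition"].iloc[0]
    wide = means.pivot_table(index="target_id", columns="condition", values="ct")
    if calibrator not in wide.columns:
        raise ValidationError(f"calibrator condition {calibrator!r} has no wells")
    if reference not in wide.index:
        raise ValidationError(f"reference gene {reference!r} has no wells")
    rows = []
    for target in wide.index:
        if target == reference:
            continue
        for condition in wide.columns:
            cts = (
                wide.at[target, condition],
                wide.at[reference, condition],
                wide.at[target, calibrator],
                wide.at[reference, calibrator],
            )
            if any(pd.isna(c) for c in cts):
                raise ValidationError(
                    f"missing Ct for target {target!r} in condition "
                    f"{condition!r}/calibrator {calibrator!r}"
                )
            rel = ddct(*cts, target_id=target, condition=condition,
                       reference_gene=reference)
            rows.append(
                {"target_id": target, "condition": condition,
                 "ddct": rel.ddct, "rel_expr": rel.rel_expr,
                 "reference_gene": reference}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group summaries with significance stars
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    """Standard star coding: p<0.05 '*', p<0.01 '**', p<0.001 '***'."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_groups(rel_exprs: pd.DataFrame) -> pd.DataFrame:
    """Per-target group means, SDs and pairwise Welch t-test with stars.

    ``rel_exprs`` has columns ``target_id, group, rel_expr`` with one row per
    biological replicate.  Exactly two groups are compared per target; a
    group with a single replicate yields a missing p (logged upstream by the
    caller if needed).
    """
    for col in ("target_id", "group", "rel_expr"):
        if col not in rel_exprs.columns:
            raise ValidationError(f"rel_exprs is missing column {col!r}")
    rows = []
    for target, sub in rel_exprs.groupby("target_id", sort=True):
        group_names = list(dict.fromkeys(sub["group"]))
        if len(group_names) != 2:
            raise ValidationError(
                f"target {target!r} must have exactly two groups, got {group_names}"
            )
        a = sub.loc[sub["group"] == group_names[0], "rel_expr"].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == group_names[1], "rel_expr"].to_numpy(dtype=float)
        if a.size >= 2 and b.size >= 2:
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                p = 1.0 if a.mean() == b.mean() else float(np.nextafter(0.0, 1.0))
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "target_id": target,
                "group1": group_names[0],
                "group2": group_names[1],
                "mean1": float(a.mean()),
                "mean2": float(b.mean()),
                "sd1": float(a.std(ddof=1)) if a.size > 1 else float("nan"),
                "sd2": float(b.std(ddof=1)) if b.size > 1 else float("nan"),
                "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)
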