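"""Over-representation analysis of gene lists against user-supplied gene sets.

For a query of n genes drawn from a universe of N, a term with K members in
the universe and k of them in the query is scored with the one-sided
(enrichment) Fisher exact test on the 2x2 table (k, n-k, K-k, N-K-n+k) —
equivalently the hypergeometric upper tail P(X >= k) — with BH correction
across terms.  Directional overlap counts feed the bubble-plot z-score
z = (n_up - n_down) / sqrt(k), the summary statistic conventional for GO
bubble plots.  Gene sets come from GMT files; no annotation content is
bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.term_id!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, category: str = "pathway") -> GeneSetCollection:
    """Read a GMT file (term, description, member genes per tab-separated line).

    Gene symbols are uppercased for matching; ``category`` tags every term in
    the file (one GMT per GO namespace / pathway database, as distributed).
    """
    if category not in CATEGORIES:
        raise ValidationError(f"category must be one of {CATEGORIES}, got {category!r}")
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: GMT line needs term, description, >=1 gene")
            term_id, name, *genes = parts
            genes = frozenset(g.strip().upper() for g in genes if g.strip())
            if not genes:
                raise FormatError(f"{path}:{line_no}: gene set {term_id!r} has no genes")
            sets.append(GeneSet(term_id=term_id, term_name=name, category=category,
                                genes=genes))
    return GeneSetCollection(sets)


def fisher_ora(
    query,
    sets: GeneSetCollection,
    universe,
    directions: dict | None = None,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each gene set.

    Genes are matched case-insensitively.  Query genes outside the universe
    are dropped with a logged count; terms with no member in the universe are
    skipped.  ``directions`` optionally maps query genes to "up"/"down" for
    the directional overlap counts and the bubble z-score.

    Returns a DataFrame with columns ``term_id, term_name, category, k, K, n,
    N, p, p_adj, n_up, n_down, z`` sorted by p.
    """
    universe_set = {str(g).upper() for g in universe}
    if not universe_set:
        raise ValidationError("universe must be non-empty")
    query_set = {str(g).upper() for g in query}
    dropped = query_set - universe_set
    if dropped:
        logger.info("%d query genes outside the universe dropped", len(dropped))
    query_set &= universe_set
    dirmap = {str(g).upper(): d for g, d in (directions or {}).items()}

    N, n = len(universe_set), len(query_set)
    rows = []
    for gs in sets:
        members = {str(g).upper() for g in gs.genes} & universe_set
        K = len(members)
        if K == 0:
            continue
        overlap = members & query_set
        k = len(overlap)
        # hypergeometric upper tail P(X >= k) == one-sided Fisher enrichment p
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        n_up = sum(1 for g in overlap if dirmap.get(g) == "up")
        n_down = sum(1 for g in overlap if dirmap.get(g) == "down")
        rows.append(
            {"term_id": gs.term_id, "term_name": gs.term_name, "category": gs.category,
             "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0),
             "n_up": n_up, "n_down": n_down,
             "z": bubble_zscore(n_up, n_down, k) if k >= 1 else float("nan")}
        )
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "category", "k", "K",
                                      "n", "N", "p", "n_up", "n_down", "z"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else out["p"]
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def bubble_zscore(n_up: int, n_down: int, k: int) -> float:
    """Directional bias of a term's overlap: (n_up - n_down) / sqrt(k)."""
    if k < 1:
        raise ValidationError("bubble z-score undefined for k = 0")
    if n_up + n_down > k:
        raise ValidationError("n_up + n_down cannot exceed the overlap k")
    if n_up < 0 or n_down < 0:
        raise ValidationError("directional counts must be >= 0")
    return float((n_up - n_down) / np.sqrt(k))
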