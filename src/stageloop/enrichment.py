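"""Fisher exact tests for functional-category enrichment of peak gene sets.

For a stage's peak set and a functional category, the 2x2 table is

                 in category   not in category
    peak set          a               b
    background        c               d

Conditional on the margins, a follows a hypergeometric distribution; the
right tail P(X >= a) measures over-representation, the left tail P(X <= a)
under-representation, and the two-tailed p-value sums the probabilities of
all tables as or less likely than the observed one (the classical
point-probability method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    stage: int
    category: str
    a: int
    b: int
    c: int
    d: int
    p_left: float
    p_right: float
    p_two: float
    degenerate: bool = False


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Left-, right- and two-tailed exact p-values of a 2x2 table.

    A zero margin makes the table degenerate (only one outcome possible);
    all three p-values are then 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    row1 = a + b
    col1 = a + c
    if min(row1, col1, N - row1, N - col1) == 0 or N == 0:
        return 1.0, 1.0, 1.0
    hg = stats.hypergeom(N, col1, row1)
    p_left = float(hg.cdf(a))
    p_right = float(hg.sf(a - 1))
    support = np.arange(max(0, row1 + col1 - N), min(row1, col1) + 1)
    pmf = hg.pmf(support)
    p_obs = hg.pmf(a)
    p_two = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p_left, 1.0), min(p_right, 1.0), min(p_two, 1.0)


def enrich_stage_peaks(
    peak_table: pd.DataFrame,
    annotation: pd.DataFrame,
    stage: int,
    *,
    peak_mode: str = "primary",
) -> list[EnrichmentResult]:
    """Test every category for enrichment in the genes peaking at ``stage``.

    ``peak_table`` is the per-gene table from peak_summary (gene_id,
    primary_peak, peaks); ``annotation`` maps gene_id -> category with
    multi-membership via repeated rows.  The background is all genes in the
    peak table; unannotated genes count only toward the background.  With
    ``peak_mode='any'`` membership uses any called peak instead of the
    primary one.
    """
    if peak_mode not in ("primary", "any"):
        raise ValueError("peak_mode must be 'primary' or 'any'")
    genes = peak_table["gene_id"].astype(str)
    if peak_mode == "primary":
        in_set = set(genes[peak_table["primary_peak"] == stage])
    else:
        has = peak_table["peaks"].astype(str).str.split(",").apply(
            lambda ps: str(stage) in ps
        )
        in_set = set(genes[has])
    background = set(genes)
    if not in_set:
        logger.warning("no genes peak at stage %d; empty enrichment result", stage)
        return []
    ann = annotation[annotation["gene_id"].astype(str).isin(background)]
    results = []
    for category, sub in ann.groupby("category"):
        members = set(sub["gene_id"].astype(str))
        a = len(in_set & members)
        b = len(in_set - members)
        c = len(members - in_set)
        d = len(background) - a - b - c
        p_left, p_right, p_two = fisher_exact(a, b, c, d)
        results.append(
            EnrichmentResult(
                stage=stage,
                category=str(category),
                a=a,
                b=b,
                c=c,
                d=d,
                p_left=p_left,
                p_right=p_right,
                p_two=p_two,
                degenerate=(p_left == p_right == p_two == 1.0 and min(a + b, a + c) == 0),
            )
        )
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular form of enrichment results (stage, category, three p-values)."""
    return pd.DataFrame(
        [
            {
                "stage": r.stage,
                "category": r.category,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "p_left": r.p_left,
                "p_right": r.p_right,
                "p_two": r.p_two,
            }
            for r in results
        ]
    )
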