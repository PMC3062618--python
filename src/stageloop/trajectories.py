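"""Stage trajectories: standardization, peak calling, correlation, clustering.

A gene's trajectory is its vector of stage least-squares means.  Peaks are
called by a confidence-interval rule: a stage is a separate peak when its
lsmean lies within the 90% CI of the trajectory's maximum and is at least
three stages away from any other accepted peak.  Genes are ordered by the
stage of their primary (tallest) peak for heatmap-style displays, and
pairwise Pearson correlations over the S stage means summarize co-expression
structure; with S stages, the two-tailed critical |r| at alpha comes from
the exact t distribution of a Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# standardization and peak calling
# ---------------------------------------------------------------------------


def standardize(lsmeans) -> tuple[np.ndarray, bool]:
    """(x - mean) / sample SD.  Constant profiles map to zeros, flagged."""
    x = np.asarray(lsmeans, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 stages to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of points >= both neighbors (endpoints: >= single neighbor)."""
    n = len(x)
    if n == 1:
        return np.array([0])
    left = np.r_[True, x[1:] >= x[:-1]]
    right = np.r_[x[:-1] >= x[1:], True]
    return np.flatnonzero(left & right)


def detect_peaks(
    lsmeans,
    se,
    ci_level: float = 0.90,
    min_sep: int = 3,
    quantile: str = "normal",
    df: float | None = None,
) -> list[int]:
    """Call peak stages (1-based) by the CI-of-the-maximum rule.

    The maximum stage k* is always a peak.  Candidate stages are local
    maxima whose lsmean is at least the lower bound of the CI of
    lsmean[k*] (built from its standard error); candidates are accepted
    greedily in decreasing height, rejecting any within min_sep - 1 stages
    (|delta stage| < min_sep) of an accepted peak.
    """
    x = np.asarray(lsmeans, dtype=float)
    s = np.asarray(se, dtype=float)
    k_star = int(np.argmax(x))
    tail = 0.5 + ci_level / 2.0
    z = (
        stats.t.ppf(tail, df)
        if quantile == "t"
        else stats.norm.ppf(tail)
    )
    lower = x[k_star] - z * s[k_star]
    cand = [k for k in _local_maxima(x) if x[k] >= lower]
    # decreasing height; ties go to the earlier stage; k* first by construction
    cand.sort(key=lambda k: (-x[k], k))
    accepted: list[int] = []
    for k in cand:
        if all(abs(k - a) >= min_sep for a in accepted):
            accepted.append(k)
    return sorted(k + 1 for k in accepted)


@dataclass
class PeakProfile:
    """Standardized trajectory of one gene with its called peaks."""

    gene_id: str
    z: np.ndarray
    peaks: list[int]
    primary: int  # stage of the tallest peak
    constant: bool = False

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def peak_profiles(
    lsmeans: pd.DataFrame,
    lsmean_se: pd.DataFrame,
    ci_level: float = 0.90,
    min_sep: int = 3,
) -> list[PeakProfile]:
    """Standardize and call peaks for every gene (rows of ``lsmeans``)."""
    profiles = []
    X = lsmeans.to_numpy(float)
    SE = lsmean_se.to_numpy(float)
    for i, gid in enumerate(lsmeans.index):
        z, const = standardize(X[i])
        peaks = detect_peaks(X[i], SE[i], ci_level=ci_level, min_sep=min_sep)
        primary = max(peaks, key=lambda k: (X[i][k - 1], -k))
        profiles.append(
            PeakProfile(gene_id=str(gid), z=z, peaks=peaks, primary=primary, constant=const)
        )
    return profiles


def peak_summary(profiles: list[PeakProfile]) -> dict:
    """Gene ordering by primary peak plus peak-count distributions.

    Returns a dict with ``table`` (one row per gene, sorted by primary peak
    stage then gene_id), ``stage_counts`` (genes whose primary peak is each
    stage) and ``n_peak_counts`` (histogram of peaks per gene).
    """
    table = pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in profiles],
            "n_peaks": [p.n_peaks for p in profiles],
            "primary_peak": [p.primary for p in profiles],
            "peaks": [",".join(map(str, p.peaks)) for p in profiles],
        }
    ).sort_values(["primary_peak", "gene_id"], kind="mergesort").reset_index(drop=True)
    stage_counts = table["primary_peak"].value_counts().sort_index()
    n_peak_counts = table["n_peaks"].value_counts().sort_index()
    return {
        "table": table,
        "stage_counts": stage_counts,
        "n_peak_counts": n_peak_counts,
    }


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------


def critical_r(n: int, alpha: float) -> float:
    """Two-tailed critical Pearson |r| at level alpha for sample size n,
    from t = r sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("critical r undefined for n < 3")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


@dataclass
class CorrelationSummary:
    """Pairwise Pearson structure of a gene set over the stage lsmeans."""

    r_matrix: pd.DataFrame
    r_crit: float
    alpha: float
    frac_pos: float
    frac_neg: float
    frac_significant: float
    cut_fractions: pd.DataFrame  # per |r| cut: frac_pos, frac_neg, ratio


def correlation_summary(
    lsmeans: pd.DataFrame,
    alpha: float = 0.01,
    cuts: tuple[float, ...] = (0.4, 0.5, 0.8),
) -> CorrelationSummary:
    """Correlations of every unordered gene pair over the S stage lsmeans.

    Constant-profile genes are excluded with a logged warning (their Pearson
    r is undefined).  Fractions are over distinct unordered pairs.
    """
    X = lsmeans.to_numpy(float)
    keep = X.std(axis=1) > 0
    if (~keep).any():
        logger.warning(
            "excluding %d constant-profile gene(s) from correlations",
            int((~keep).sum()),
        )
    X = X[keep]
    index = lsmeans.index[keep]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 non-constant genes")
    n_stages = X.shape[1]
    R = np.corrcoef(X)
    iu = np.triu_indices(len(index), k=1)
    r = R[iu]
    r_crit = critical_r(n_stages, alpha)
    rows = []
    for cut in cuts:
        pos = float((r > cut).mean())
        neg = float((r < -cut).mean())
        rows.append(
            {
                "cut": cut,
                "frac_pos": pos,
                "frac_neg": neg,
                "ratio": pos / neg if neg > 0 else np.inf,
            }
        )
    return CorrelationSummary(
        r_matrix=pd.DataFrame(R, index=index, columns=index),
        r_crit=r_crit,
        alpha=alpha,
        frac_pos=float((r > r_crit).mean()),
        frac_neg=float((r < -r_crit).mean()),
        frac_significant=float(((r > r_crit) | (r < -r_crit)).mean()),
        cut_fractions=pd.DataFrame(rows),
    )


def dedup_by_annotation(
    genes: pd.DataFrame,
    name_col: str = "name",
    case_sensitive: bool = True,
) -> pd.DataFrame:
    """Keep the first-listed gene per distinct name (row order preserved).

    Used for analyses (e.g. ribosomal correlations) where spots sharing an
    annotation may represent the same transcript.
    """
    names = genes[name_col].astype(str)
    if not case_sensitive:
        names = names.str.lower()
    return genes[~names.duplicated(keep="first")]


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Average-linkage tree over genes or stages with correlation distance."""

    linkage: np.ndarray
    labels: list[str]
    axis: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels)

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        """Newick string with cophenetic branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            children = ",".join(rec(c, node.dist) for c in (node.left, node.right))
            return f"({children}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hcluster(matrix: pd.DataFrame, axis: str = "genes") -> Dendrogram:
    """Agglomerative clustering with distance 1 - Pearson r, average linkage.

    ``matrix`` is genes x stages; ``axis='stages'`` clusters the columns.
    """
    if axis not in ("genes", "stages"):
        raise ValueError("axis must be 'genes' or 'stages'")
    data = matrix if axis == "genes" else matrix.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    X = data.to_numpy(float)
    R = np.corrcoef(X)
    D = np.clip(1.0 - R, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=[str(l) for l in data.index], axis=axis)
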