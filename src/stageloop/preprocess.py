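"""Detection filtering and within-array Lowess normalization.

The detection rule uses herring-sperm control spots as the non-specific
hybridization background: a gene is kept only if at least one of its
channels exceeds the pooled control mean plus one sample SD.  Controls are
always removed.

Two-color arrays carry dye bias that depends on spot intensity and on slide
position.  Both are removed in (M, A) coordinates per array: a Lowess fit of
M on A per subgrid ("regional") followed by a smooth spatial fit of the
residual M over the slide, realized as successive Lowess fits on x and on y.
Only M is adjusted; the average log2 intensity A of every spot is preserved
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .design import LoopDesign
from .exceptions import InsufficientControlsError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x channels of log2 expression plus per-channel metadata.

    ``values`` is indexed by gene_id with one column per channel_id;
    ``channel_meta`` is indexed by channel_id with array_id, dye, stage,
    replicate and pool_id columns, in design channel order.
    """

    values: pd.DataFrame
    channel_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.channel_meta.index):
            raise ValueError("values columns must match channel_meta index")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, channel_meta=self.channel_meta)


def control_threshold(control_signals) -> float:
    """Detection threshold: mean + 1 sample SD of pooled control signals."""
    sig = np.asarray(control_signals, dtype=float)
    if sig.size < 2:
        raise InsufficientControlsError(
            "need at least 2 control signals to compute mean + SD"
        )
    return float(sig.mean() + sig.std(ddof=1))


def pooled_control_signals(tables: list[pd.DataFrame]) -> np.ndarray:
    """All herring-sperm signals from both channels of every array."""
    parts = []
    for tab in tables:
        ctrl = tab[tab["control_type"] == "herring_sperm"]
        parts.append(ctrl["signal_cy3"].to_numpy(float))
        parts.append(ctrl["signal_cy5"].to_numpy(float))
    return np.concatenate(parts) if parts else np.empty(0)


def filter_genes(tables: list[pd.DataFrame], threshold: float) -> pd.Index:
    """Genes whose raw signal exceeds ``threshold`` in at least one channel.

    The inequality is strict; controls never pass.  Returns gene ids in
    sorted order.
    """
    best: dict[str, float] = {}
    for tab in tables:
        genes = tab[tab["control_type"] == ""]
        m = np.maximum(
            genes["signal_cy3"].to_numpy(float), genes["signal_cy5"].to_numpy(float)
        )
        for gid, v in zip(genes["gene_id"], m):
            if v > best.get(gid, -np.inf):
                best[gid] = v
    kept = sorted(g for g, v in best.items() if v > threshold)
    return pd.Index(kept, name="gene_id")


def _lowess_fit(y: np.ndarray, x: np.ndarray, frac: float) -> np.ndarray:
    """Lowess fit of y on x evaluated at x, robust to tied/degenerate x."""
    if np.ptp(x) == 0 or y.size < 5:
        return np.full_like(y, y.mean())
    delta = 0.01 * np.ptp(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = _sm_lowess(y, x, frac=frac, delta=delta, return_sorted=False)
    # statsmodels returns NaN if interpolation fails on pathological input
    if np.isnan(fit).any():
        fit = np.where(np.isnan(fit), y.mean(), fit)
    return fit


def lowess_normalize(
    table: pd.DataFrame,
    *,
    span_intensity: float = 0.2,
    span_spatial: float = 0.3,
    region_col: str = "subgrid",
    spatial_mode: str = "separable",
) -> pd.DataFrame:
    """Joint regional and spatial Lowess correction of one array's M values.

    Stage 1 fits M on A per region (subgrid) and subtracts the fit; stage 2
    smooths the residual M over slide coordinates (successive Lowess on x
    then y by default) and subtracts again.  Returns a frame with corrected
    ``log2_cy3``/``log2_cy5`` per spot; A is preserved exactly.  Spots with a
    zero signal in either channel are dropped with a logged warning.
    """
    if spatial_mode not in ("separable", "none"):
        raise ValueError(f"unknown spatial_mode {spatial_mode!r}")
    spots = table[table["control_type"] == ""].copy()
    zero = (spots["signal_cy3"] <= 0) | (spots["signal_cy5"] <= 0)
    if zero.any():
        logger.warning(
            "array %s: dropping %d spot(s) with non-positive signal",
            table["array_id"].iloc[0] if len(table) else "?",
            int(zero.sum()),
        )
        spots = spots[~zero]
    log_cy3 = np.log2(spots["signal_cy3"].to_numpy(float))
    log_cy5 = np.log2(spots["signal_cy5"].to_numpy(float))
    M = log_cy5 - log_cy3
    A = 0.5 * (log_cy5 + log_cy3)

    M_corr = M.copy()
    for _, idx in spots.groupby(region_col).indices.items():
        M_corr[idx] = M[idx] - _lowess_fit(M[idx], A[idx], span_intensity)
    if spatial_mode == "separable":
        x = spots["x"].to_numpy(float)
        y = spots["y"].to_numpy(float)
        M_corr = M_corr - _lowess_fit(M_corr, x, span_spatial)
        M_corr = M_corr - _lowess_fit(M_corr, y, span_spatial)

    out = spots[["array_id", "gene_id"]].copy()
    out["A"] = A
    out["M"] = M_corr
    out["log2_cy5"] = A + M_corr / 2.0
    out["log2_cy3"] = A - M_corr / 2.0
    return out.reset_index(drop=True)


def build_expression_matrix(
    tables: list[pd.DataFrame],
    design: LoopDesign,
    genes: pd.Index,
    *,
    lowess: bool = True,
    span_intensity: float = 0.2,
    span_spatial: float = 0.3,
) -> ExpressionMatrix:
    """Assemble the filtered, normalized genes x channels log2 matrix.

    With ``lowess=False`` channels are plain log2 signals (useful when the
    dye-bias structure itself is under study).  Genes missing from any
    channel after zero-signal drops are excluded so the matrix is complete.
    """
    meta = design.channel_table().set_index("channel_id")
    by_array = {int(t["array_id"].iloc[0]): t for t in tables}
    missing = [a.array_id for a in design.arrays if a.array_id not in by_array]
    if missing:
        from .exceptions import ReconciliationError

        raise ReconciliationError(f"no spot table for arrays {missing}")

    cols: dict[str, pd.Series] = {}
    for arr in design.arrays:
        tab = by_array[arr.array_id]
        tab = tab[tab["gene_id"].isin(genes)]
        if lowess:
            norm = lowess_normalize(
                tab, span_intensity=span_intensity, span_spatial=span_spatial
            )
            cy3 = pd.Series(norm["log2_cy3"].to_numpy(), index=norm["gene_id"])
            cy5 = pd.Series(norm["log2_cy5"].to_numpy(), index=norm["gene_id"])
        else:
            keep = (tab["signal_cy3"] > 0) & (tab["signal_cy5"] > 0)
            tab = tab[keep]
            idx = tab["gene_id"]
            cy3 = pd.Series(np.log2(tab["signal_cy3"].to_numpy(float)), index=idx)
            cy5 = pd.Series(np.log2(tab["signal_cy5"].to_numpy(float)), index=idx)
        cols[f"A{arr.array_id}_Cy3"] = cy3
        cols[f"A{arr.array_id}_Cy5"] = cy5

    values = pd.DataFrame(cols).reindex(columns=meta.index)
    n_before = len(values)
    values = values.dropna()
    if len(values) < n_before:
        logger.warning(
            "dropped %d gene(s) missing from at least one channel",
            n_before - len(values),
        )
    values = values.loc[values.index.intersection(genes).sort_values()]
    values.index.name = "gene_id"
    return ExpressionMatrix(values=values, channel_meta=meta)
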