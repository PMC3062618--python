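"""Linear mixed models for two-color loop designs.

Two models are fit, mirroring the two-stage normalization + testing scheme
standard for loop designs:

1. A global normalization model across all genes,
       y = mu + A_i (random) + D_j (fixed) + (AxD)_ij (random) + eps,
   whose residuals remove array, dye and array-by-dye channel effects.

2. A per-gene model on those residuals,
       r = mu + A_i (random) + D_j (fixed) + T_k (fixed) + eps,
   where T is either the developmental stage (S levels) or a two-level
   pre/post-hatch recoding.  Stage least-squares means, the overall stage
   F test, and adjacent-stage contrasts all come from this fit.

Variance components are estimated by REML.  Because every array carries
exactly two channels, the per-array sum/difference transform diagonalizes
the marginal covariance (differences have variance sigma2_e, sums
sigma2_e + 2*sigma2_a), and a generalized eigendecomposition shared by all
genes reduces each REML profile evaluation to O(p) per gene; the profile
over the variance ratio is minimized by a vectorized golden-section search,
so tens of thousands of gene fits take seconds.

Fixed-effect inference (stage F test, lsmeans, contrasts) conditions on the
arrays — the classical exact analysis for a balanced block design with two
channels per block.  Its residual mean square has exactly
df_resid = n_channels - rank([X Z]) degrees of freedom, matching the
standard accounting for this design (dye 1, array 2S-1, stage S-1, residual
S: 40 residual d.f. at S=40, and 2S-2 = 78 for the two-level pre/post
model), so the F and t references are exact and p-values are uniform under
the null.  A Wald test built on the REML residual variance would pair a
~(3S)-df variance estimate with an S-df reference and be badly conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .design import LoopDesign
from .exceptions import DesignDeficientError, StageloopError
from .preprocess import ExpressionMatrix

_TINY = 1e-300
_W_MIN = 1e-8  # smallest sum-stratum weight, i.e. largest variance ratio


# ---------------------------------------------------------------------------
# global normalization
# ---------------------------------------------------------------------------


@dataclass
class GlobalNormalization:
    """Fitted channel-level effects and the residual expression matrix."""

    residuals: ExpressionMatrix
    mu: float
    dye_effects: pd.Series  # sum-to-zero, indexed Cy3/Cy5
    array_effects: pd.Series  # BLUPs, indexed by array_id
    channel_effects: pd.Series  # (AxD) BLUPs, indexed by channel_id
    sigma2_array: float
    sigma2_channel: float  # array x dye interaction variance
    sigma2_resid: float  # gene-level residual variance within channels
    dye_diff_se: float  # SE of the fitted Cy5 - Cy3 difference


def fit_global_normalization(matrix: ExpressionMatrix) -> GlobalNormalization:
    """Remove dye (fixed), array (random) and array-x-dye (random) effects.

    All genes act as replicate observations of each array-x-dye channel, so
    the model reduces to a mixed model on the channel means; random effects
    enter as BLUPs with method-of-moments variance components (truncated at
    zero), which keeps the fit closed-form and exactly reproducible.
    """
    meta = matrix.channel_meta
    arrays = meta["array_id"].unique()
    if len(arrays) < 2:
        raise DesignDeficientError("global normalization needs at least 2 arrays")
    Y = matrix.values.to_numpy(float)
    n_genes = Y.shape[0]
    ch_mean = pd.Series(Y.mean(axis=0), index=matrix.values.columns)

    mu = float(ch_mean.mean())
    dye = meta["dye"]
    dye_effects = ch_mean.groupby(dye).mean() - mu

    by_array = ch_mean.groupby(meta["array_id"])
    array_means = by_array.mean()
    # within-array dye difference carries the array x dye + residual variance
    cy5 = ch_mean[meta.index[dye == "Cy5"]].to_numpy()
    cy3 = ch_mean[meta.index[dye == "Cy3"]].to_numpy()
    d = cy5 - cy3
    n_arr = len(array_means)
    sigma2_cell = float(((d - d.mean()) ** 2).sum() / (2 * max(n_arr - 1, 1)))
    var_between = float(((array_means - mu) ** 2).sum() / max(n_arr - 1, 1))
    sigma2_array = max(0.0, var_between - sigma2_cell / 2.0)
    shrink_a = (
        sigma2_array / (sigma2_array + sigma2_cell / 2.0)
        if sigma2_array + sigma2_cell > 0
        else 0.0
    )
    array_effects = shrink_a * (array_means - mu)

    fitted_mean = (
        mu
        + dye_effects[dye].to_numpy()
        + array_effects[meta["array_id"]].to_numpy()
    )
    cell_resid = ch_mean.to_numpy() - fitted_mean
    sigma2_resid = float(Y.var(axis=0, ddof=1).mean()) if n_genes > 1 else 0.0
    sigma2_channel = max(0.0, sigma2_cell - sigma2_resid / max(n_genes, 1))
    denom = sigma2_channel + sigma2_resid / max(n_genes, 1)
    shrink_ad = sigma2_channel / denom if denom > 0 else 0.0
    channel_effects = pd.Series(shrink_ad * cell_resid, index=ch_mean.index)

    resid = Y - (fitted_mean + channel_effects.to_numpy())[None, :]
    residuals = matrix.copy_with(
        pd.DataFrame(resid, index=matrix.values.index, columns=matrix.values.columns)
    )
    dye_diff_se = float(np.sqrt(2.0 * sigma2_cell / max(n_arr, 1)))
    return GlobalNormalization(
        residuals=residuals,
        mu=mu,
        dye_effects=dye_effects,
        array_effects=array_effects,
        channel_effects=channel_effects,
        sigma2_array=sigma2_array,
        sigma2_channel=sigma2_channel,
        sigma2_resid=sigma2_resid,
        dye_diff_se=dye_diff_se,
    )


# ---------------------------------------------------------------------------
# per-gene mixed model
# ---------------------------------------------------------------------------


def _design_matrix(
    dye_sign: np.ndarray, levels: np.ndarray, n_levels: int
) -> np.ndarray:
    """[intercept | dye (+-1) | treatment, sum-to-zero] design matrix."""
    n = len(levels)
    X = np.zeros((n, 2 + n_levels - 1))
    X[:, 0] = 1.0
    X[:, 1] = dye_sign
    for l in range(1, n_levels):
        X[:, 1 + l] = (levels == l).astype(float) - (levels == n_levels).astype(float)
    return X


@dataclass
class _Strata:
    """Sum/difference-transformed design pieces shared by every gene."""

    phi: np.ndarray  # generalized eigenvalues of (Xs'Xs, X'X), in [0, 1]
    R: np.ndarray  # X'X-orthonormal eigenvectors (p x p)
    Ps: np.ndarray  # Xs @ R
    Pd: np.ndarray  # Xd @ R


def _build_strata(Xs: np.ndarray, Xd: np.ndarray) -> _Strata:
    Gs = Xs.T @ Xs
    B = Gs + Xd.T @ Xd  # = X'X in the transformed basis
    phi, R = scipy.linalg.eigh(Gs, B)
    phi = np.clip(phi, 0.0, 1.0)
    return _Strata(phi=phi, R=R, Ps=Xs @ R, Pd=Xd @ R)


class LoopMixedModel:
    """Vectorized REML engine for r = mu + A(random) + D + T + eps on a loop.

    ``levels`` maps each channel (in design channel order) to a treatment
    level 1..L; for the stage model L = S, for the pre/post model L = 2.
    """

    def __init__(self, design: LoopDesign, levels: np.ndarray):
        design.validate()
        self.design = design
        meta = design.channel_table()
        self.meta = meta
        self.levels = np.asarray(levels, int)
        self.n_levels = int(self.levels.max())
        n = len(meta)
        self.n_obs = n
        self.n_arrays = design.n_arrays
        dye_sign = np.where(meta["dye"].to_numpy() == "Cy5", 1.0, -1.0)
        X = _design_matrix(dye_sign, self.levels, self.n_levels)
        self.p = X.shape[1]
        # per-array sum/difference transform; channel order is (Cy3, Cy5) pairs
        cy3_rows = np.arange(0, n, 2)
        cy5_rows = np.arange(1, n, 2)
        self._cy3_rows, self._cy5_rows = cy3_rows, cy5_rows
        s = 1.0 / np.sqrt(2.0)
        Xs = s * (X[cy3_rows] + X[cy5_rows])
        Xd = s * (X[cy5_rows] - X[cy3_rows])
        self.full = _build_strata(Xs, Xd)
        self.reduced = _build_strata(Xs[:, :2], Xd[:, :2])
        self.df_resid = n - self.n_arrays - self.n_levels
        self.df_breakdown = {
            "dye": 1,
            "array": self.n_arrays - 1,
            "treatment": self.n_levels - 1,
            "residual": self.df_resid,
        }
        if self.df_resid <= 0:
            raise DesignDeficientError("no residual degrees of freedom")
        # exact conditional-on-arrays (block ANOVA) design: X plus sum-to-zero
        # array dummies; its residual mean square has df_resid degrees of freedom
        arr_codes = pd.factorize(meta["array_id"])[0]
        Zc = np.zeros((n, self.n_arrays - 1))
        for i in range(self.n_arrays - 1):
            Zc[:, i] = (arr_codes == i).astype(float) - (
                arr_codes == self.n_arrays - 1
            ).astype(float)
        W = np.hstack([X, Zc])
        if np.linalg.matrix_rank(W) != W.shape[1]:
            raise DesignDeficientError("stage effects confounded with arrays")
        self._W = W
        self._W0 = np.hstack([X[:, :2], Zc])
        self._WtW_inv = np.linalg.inv(W.T @ W)
        self._P_w = self._WtW_inv @ W.T
        W0tW0_inv = np.linalg.inv(self._W0.T @ self._W0)
        self._P_w0 = W0tW0_inv @ self._W0.T
        # lsmean vectors over W columns: lsmean_l = mu + T_l (array terms zero)
        Cw = np.zeros((self.n_levels, W.shape[1]))
        Cw[:, 0] = 1.0
        for l in range(1, self.n_levels):
            Cw[l - 1, 1 + l] = 1.0
            Cw[self.n_levels - 1, 1 + l] = -1.0
        self._lsmean_ctr = Cw
        self._lsmean_quad = np.einsum(
            "lp,pq,lq->l", Cw, self._WtW_inv, Cw
        )  # c' (W'W)^-1 c per lsmean

    # -- REML profile -------------------------------------------------------

    def _transform(self, Y: np.ndarray) -> tuple[np.ndarray, ...]:
        s = 1.0 / np.sqrt(2.0)
        Ys = s * (Y[:, self._cy3_rows] + Y[:, self._cy5_rows])
        Yd = s * (Y[:, self._cy5_rows] - Y[:, self._cy3_rows])
        return Ys, Yd

    @staticmethod
    def _rss(strata: _Strata, w, Us, Ud, qs, qd) -> np.ndarray:
        """GLS residual sum of squares at weight w (scalar or per-gene)."""
        nu = w * strata.phi[:, None] + (1.0 - strata.phi)[:, None]
        bt = w * Us + Ud
        return w * qs + qd - (bt * bt / nu).sum(axis=0)

    def _criterion(self, w, Us, Ud, qs, qd) -> np.ndarray:
        """-2 REML log-likelihood profiled over sigma2_e, up to constants."""
        st = self.full
        nu = w * st.phi[:, None] + (1.0 - st.phi)[:, None]
        bt = w * Us + Ud
        rss = np.maximum(w * qs + qd - (bt * bt / nu).sum(axis=0), _TINY)
        return (
            (self.n_obs - self.p) * np.log(rss)
            - self.n_arrays * np.log(w)
            + np.log(nu).sum(axis=0)
        )

    def fit(self, matrix: ExpressionMatrix) -> "MixedFitResult":
        """REML-fit every gene in ``matrix`` (rows) at once."""
        if list(matrix.values.columns) != list(self.meta["channel_id"]):
            raise StageloopError("matrix channels do not match the design")
        Y = matrix.values.to_numpy(float)
        Ys, Yd = self._transform(Y)
        st, st0 = self.full, self.reduced
        Us = st.Ps.T @ Ys.T
        Ud = st.Pd.T @ Yd.T
        Us0 = st0.Ps.T @ Ys.T
        Ud0 = st0.Pd.T @ Yd.T
        qs = (Ys * Ys).sum(axis=1)
        qd = (Yd * Yd).sum(axis=1)
        G = Y.shape[0]

        # coarse grid on log w, then vectorized golden-section refinement
        t_grid = np.linspace(np.log(_W_MIN), 0.0, 25)
        crit = np.stack(
            [self._criterion(np.exp(t), Us, Ud, qs, qd) for t in t_grid]
        )
        best = crit.argmin(axis=0)
        lo = t_grid[np.maximum(best - 1, 0)]
        hi = t_grid[np.minimum(best + 1, len(t_grid) - 1)]
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo.copy(), hi.copy()
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc = self._criterion(np.exp(c), Us, Ud, qs, qd)
        fd = self._criterion(np.exp(d), Us, Ud, qs, qd)
        for _ in range(60):
            left = fc < fd
            b = np.where(left, d, b)
            a = np.where(left, a, c)
            c_new = b - gr * (b - a)
            d_new = a + gr * (b - a)
            # only one endpoint moved per gene; recompute both (vector ops are cheap)
            c, d = c_new, d_new
            fc = self._criterion(np.exp(c), Us, Ud, qs, qd)
            fd = self._criterion(np.exp(d), Us, Ud, qs, qd)
        t_hat = 0.5 * (a + b)
        # check the lambda = 0 boundary explicitly
        f_hat = self._criterion(np.exp(t_hat), Us, Ud, qs, qd)
        f_one = self._criterion(1.0, Us, Ud, qs, qd)
        t_hat = np.where(f_one <= f_hat, 0.0, t_hat)
        w_hat = np.exp(t_hat)
        lam = (1.0 / w_hat - 1.0) / 2.0

        nu = w_hat * st.phi[:, None] + (1.0 - st.phi)[:, None]
        bt = w_hat * Us + Ud
        rss_gls = np.maximum(w_hat * qs + qd - (bt * bt / nu).sum(axis=0), 0.0)
        sigma2_e = rss_gls / (self.n_obs - self.p)
        sigma2_a = lam * sigma2_e

        # exact block-ANOVA fixed-effect inference, conditional on arrays
        Yt = Y.T  # (n x G)
        beta_w = self._P_w @ Yt
        resid = Yt - self._W @ beta_w
        rss = (resid * resid).sum(axis=0)
        resid0 = Yt - self._W0 @ (self._P_w0 @ Yt)
        rss0 = (resid0 * resid0).sum(axis=0)
        ms_resid = rss / self.df_resid
        q = self.n_levels - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(
                ms_resid > 0,
                np.maximum(rss0 - rss, 0.0) / q / np.maximum(ms_resid, _TINY),
                np.inf,
            )
        p_overall = stats.f.sf(F, q, self.df_resid)

        Cw = self._lsmean_ctr  # (L x p_w)
        lsmeans = Cw @ beta_w  # (L x G)
        lsvar = self._lsmean_quad[:, None] * ms_resid
        return MixedFitResult(
            model=self,
            gene_ids=matrix.values.index.to_numpy(),
            w_hat=w_hat,
            beta_w=beta_w,
            ms_resid=ms_resid,
            sigma2_array=sigma2_a,
            sigma2_resid=sigma2_e,
            F=F,
            p_overall=np.asarray(p_overall),
            lsmeans=lsmeans.T,
            lsmean_se=np.sqrt(np.maximum(lsvar, 0.0)).T,
        )


@dataclass
class MixedFitResult:
    """Vectorized per-gene fits: variance components, lsmeans, tests.

    sigma2_array / sigma2_resid are the REML variance components;
    ms_resid is the block-ANOVA residual mean square (df_resid degrees of
    freedom) that standard errors, F and t statistics are built on.
    """

    model: LoopMixedModel
    gene_ids: np.ndarray
    w_hat: np.ndarray
    beta_w: np.ndarray  # (p_w x G) conditional-on-arrays fixed effects
    ms_resid: np.ndarray
    sigma2_array: np.ndarray
    sigma2_resid: np.ndarray
    F: np.ndarray
    p_overall: np.ndarray
    lsmeans: np.ndarray  # (G x L)
    lsmean_se: np.ndarray  # (G x L)

    @property
    def df_breakdown(self) -> dict:
        return dict(self.model.df_breakdown)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def lsmeans_frame(self) -> pd.DataFrame:
        cols = [f"stage_{l}" for l in range(1, self.model.n_levels + 1)]
        return pd.DataFrame(self.lsmeans, index=self.gene_ids, columns=cols)

    def lsmean_se_frame(self) -> pd.DataFrame:
        cols = [f"stage_{l}" for l in range(1, self.model.n_levels + 1)]
        return pd.DataFrame(self.lsmean_se, index=self.gene_ids, columns=cols)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "F": self.F,
                "p_overall": self.p_overall,
                "sigma2_array": self.sigma2_array,
                "sigma2_resid": self.sigma2_resid,
            }
        ).set_index("gene_id")

    def _contrast_stats(self, k: int, l: int) -> tuple[np.ndarray, np.ndarray]:
        """delta = lsmean_k - lsmean_l with its model SE (1-based levels)."""
        Cw = self.model._lsmean_ctr
        c = Cw[k - 1] - Cw[l - 1]
        delta = c @ self.beta_w
        var = float(c @ self.model._WtW_inv @ c) * self.ms_resid
        return delta, np.sqrt(np.maximum(var, 0.0))

    def contrast(self, k: int, l: int) -> pd.DataFrame:
        """t-test of lsmean_k - lsmean_l with containment denominator df."""
        delta, se = self._contrast_stats(k, l)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
        p = 2.0 * stats.t.sf(np.abs(t), self.model.df_resid)
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "pair": f"{k}-{l}",
                "delta": delta,
                "se": se,
                "t": t,
                "p": p,
                "neg_log10_p": -np.log10(np.maximum(p, _TINY)),
            }
        )


def fit_gene_models(
    matrix: ExpressionMatrix, design: LoopDesign
) -> MixedFitResult:
    """Fit the per-gene stage model to every gene of a (residual) matrix."""
    levels = design.channel_table()["stage"].to_numpy()
    return LoopMixedModel(design, levels).fit(matrix)


def fit_gene_model(
    values, design: LoopDesign, gene_id: str = "gene"
) -> MixedFitResult:
    """Convenience single-gene fit; ``values`` follows design channel order."""
    meta = design.channel_table()
    mat = ExpressionMatrix(
        values=pd.DataFrame(
            [np.asarray(values, float)],
            index=pd.Index([gene_id], name="gene_id"),
            columns=meta["channel_id"],
        ),
        channel_meta=meta.set_index("channel_id"),
    )
    return fit_gene_models(mat, design)


def overall_stage_test(fit: MixedFitResult, alpha: float = 0.01) -> pd.Index:
    """Genes whose overall stage F test has p < alpha (no multiplicity
    adjustment: the analysis works at a nominal per-gene cut-off)."""
    mask = fit.p_overall < alpha
    return pd.Index(fit.gene_ids[mask], name="gene_id")


def adjacent_contrasts(fit: MixedFitResult) -> pd.DataFrame:
    """All S-1 adjacent-stage contrasts, delta = earlier - later lsmean."""
    frames = [
        fit.contrast(k, k + 1) for k in range(1, fit.model.n_levels)
    ]
    return pd.concat(frames, ignore_index=True)


def fit_prepost(
    matrix: ExpressionMatrix, design: LoopDesign, split_stage: int = 35
) -> MixedFitResult:
    """Two-level recoding of stage: pre (<= split) vs post (> split).

    delta in the resulting contrasts is pre - post; the post/pre log2 fold
    change is its negation.
    """
    if not (1 <= split_stage <= design.n_stages - 1):
        raise StageloopError(
            f"split stage must be in [1, {design.n_stages - 1}]"
        )
    stages = design.channel_table()["stage"].to_numpy()
    levels = np.where(stages <= split_stage, 1, 2)
    return LoopMixedModel(design, levels).fit(matrix)


def prepost_contrasts(fit: MixedFitResult) -> pd.DataFrame:
    """Pre-vs-post contrast table with the post/pre log2 fold change."""
    out = fit.contrast(1, 2)
    out["pair"] = "pre-post"
    out["log2_fc_post_pre"] = -out["delta"]
    return out
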