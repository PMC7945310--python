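"""Loss-of-function calling from beta scores with a Gaussian mixture.

A four-component Gaussian mixture is fitted to the beta-score
distribution of one screen library.  The expected structure is one
null-like component with mean near zero, two components with negative
means (deleterious variants) and one with positive mean.  A variant is
called loss-of-function when its summed posterior over the two
negative-mean components, P_i, exceeds 0.8.  Significance of each
variant's mean beta is assessed with a Wald test (mean/SE against the
standard normal) and Benjamini-Hochberg correction across the library.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LOF_POSTERIOR_THRESHOLD = 0.8
MIN_SCORES = 50


class LofGaussianMixture(BaseEstimator):
    """Gaussian-mixture loss-of-function classifier over beta scores.

    Parameters
    ----------
    n_components : number of mixture components (4 for calling).
    threshold : posterior mass on the negative-mean components above which
        a variant is called loss-of-function (strict inequality).
    n_init : random EM restarts (k-means initialization).
    tol : EM convergence tolerance on the mean log-likelihood.
    max_iter : EM iteration cap per restart.
    random_state : seed for reproducible fits.

    Attributes
    ----------
    weights_, means_, variances_ : fitted mixture parameters (length K).
    negative_components_ : indices of the two negative-mean components.
    beta_cutoff_ : the beta score at which P(beta) crosses ``threshold``
        (the library's equivalent score cutoff), found by bisection.
    converged_, loglik_ : EM diagnostics.
    """

    def __init__(
        self,
        n_components: int = 4,
        threshold: float = LOF_POSTERIOR_THRESHOLD,
        n_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 1000,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.threshold = threshold
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _validate(self, scores) -> np.ndarray:
        x = np.asarray(scores, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < MIN_SCORES:
            raise ValueError(f"need >= {MIN_SCORES} finite scores, got {x.size}")
        if np.ptp(x) == 0:
            raise ValueError("degenerate score distribution (all values identical)")
        return x

    def fit(self, scores, y=None) -> "LofGaussianMixture":
        x = self._validate(scores)
        gm = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            n_init=self.n_init,
            tol=self.tol,
            max_iter=self.max_iter,
            init_params="kmeans",
            random_state=self.random_state,
        ).fit(x[:, None])
        if not gm.converged_:
            raise RuntimeError(
                f"EM did not converge in any of {self.n_init} restarts "
                f"(final lower bound {gm.lower_bound_:.4g})"
            )
        self.gmm_ = gm
        self.weights_ = gm.weights_.copy()
        self.means_ = gm.means_.ravel().copy()
        self.variances_ = gm.covariances_.reshape(-1).copy()
        self.converged_ = bool(gm.converged_)
        self.loglik_ = float(gm.score(x[:, None]) * x.size)
        neg = np.flatnonzero(self.means_ < 0)
        if neg.size != 2:
            warnings.warn(
                f"expected 2 negative-mean components, found {neg.size}; "
                "falling back to the two smallest means", stacklevel=2,
            )
            neg = np.argsort(self.means_)[:2]
        self.negative_components_ = np.sort(neg)
        self.beta_cutoff_ = self._find_cutoff()
        return self

    def posterior(self, scores) -> np.ndarray:
        """P_i: summed posterior over the negative-mean components."""
        x = np.asarray(scores, dtype=float).ravel()
        out = np.full(x.shape, np.nan)
        ok = np.isfinite(x)
        if ok.any():
            resp = self.gmm_.predict_proba(x[ok, None])
            out[ok] = resp[:, self.negative_components_].sum(axis=1)
        return out

    # alias with sklearn naming; column 1 is the LOF probability
    def predict_proba(self, scores) -> np.ndarray:
        p = self.posterior(scores)
        return np.column_stack([1 - p, p])

    def predict(self, scores) -> np.ndarray:
        return self.posterior(scores) > self.threshold

    def _find_cutoff(self) -> float:
        """Bisection for the equivalent beta cutoff where P crosses threshold.

        P(beta) decreases from the negative-mean region toward the null
        region; the cutoff is the rightmost crossing of the threshold on
        the span from below the negative means up to max(0, largest mean).
        A broad null component can re-dominate in the extreme left tail,
        so the search starts at the negative means rather than -inf.
        """
        neg = self.negative_components_
        sd_neg = float(np.sqrt(self.variances_[neg].max()))
        lo = float(self.means_[neg].min() - 2 * sd_neg)
        hi = float(max(self.means_.max(), 0.0))
        grid = np.linspace(lo, hi, 1024)
        pg = self.posterior(grid)
        above = np.flatnonzero(pg > self.threshold)
        if above.size == 0 or above[-1] == grid.size - 1:
            warnings.warn("posterior never crosses the threshold; no cutoff",
                          stacklevel=2)
            return float("nan")
        a, b = grid[above[-1]], grid[above[-1] + 1]
        for _ in range(100):
            mid = 0.5 * (a + b)
            if self.posterior([mid])[0] > self.threshold:
                a = mid
            else:
                b = mid
            if b - a < 1e-10:
                break
        return 0.5 * (a + b)

    def check_monotone(self, n_grid: int = 256) -> bool:
        """Warn if P(beta) is not non-increasing across the negative span."""
        lo = float(self.means_.min())
        hi = float(max(self.means_.max(), 0.0))
        grid = np.linspace(lo, hi, n_grid)
        pg = self.posterior(grid)
        ok = bool(np.all(np.diff(pg) <= 1e-9))
        if not ok:
            warnings.warn("LOF posterior is not monotone over the negative span",
                          stacklevel=2)
        return ok


def fit_gmm(
    scores,
    n_components: int = 4,
    seed: int | None = 0,
    n_init: int = 10,
    tol: float = 1e-6,
) -> LofGaussianMixture:
    """Fit the mixture; functional wrapper over :class:`LofGaussianMixture`."""
    return LofGaussianMixture(
        n_components=n_components, n_init=n_init, tol=tol, random_state=seed
    ).fit(scores)


def lof_posterior_and_call(
    scores,
    fit: LofGaussianMixture,
    threshold: float = LOF_POSTERIOR_THRESHOLD,
) -> pd.DataFrame:
    """P_i, the LOF call and the library's equivalent beta cutoff."""
    p = fit.posterior(scores)
    return pd.DataFrame({
        "P": p,
        "lof_call": p > threshold,
        "beta_cutoff": fit.beta_cutoff_,
    })


def model_selection_report(scores, ks: Sequence[int] = range(2, 7), seed: int = 0) -> pd.DataFrame:
    """AIC/BIC over candidate component counts (diagnostic only; K=4 calls)."""
    x = np.asarray(scores, dtype=float).ravel()
    x = x[np.isfinite(x)][:, None]
    rows = []
    for k in ks:
        gm = GaussianMixture(n_components=k, n_init=5, random_state=seed).fit(x)
        rows.append({"n_components": k, "aic": gm.aic(x), "bic": gm.bic(x),
                     "converged": gm.converged_})
    return pd.DataFrame(rows)


def wald_bh(beta_by_replicate: pd.DataFrame) -> pd.DataFrame:
    """Wald z and p per variant plus Benjamini-Hochberg adjusted p.

    ``beta_by_replicate`` is variants x replicates.  z = mean / SE with
    SE = sd / sqrt(n); two-sided p against the standard normal.  Variants
    with fewer than 2 finite replicates get NaN.  SE = 0 yields p = 0 when
    the mean is nonzero, p = 1 otherwise (flagged in ``se_zero``).
    """
    arr = beta_by_replicate.to_numpy(dtype=float)
    n = np.isfinite(arr).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(arr), arr, np.nan), axis=1)
        sd = np.nanstd(np.where(np.isfinite(arr), arr, np.nan), axis=1, ddof=1)
    se = sd / np.sqrt(n)
    z = np.full(mean.shape, np.nan)
    p = np.full(mean.shape, np.nan)
    se_zero = np.zeros(mean.shape, dtype=bool)
    valid = n >= 2
    pos_se = valid & (se > 0)
    z[pos_se] = mean[pos_se] / se[pos_se]
    p[pos_se] = 2 * stats.norm.sf(np.abs(z[pos_se]))
    zero_se = valid & (se == 0)
    se_zero |= zero_se
    z[zero_se & (mean != 0)] = np.inf * np.sign(mean[zero_se & (mean != 0)])
    p[zero_se] = np.where(mean[zero_se] != 0, 0.0, 1.0)
    bh = np.full(mean.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        bh[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame({
        "mean_beta": mean, "se_beta": se, "wald_z": z, "wald_p": p,
        "bh_p": bh, "se_zero": se_zero,
    }, index=beta_by_replicate.index)


def evaluate(
    calls: pd.DataFrame,
    labels: pd.Series | None = None,
    positive: str = "P/LP",
    negative: str = "B/LB",
    specificity: float = 0.95,
) -> dict:
    """Enrichment and ROC summaries of a call set.

    ``calls`` needs mean_beta, lof_call and (optionally) mutational_type.
    ``labels`` maps variant ids to clinical classes; pathogenic variants
    are ranked positive along -mean_beta (more negative beta = more
    deleterious).  Returns category enrichment (LOF fraction + Fisher
    exact versus the other categories) and, when labels allow, AUC,
    sensitivity at the requested specificity and the binary call's
    sensitivity/specificity.
    """
    report: dict = {}
    if "mutational_type" in calls.columns:
        rows = []
        for mtype, grp in calls.groupby("mutational_type"):
            rest = calls[calls["mutational_type"] != mtype]
            a = int(grp["lof_call"].sum())
            b = int(len(grp) - a)
            c = int(rest["lof_call"].sum())
            d = int(len(rest) - c)
            _, pval = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({"mutational_type": mtype, "n": len(grp),
                         "lof_fraction": a / len(grp) if len(grp) else np.nan,
                         "fisher_p": pval})
        report["enrichment"] = pd.DataFrame(rows)
    if labels is not None:
        lab = labels.reindex(calls["guide_id"] if "guide_id" in calls.columns
                             else calls.index)
        y = pd.Series(np.where(lab.values == positive, 1,
                               np.where(lab.values == negative, 0, -1)),
                      index=calls.index)
        mask = (y >= 0) & calls["mean_beta"].notna().values
        if mask.sum() == 0 or y[mask].nunique() < 2:
            logger.warning("ROC skipped: need both positive and negative labels")
        else:
            score = -calls.loc[mask, "mean_beta"].values
            y_true = y[mask].values
            report["auc"] = float(roc_auc_score(y_true, score))
            fpr, tpr, _ = roc_curve(y_true, score)
            sens = tpr[fpr <= 1 - specificity]
            report["sensitivity_at_specificity"] = float(sens.max()) if sens.size else 0.0
            called = calls.loc[mask, "lof_call"].values.astype(bool)
            pos, neg = y_true == 1, y_true == 0
            report["call_sensitivity"] = float(called[pos].mean()) if pos.any() else np.nan
            report["call_specificity"] = float((~called[neg]).mean()) if neg.any() else np.nan
    return report


def classify_scores(
    scores: pd.DataFrame,
    threshold: float = LOF_POSTERIOR_THRESHOLD,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Fit the mixture on filtered scores and call LOF variants.

    ``scores`` is the score table (guide_id, beta_<rep>..., mean_beta,
    filtered).  Targeting guides passing the filters enter the fit;
    everything scored receives a posterior.  Returns (calls, fit report).
    """
    df = scores.set_index("guide_id") if "guide_id" in scores.columns else scores.copy()
    usable = df["mean_beta"].notna()
    if "filtered" in df.columns:
        usable &= ~df["filtered"].astype(bool)
    if "control_class" in df.columns:
        usable &= df["control_class"] != "non_targeting"
    fit = LofGaussianMixture(threshold=threshold, random_state=seed).fit(
        df.loc[usable, "mean_beta"]
    )
    fit.check_monotone()
    p = fit.posterior(df["mean_beta"])
    rep_cols = [c for c in df.columns if c.startswith("beta_")]
    stats_df = wald_bh(df[rep_cols]) if rep_cols else None
    calls = pd.DataFrame({
        "mean_beta": df["mean_beta"],
        "P": p,
        "lof_call": (p > threshold) & usable,
        "in_fit": usable,
    }, index=df.index)
    if stats_df is not None:
        calls["wald_z"] = stats_df["wald_z"]
        calls["wald_p"] = stats_df["wald_p"]
        calls["bh_p"] = stats_df["bh_p"]
    for c in ("mutational_type", "control_class", "q_scaled"):
        if c in df.columns:
            calls[c] = df[c]
    # crude empirical proxy for the call set's purity, NOT a model-based
    # FDR estimate: share of calls that hit expected-null variants
    null_like = pd.Series(False, index=calls.index)
    if "mutational_type" in calls.columns:
        null_like |= calls["mutational_type"].eq("synonymous")
    if "control_class" in calls.columns:
        null_like |= calls["control_class"].eq("non_targeting")
    n_calls = int(calls["lof_call"].sum())
    proxy = float((calls["lof_call"] & null_like).sum() / n_calls) if n_calls else float("nan")
    report = {
        "empirical_null_call_fraction": proxy,
        "weights": fit.weights_.tolist(),
        "means": fit.means_.tolist(),
        "variances": fit.variances_.tolist(),
        "negative_components": fit.negative_components_.tolist(),
        "beta_cutoff": fit.beta_cutoff_,
        "loglik": fit.loglik_,
        "converged": fit.converged_,
        "threshold": threshold,
        "n_fit": int(usable.sum()),
    }
    return calls.reset_index(), report
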