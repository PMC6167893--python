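"""Design-based estimation for complex-survey cohorts.

Implements Horvitz–Thompson ratio means and survey-weighted pseudo-maximum-
likelihood GLMs (linear and logistic) with Taylor-linearized ("sandwich")
variance estimated from between-PSU variation within strata, as used for
two-stage stratified samples analysed with sampling weights. Subpopulation
(domain) analysis keeps every record of the full design in the variance
computation and zeroes the score contributions of out-of-domain records,
which is the standard guard against the bias of naive row-dropping.

Point estimation of the weighted GLM is delegated to :mod:`statsmodels`
(``var_weights`` pseudo-likelihood); everything design-based — PSU/stratum
score aggregation, domain zeroing, the sandwich itself — is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from ._design import build_design_matrix

__all__ = [
    "SurveyDesign",
    "FitResult",
    "MeanResult",
    "SurveyGLM",
    "estimate_mean_prop",
    "fit_weighted_glm",
    "adjusted_genotype_means",
    "SeparationError",
    "RankDeficiencyError",
    "SinglePSUError",
]

Z95 = float(stats.norm.ppf(0.975))


class SeparationError(RuntimeError):
    """Logistic fit shows (quasi-)complete separation."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient on the estimation sample."""


class SinglePSUError(ValueError):
    """A stratum contributes a single PSU; between-PSU variance is undefined."""


@dataclass
class SurveyDesign:
    """Stratum / PSU / weight structure governing all variance computation.

    Parameters
    ----------
    strata, psu : arrays of identifiers, one per record.
    weights : positive sampling weights (inverse inclusion probabilities,
        possibly rescaled; estimates are invariant to a common rescaling).
    subpop : optional boolean domain indicator. Out-of-domain records never
        enter point estimation but always remain in the variance computation.
    """

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray
    subpop: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        self.psu = np.asarray(self.psu)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.weights)
        if len(self.strata) != n or len(self.psu) != n:
            raise ValueError("strata, psu and weights must have equal length")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("sampling weights must be strictly positive")
        if self.subpop is not None:
            self.subpop = np.asarray(self.subpop, dtype=bool)
            if len(self.subpop) != n:
                raise ValueError("subpop indicator length mismatch")
        # each PSU must sit in exactly one stratum
        tab = pd.DataFrame({"s": self.strata, "p": self.psu})
        bad = tab.groupby("p")["s"].nunique()
        if (bad > 1).any():
            dup = bad[bad > 1].index.tolist()
            raise ValueError(f"PSU(s) {dup} appear in more than one stratum")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        strata: str = "stratum",
        psu: str = "psu",
        weight: str = "sampling_weight",
        subpop: str | np.ndarray | None = None,
    ) -> "SurveyDesign":
        sp = None
        if isinstance(subpop, str):
            sp = df[subpop].to_numpy(dtype=bool)
        elif subpop is not None:
            sp = np.asarray(subpop, dtype=bool)
        return cls(df[strata].to_numpy(), df[psu].to_numpy(), df[weight].to_numpy(), sp)

    @property
    def n(self) -> int:
        return len(self.weights)

    def replace_subpop(self, subpop: np.ndarray | None) -> "SurveyDesign":
        return SurveyDesign(self.strata, self.psu, self.weights, subpop)


@dataclass
class FitResult:
    """Coefficients plus design-based inference for one fitted equation."""

    names: list[str]
    params: np.ndarray
    cov: np.ndarray
    family: str
    n_used: int
    converged: bool
    alpha: float = 0.05

    @property
    def bse(self) -> np.ndarray:
        # with few PSUs the sandwich is rank-limited; clip numerical negatives
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self) -> np.ndarray:
        z = stats.norm.ppf(1 - self.alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        out = pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.params,
                "se": self.bse,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p_value": self.pvalues,
            }
        )
        if self.family == "logit":
            out["odds_ratio"] = np.exp(self.params)
            out["or_ci_low"] = np.exp(ci[:, 0])
            out["or_ci_high"] = np.exp(ci[:, 1])
        return out

    def __getitem__(self, term: str) -> float:
        return float(self.params[self.names.index(term)])


@dataclass
class MeanResult:
    estimate: float
    se: float
    ci: tuple[float, float]
    n_used: int


def _psu_score_totals(
    scores: np.ndarray, design: SurveyDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-record score rows within (stratum, PSU); returns (totals, strata ids)."""
    key = pd.MultiIndex.from_arrays([design.strata, design.psu])
    df = pd.DataFrame(np.atleast_2d(scores.T).T, index=key)
    tot = df.groupby(level=[0, 1], sort=True).sum()
    return tot.to_numpy(), tot.index.get_level_values(0).to_numpy()


def taylor_variance(
    scores: np.ndarray, design: SurveyDesign, single_psu: str = "error"
) -> np.ndarray:
    """Between-PSU-within-stratum variance of a score total.

    ``scores`` holds one linearized score row per record of the *full* design
    (zeros for records outside the domain / estimation sample). Strata are
    treated as sampled with replacement at the first stage:
    ``V = sum_h n_h/(n_h-1) sum_j (z_hj - zbar_h)(z_hj - zbar_h)'``.

    single_psu: 'error' raises on a lone-PSU stratum; 'center' deviates such
    strata from the grand mean of all PSU totals instead.
    """
    if single_psu not in ("error", "center"):
        raise ValueError("single_psu must be 'error' or 'center'")
    z, strata = _psu_score_totals(scores, design)
    p = z.shape[1]
    V = np.zeros((p, p))
    grand = z.mean(axis=0)
    for h in pd.unique(strata):
        zh = z[strata == h]
        nh = len(zh)
        if nh == 1:
            if single_psu == "error":
                raise SinglePSUError(
                    f"stratum {h!r} has a single PSU; variance undefined "
                    "(pass single_psu='center' to deviate from the grand mean)"
                )
            d = zh - grand
            V += d.T @ d
            continue
        d = zh - zh.mean(axis=0)
        V += (nh / (nh - 1)) * (d.T @ d)
    return V


def estimate_mean_prop(
    design: SurveyDesign,
    values: np.ndarray | pd.Series,
    subpop: np.ndarray | None = None,
    single_psu: str = "error",
    alpha: float = 0.05,
) -> MeanResult:
    """Horvitz–Thompson ratio mean (or proportion for a 0/1 variable).

    Missing values are treated as outside the estimation domain but their
    records stay in the variance computation, as do records outside
    ``subpop``.
    """
    y = np.asarray(values, dtype=float)
    if len(y) != design.n:
        raise ValueError("variable length does not match design")
    dom = ~np.isnan(y)
    if subpop is not None:
        dom &= np.asarray(subpop, dtype=bool)
    if design.subpop is not None:
        dom &= design.subpop
    if not dom.any():
        raise ValueError("empty estimation domain")
    w = design.weights
    wsum = float(np.sum(w[dom]))
    est = float(np.sum(w[dom] * y[dom]) / wsum)
    # linearized residuals, zero outside the domain
    e = np.zeros(design.n)
    e[dom] = w[dom] * (y[dom] - est) / wsum
    V = taylor_variance(e[:, None], design, single_psu=single_psu)
    se = float(np.sqrt(V[0, 0]))
    z = stats.norm.ppf(1 - alpha / 2)
    return MeanResult(est, se, (est - z * se, est + z * se), int(dom.sum()))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns with pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        keep = piv[:rank]
        aliased = [names[j] for j in sorted(set(range(X.shape[1])) - set(keep))]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]}; aliased columns: {aliased}"
        )


class SurveyGLM(BaseEstimator):
    """Survey-weighted GLM (linear or logit) with Taylor-linearized variance.

    Parameters
    ----------
    family : 'linear' or 'logit' (canonical links).
    single_psu : lone-PSU-stratum policy, 'error' (default) or 'center'.
    alpha : CI level complement; CIs use the normal reference
        ``estimate ± z_{1-alpha/2} SE``.
    use_t : if True, use a t reference with (PSUs − strata) degrees of
        freedom for p-values and CIs instead of the normal.

    Fitted attributes (trailing underscore): ``params_``, ``cov_``, ``bse_``,
    ``pvalues_``, ``names_``, ``n_used_``, ``converged_``, ``result_``
    (a :class:`FitResult`).
    """

    def __init__(
        self,
        family: str = "linear",
        single_psu: str = "error",
        alpha: float = 0.05,
        use_t: bool = False,
        max_iter: int = 200,
    ) -> None:
        self.family = family
        self.single_psu = single_psu
        self.alpha = alpha
        self.use_t = use_t
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------
    def _families(self):
        if self.family == "linear":
            return sm.families.Gaussian()
        if self.family == "logit":
            return sm.families.Binomial()
        raise ValueError("family must be 'linear' or 'logit'")

    def fit(
        self,
        X: pd.DataFrame | np.ndarray,
        y: np.ndarray | pd.Series,
        design: SurveyDesign,
        subpop: np.ndarray | None = None,
    ) -> "SurveyGLM":
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xa.shape[1])]
        ya = np.asarray(y, dtype=float)
        if len(ya) != design.n or len(Xa) != design.n:
            raise ValueError("X/y length must match the full design")

        dom = ~np.isnan(ya) & ~np.isnan(Xa).any(axis=1)
        if subpop is not None:
            dom &= np.asarray(subpop, dtype=bool)
        if design.subpop is not None:
            dom &= design.subpop
        n_used = int(dom.sum())
        if n_used == 0:
            raise ValueError("empty estimation sample")
        Xe, ye, we = Xa[dom], ya[dom], design.weights[dom]
        _check_rank(Xe, names)

        fam = self._families()
        try:
            res = sm.GLM(ye, Xe, family=fam, var_weights=we).fit(maxiter=self.max_iter)
        except Exception as exc:  # statsmodels PerfectSeparation and kin
            if "separat" in str(exc).lower():
                raise SeparationError(str(exc)) from exc
            raise
        params = np.asarray(res.params, dtype=float)
        mu = np.asarray(res.fittedvalues, dtype=float)
        converged = bool(getattr(res, "converged", True))
        if self.family == "logit":
            eta = Xe @ params
            if np.any(np.abs(eta) > 30):
                j = int(np.argmax(np.abs(params[1:] if len(params) > 1 else params)))
                off = names[j + 1] if len(params) > 1 else names[0]
                raise SeparationError(
                    f"fitted linear predictor diverges (|eta|>30); likely separation "
                    f"involving covariate {off!r}"
                )
            v = we * mu * (1 - mu)
        else:
            v = we
        B = Xe.T @ (v[:, None] * Xe)  # observed information (pseudo-likelihood)
        # per-record scores on the FULL design; zero outside estimation sample
        scores = np.zeros((design.n, Xe.shape[1]))
        scores[dom] = (we * (ye - mu))[:, None] * Xe
        M = taylor_variance(scores, design, single_psu=self.single_psu)
        Binv = np.linalg.inv(B)
        cov = Binv @ M @ Binv
        cov = (cov + cov.T) / 2.0

        self.names_ = names
        self.params_ = params
        self.cov_ = cov
        self.bse_ = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.n_used_ = n_used
        self.converged_ = converged
        self.design_df_ = self._design_df(design)
        self.result_ = FitResult(names, params, cov, self.family, n_used, converged, self.alpha)
        if self.use_t:
            self.result_ = self._t_result(self.result_)
        self.pvalues_ = self.result_.pvalues
        self._dom_ = dom
        self._mu_ = mu
        self._X_ = Xe
        self._w_ = we
        self._B_ = B
        self._scores_full_ = scores
        return self

    @staticmethod
    def _design_df(design: SurveyDesign) -> int:
        key = pd.MultiIndex.from_arrays([design.strata, design.psu])
        n_psu = len(key.unique())
        n_strata = len(pd.unique(design.strata))
        return n_psu - n_strata

    def _t_result(self, r: FitResult) -> FitResult:
        # patch pvalues/CIs to a t reference by scaling via class below
        class _TResult(FitResult):
            df: int = self.design_df_

            @property
            def pvalues(self):  # type: ignore[override]
                return 2.0 * stats.t.sf(np.abs(self.zvalues), self.df)

            def conf_int(self):  # type: ignore[override]
                tq = stats.t.ppf(1 - self.alpha / 2, self.df)
                se = self.bse
                return np.column_stack([self.params - tq * se, self.params + tq * se])

        return _TResult(r.names, r.params, r.cov, r.family, r.n_used, r.converged, r.alpha)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        eta = Xa @ self.params_
        if self.family == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def fit_weighted_glm(
    design: SurveyDesign,
    df: pd.DataFrame,
    response: str,
    covariates: list[str],
    family: str = "linear",
    subpop: np.ndarray | None = None,
    single_psu: str = "error",
    alpha: float = 0.05,
) -> FitResult:
    """Fit ``response ~ covariates`` as a survey-weighted GLM on ``df``.

    Covariate names are expanded via :func:`build_design_matrix` (categoricals
    become treatment-coded indicators). Rows with any missing operand are
    excluded from estimation (complete case per model) but retained in the
    variance computation.
    """
    X, names = build_design_matrix(df, covariates)
    y = pd.to_numeric(df[response]).to_numpy(dtype=float)
    est = SurveyGLM(family=family, single_psu=single_psu, alpha=alpha)
    est.fit(pd.DataFrame(X, columns=names), y, design, subpop=subpop)
    return est.result_


@dataclass
class AdjustedMeans:
    """Model-adjusted outcome means per genotype class (dis-joint coding)."""

    means: dict[int, float]
    ses: dict[int, float]
    joint_chi2: float
    joint_df: int
    joint_p: float
    n_used: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype_class": sorted(self.means),
                "adjusted_mean": [self.means[g] for g in sorted(self.means)],
                "se": [self.ses[g] for g in sorted(self.means)],
            }
        )


def adjusted_genotype_means(
    design: SurveyDesign,
    df: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    genotype: str = "dosage",
    subpop: np.ndarray | None = None,
    single_psu: str = "error",
) -> AdjustedMeans:
    """Adjusted outcome means per genotype class with a joint Wald test.

    Genotype enters dis-jointly as two indicator contrasts (heterozygote and
    risk-homozygote vs reference homozygote); means are evaluated at the
    weighted covariate means of the estimation sample; the joint 2-df Wald
    statistic tests any genotype effect.
    """
    g = pd.to_numeric(df[genotype]).to_numpy(dtype=float)
    classes = [0, 1, 2]
    present = [c for c in classes if np.nansum(g == c) > 0]
    if len(present) < len(classes):
        missing = sorted(set(classes) - set(present))
        raise ValueError(f"empty genotype class(es): {missing}")
    Xc, names = build_design_matrix(df, covariates)
    ind = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
    ind[np.isnan(g)] = np.nan
    X = np.column_stack([np.ones(len(df)), ind, Xc[:, 1:]])  # const, g1, g2, covars
    names = ["const", "g1", "g2"] + names[1:]
    y = pd.to_numeric(df[outcome]).to_numpy(dtype=float)
    est = SurveyGLM(family="linear", single_psu=single_psu)
    est.fit(pd.DataFrame(X, columns=names), y, design, subpop=subpop)

    dom = est._dom_
    w = design.weights[dom]
    xbar = np.average(X[dom][:, 3:], axis=0, weights=w) if X.shape[1] > 3 else np.empty(0)
    means, ses = {}, {}
    for cls, (i1, i2) in zip(classes, [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)]):
        a = np.concatenate([[1.0, i1, i2], xbar])
        means[cls] = float(a @ est.params_)
        ses[cls] = float(np.sqrt(a @ est.cov_ @ a))
    c = est.params_[1:3]
    Vc = est.cov_[1:3, 1:3]
    chi2 = float(c @ np.linalg.solve(Vc, c))
    p = float(stats.chi2.sf(chi2, 2))
    return AdjustedMeans(means, ses, chi2, 2, p, est.n_used_)
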