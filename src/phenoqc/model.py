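"""Lagged random-intercept mixed models linking data quality to symptoms.

For subject ``i`` and week ``j`` the weekly mean symptom score in a
domain is modelled as

    Y_ij = b0 + mu_i + b1*A_{i,j-l} + b2*G_{i,j-l} + b3*V_{i,j-l}
                + b4*C_{i,j-l} + b5*T_{i,j-l} + e_ij,

with a Gaussian subject random intercept ``mu_i ~ N(0, sigma_mu^2)``
and residual ``e_ij ~ N(0, sigma_e^2)``.  Estimation is by restricted
maximum likelihood with Wald z-tests on the fixed effects.  Fits over a
domain-by-lag grid are corrected for multiple testing with the
Benjamini–Hochberg–Yekutieli (BY) step-up procedure, which controls the
false discovery rate under arbitrary dependence via the harmonic-sum
factor ``c(m) = sum_{k<=m} 1/k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import EstimationError
from .weekly import COVARIATES, lag_table

__all__ = [
    "SymptomLagModel",
    "SymptomLagResults",
    "fit_grid",
    "bhy_adjust",
    "SignificanceGrid",
    "significance_grid",
    "grid_from_frame",
]


class SymptomLagModel:
    """Random-intercept model of a weekly symptom score on lagged data quality.

    Parameters
    ----------
    table : DataFrame
        One row per subject-week with the outcome, the (already lagged)
        covariates, and a subject identifier column.  Build it with
        :func:`phenoqc.weekly.lag_table` or use :meth:`from_weekly`.
    outcome, covariates, groups : str / sequence of str / str
        Column names.
    standardize : bool
        If true, z-score the covariates within the analysis set before
        fitting (off by default).
    domain, lag : metadata carried through to the results.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        outcome: str = "Y",
        covariates: Sequence[str] = COVARIATES,
        groups: str = "subject_id",
        standardize: bool = False,
        domain: str | None = None,
        lag: int | None = None,
    ) -> None:
        data = table.dropna(subset=[outcome, *covariates]).reset_index(drop=True)
        n_subjects = data[groups].nunique()
        if n_subjects < 2:
            raise EstimationError(
                f"need >= 2 subjects to separate the random intercept, got {n_subjects}"
            )
        if len(data) <= len(covariates) + 1:
            raise EstimationError(
                f"{len(data)} rows cannot identify {len(covariates) + 1} fixed effects"
            )
        self.dropped_terms: list[str] = [
            c for c in covariates if np.isclose(data[c].std(ddof=0), 0.0)
        ]
        if self.dropped_terms:
            warnings.warn(
                f"constant covariate(s) dropped from the design: {self.dropped_terms}",
                stacklevel=2,
            )
        self.covariates = [c for c in covariates if c not in self.dropped_terms]
        self.outcome = outcome
        self.groups_col = groups
        self.standardize = standardize
        self.domain = domain if domain is not None else table.attrs.get("outcome_domain")
        self.lag = lag if lag is not None else table.attrs.get("lag")
        self.n_dropped = table.attrs.get("n_dropped", 0)

        exog = data[self.covariates].astype(float)
        if standardize:
            exog = (exog - exog.mean()) / exog.std(ddof=0)
        self.exog = sm.add_constant(exog, prepend=True).rename(columns={"const": "Intercept"})
        self.endog = data[outcome].astype(float)
        self.groups = data[groups]
        self.data = data

    @classmethod
    def from_weekly(
        cls,
        weekly: pd.DataFrame,
        domain: str,
        lag: int,
        covariates: Sequence[str] = COVARIATES,
        **kwargs,
    ) -> "SymptomLagModel":
        """Build the model from a subject-week feature table at a given lag."""
        table = lag_table(weekly, lag, domain, tuple(covariates))
        return cls(table, covariates=covariates, domain=domain, lag=lag, **kwargs)

    def fit(self, reml: bool = True, maxiter: int = 200, tol: float = 1e-8) -> "SymptomLagResults":
        """Fit by (restricted) maximum likelihood and return the results.

        Covariates are rescaled to unit variance internally for
        numerical conditioning (latencies are in seconds, coverages in
        [0, 1]); the reparameterization is exact and estimates, standard
        errors and intervals are reported on the original scale.  A
        sequence of optimizers is tried until one converges.
        """
        scales = self.exog.std(ddof=0).replace(0.0, 1.0)
        scales["Intercept"] = 1.0
        exog_scaled = self.exog / scales
        mlm = sm.MixedLM(self.endog, exog_scaled, groups=self.groups)
        res, last_exc = None, None
        with warnings.catch_warnings():
            # boundary variance estimates are expected and handled explicitly
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    candidate = mlm.fit(reml=reml, method=method, maxiter=maxiter, gtol=tol)
                except np.linalg.LinAlgError as exc:  # ill-conditioned step
                    last_exc = exc
                    continue
                res = candidate
                if res.converged:
                    break
        if res is None:
            raise EstimationError(f"mixed-model estimation failed: {last_exc}")
        return SymptomLagResults(self, res, scales)


class SymptomLagResults:
    """Estimates, uncertainties and diagnostics for one fitted model."""

    def __init__(self, model: SymptomLagModel, mixedlm_results, scales=None) -> None:
        self.model = model
        self._res = mixedlm_results
        names = list(model.exog.columns)
        self.fe_names = names
        if scales is None:
            scales = pd.Series(1.0, index=names)
        self._scales = scales[names]
        self.params = mixedlm_results.params[names] / self._scales
        self.bse = mixedlm_results.bse[names] / self._scales
        self.pvalues = mixedlm_results.pvalues[names]
        self.tvalues = mixedlm_results.tvalues[names]
        #: Subject random-intercept variance sigma_mu^2.
        self.sigma2_subject = float(np.asarray(mixedlm_results.cov_re)[0, 0])
        #: Residual variance sigma_e^2.
        self.sigma2_resid = float(mixedlm_results.scale)
        self.n_obs = int(mixedlm_results.nobs)
        self.n_subjects = int(model.groups.nunique())
        self.converged = bool(mixedlm_results.converged)
        self.domain = model.domain
        self.lag = model.lag

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald confidence intervals for the fixed effects (original scale)."""
        ci = self._res.conf_int(alpha=alpha).loc[self.fe_names]
        return ci.div(self._scales, axis=0)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, Wald z, p-value, 95% CI.

        Variance components and fit metadata are attached in
        ``DataFrame.attrs``.
        """
        ci = self.conf_int()
        table = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.tvalues,
                "pvalue": self.pvalues,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
        table.attrs.update(
            {
                "domain": self.domain,
                "lag": self.lag,
                "sigma2_subject": self.sigma2_subject,
                "sigma2_resid": self.sigma2_resid,
                "n_rows": self.n_obs,
                "n_subjects": self.n_subjects,
                "estimator": "REML",
                "test": "Wald z",
                "converged": self.converged,
            }
        )
        return table

    def to_frame(self) -> pd.DataFrame:
        """One row per fixed effect (dropped covariates included as NaN)."""
        ci = self.conf_int()
        rows = []
        for name in self.fe_names:
            rows.append(
                {
                    "term": name,
                    "estimate": self.params[name],
                    "se": self.bse[name],
                    "pvalue": self.pvalues[name],
                    "ci_low": ci.loc[name, 0],
                    "ci_high": ci.loc[name, 1],
                }
            )
        for name in self.model.dropped_terms:
            rows.append(
                {"term": name, "estimate": np.nan, "se": np.nan, "pvalue": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan}
            )
        df = pd.DataFrame(rows)
        df["domain"] = self.domain
        df["lag"] = self.lag
        df["sigma2_subject"] = self.sigma2_subject
        df["sigma2_resid"] = self.sigma2_resid
        df["n_rows"] = self.n_obs
        df["n_subjects"] = self.n_subjects
        return df


def fit_grid(
    weekly: pd.DataFrame,
    domains: Sequence[str],
    lags: Sequence[int],
    covariates: Sequence[str] = COVARIATES,
    **kwargs,
) -> list[SymptomLagResults]:
    """Fit one model per domain-by-lag cell of the analysis grid."""
    fits = []
    for domain in domains:
        for lag in lags:
            model = SymptomLagModel.from_weekly(weekly, domain, lag, covariates, **kwargs)
            fits.append(model.fit())
    return fits


def bhy_adjust(pvals: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg–Yekutieli step-up rejection flags at FDR level ``q``.

    Rejects the ``i*`` smallest p-values, where ``i*`` is the largest
    ``i`` with ``p_(i) <= i*q / (m*c(m))`` and ``c(m)`` is the harmonic
    sum; flags are returned in input order.  Controls the FDR at ``q``
    under arbitrary dependence between the tests.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"FDR level must be in (0, 1), got {q}")
    reject, *_ = multipletests(p, alpha=q, method="fdr_by")
    return reject


@dataclass
class SignificanceGrid:
    """Signed-significance grid over covariate x domain x lag cells.

    ``frame`` has one row per cell with the signed -log10 p-value, the
    unadjusted p < 0.05 flag, and the BY-adjusted flag at FDR ``q``.
    """

    frame: pd.DataFrame
    q: float
    family: str

    def pivot(self, value: str = "signed_neglog10p") -> pd.DataFrame:
        """Wide layout: rows (covariate, domain), columns lag."""
        return self.frame.pivot(index=["covariate", "domain"], columns="lag", values=value)

    def plot(self, **kwargs):
        from .plotting import plot_significance_grid

        return plot_significance_grid(self, **kwargs)


def grid_from_frame(
    frame: pd.DataFrame,
    q: float = 0.05,
    family: str = "global",
    raw_alpha: float = 0.05,
) -> SignificanceGrid:
    """Build the significance grid from a per-cell results table.

    ``frame`` needs columns ``covariate, domain, lag, estimate,
    pvalue`` (NaN p-values, e.g. dropped covariates, are excluded from
    the multiple-testing family).
    """
    if family not in ("global", "per-lag"):
        raise ValueError(f"family must be 'global' or 'per-lag', got {family!r}")
    frame = frame.reset_index(drop=True).copy()
    # Wald p-values can underflow to exactly 0 for extreme z; keep them
    # representable so -log10 p and the step-up correction stay defined
    frame["pvalue"] = frame["pvalue"].clip(lower=np.finfo(float).tiny)
    frame["neglog10p"] = -np.log10(frame["pvalue"])
    frame["sign"] = np.sign(frame["estimate"]).fillna(0).astype(int)
    frame["signed_neglog10p"] = frame["sign"] * frame["neglog10p"]
    frame["significant_raw"] = frame["pvalue"] < raw_alpha
    frame["significant_fdr"] = False
    if family == "global":
        groups = [frame.index[frame["pvalue"].notna()]]
    else:
        valid = frame[frame["pvalue"].notna()]
        groups = [idx for _, idx in valid.groupby("lag").groups.items()]
    for idx in groups:
        if len(idx):
            frame.loc[idx, "significant_fdr"] = bhy_adjust(frame.loc[idx, "pvalue"], q)
    return SignificanceGrid(frame=frame, q=q, family=family)


def significance_grid(
    fits: Sequence[SymptomLagResults],
    q: float = 0.05,
    family: str = "global",
    raw_alpha: float = 0.05,
) -> SignificanceGrid:
    """Assemble fitted models into the signed-significance grid.

    ``family`` chooses the multiple-testing family for the BY
    correction: ``"global"`` corrects jointly across every cell of the
    grid, ``"per-lag"`` corrects within each lag separately.
    """
    rows = []
    for res in fits:
        for name in res.fe_names:
            if name == "Intercept":
                continue
            rows.append(
                {
                    "covariate": name,
                    "domain": res.domain,
                    "lag": res.lag,
                    "estimate": res.params[name],
                    "se": res.bse[name],
                    "pvalue": res.pvalues[name],
                    "n_rows": res.n_obs,
                    "n_subjects": res.n_subjects,
                }
            )
        for name in res.model.dropped_terms:
            rows.append(
                {"covariate": name, "domain": res.domain, "lag": res.lag,
                 "estimate": np.nan, "se": np.nan, "pvalue": np.nan,
                 "n_rows": res.n_obs, "n_subjects": res.n_subjects}
            )
    return grid_from_frame(pd.DataFrame(rows), q=q, family=family, raw_alpha=raw_alpha)
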