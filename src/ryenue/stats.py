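"""Trial-level statistics.

* per-group summary statistics (n, mean, SD, range, CV) in the shape of a
  trial summary table;
* pairwise-complete Pearson correlation matrices with two-sided p-values
  and significance stars (feature-biomass correlation analysis);
* best linear unbiased estimates (BLUEs) of every genotype x treatment cell
  from a linear mixed model — genotype, N treatment and their interaction
  fixed, replicate random — fitted by REML, with Wald tests of the three
  fixed terms; on a balanced complete design the cell BLUEs coincide with
  the arithmetic cell means, which serves as an exact oracle in the tests;
* parameter-recovery reports comparing estimated genotype effects with the
  synthetic generator's true multipliers.

The REML machinery is delegated to ``statsmodels`` MixedLM; this module
owns the design construction, the cell parameterisation and the contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConvergenceError, InvalidArgumentError

log = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summarize(
    df: pd.DataFrame, value: str, group_cols: list[str]
) -> pd.DataFrame:
    """Per-group n, mean, SD (n-1 denominator), min, max and CV = SD/mean.

    Groups where the mean is zero get a flagged (NaN) CV; empty groups are
    skipped with a log message.
    """
    rows = []
    for keys, grp in df.groupby(group_cols, sort=True, dropna=False):
        vals = grp[value].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            log.warning("empty group %s for %s; skipped", keys, value)
            continue
        keys = keys if isinstance(keys, tuple) else (keys,)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        row = dict(zip(group_cols, keys))
        row.update(
            n=vals.size,
            mean=mean,
            sd=sd,
            min=float(vals.min()),
            max=float(vals.max()),
            cv=sd / mean if mean != 0 else np.nan,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        return self.p.map(lambda p: significance_stars(p) if np.isfinite(p) else "")


def correlate(df: pd.DataFrame, variables: list[str], min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Cells with fewer than ``min_pairs`` complete observations are flagged
    missing (NaN r and p).  The matrix is symmetric with a unit diagonal.
    """
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.empty((k, k), dtype=int)
    for i, vi in enumerate(variables):
        n[i, i] = df[vi].notna().sum()
    for i in range(k):
        for j in range(i + 1, k):
            sub = df[[variables[i], variables[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < min_pairs:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = sps.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(variables)
    return CorrelationMatrix(
        variables=list(variables),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# mixed-model BLUEs
# ---------------------------------------------------------------------------

@dataclass
class BLUEResult:
    """Cell estimates and fixed-term Wald tests for one response/phase."""

    cells: pd.DataFrame       # genotype, treatment, estimate, se
    tests: pd.DataFrame       # term, df, statistic, pvalue
    method: str               # "reml" or "ols-fallback"
    response: str


_FORMULA = "C(genotype, Sum) * C(treatment, Sum)"
_TERM_NAMES = {
    "C(genotype, Sum)": "genotype",
    "C(treatment, Sum)": "treatment",
    "C(genotype, Sum):C(treatment, Sum)": "genotype:treatment",
}


def _gls_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, tau2: float, sigma2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form GLS for a model with one random intercept per group.

    V_g = sigma2 * I + tau2 * J within each group, so V_g^-1 has the
    Sherman-Morrison form and X' V^-1 X accumulates group by group.
    Returns (beta, cov_beta).
    """
    XtViX = np.zeros((X.shape[1], X.shape[1]))
    XtViy = np.zeros(X.shape[1])
    for g in np.unique(groups):
        idx = groups == g
        Xg = X[idx]
        yg = y[idx]
        n = Xg.shape[0]
        f = tau2 / (sigma2 + n * tau2)
        ViX = (Xg - f * Xg.sum(axis=0)) / sigma2
        Viy = (yg - f * yg.sum()) / sigma2
        XtViX += Xg.T @ ViX
        XtViy += Xg.T @ Viy
    try:
        cov = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular GLS system: {exc}") from exc
    return cov @ XtViy, cov


def _reml_variances(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """REML estimates (tau2, sigma2) of the replicate and residual variances."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        # the replicate variance may legitimately shrink to the REML
        # boundary (zero); that is a valid fit, not a failure
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"mixed-model fit is singular: {exc}") from exc
    tau2 = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = float(res.scale)
    if not (np.isfinite(tau2) and np.isfinite(sigma2)) or sigma2 < 0 or tau2 < 0:
        raise ConvergenceError("REML produced invalid variance estimates")
    return tau2, sigma2


def fit_blues(df: pd.DataFrame, response: str) -> BLUEResult:
    """Genotype x treatment BLUEs under the trial's mixed model.

    The sum-to-zero factorial parameterisation (genotype, treatment and
    interaction fixed; replicate random intercept) is fitted by REML; the
    fixed effects and their covariance are then the closed-form GLS
    solution at the REML variance components, which stays exact even when
    the replicate variance estimate sits on the zero boundary.  The fit
    yields Wald tests of the three fixed terms (numerator df G-1, T-1,
    (G-1)(T-1)) and — by evaluating the fitted surface at each cell — the
    genotype x treatment BLUEs with standard errors.  On a balanced
    complete design these BLUEs equal the arithmetic cell means.  With
    fewer than two replicates the block effect is unidentifiable, and with
    an exactly noise-free response there is no variance to estimate; both
    cases fall back to ordinary least squares (logged).
    """
    from patsy import dmatrix

    required = {"genotype", "treatment", "replicate", response}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"trait table must contain {sorted(required)}")
    data = df.dropna(subset=[response]).copy()
    if data.empty:
        raise InvalidArgumentError(f"no observations for response {response!r}")

    y = data[response].to_numpy(dtype=float)
    design = dmatrix(_FORMULA, data, return_type="dataframe")
    X = np.asarray(design)
    groups = data["replicate"].to_numpy()
    n_reps = data["replicate"].nunique()

    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    dof = max(len(y) - np.linalg.matrix_rank(X), 1)
    sigma2_ols = float(resid @ resid) / dof
    noise_free = sigma2_ols <= 1e-12 * max(1.0, float(np.var(y)))

    if n_reps >= 2 and not noise_free:
        method = "reml"
        tau2, sigma2 = _reml_variances(y, X, groups)
        beta, cov = _gls_random_intercept(y, X, groups, tau2, sigma2)
    else:
        method = "ols-fallback"
        if n_reps < 2:
            log.warning(
                "replicate effect unidentifiable with %d replicate(s); "
                "falling back to fixed-effects least squares",
                n_reps,
            )
        else:
            log.info("response is noise-free; using exact least squares")
        beta = beta_ols
        cov = sigma2_ols * np.linalg.pinv(X.T @ X)

    cells = (
        data[["genotype", "treatment"]]
        .drop_duplicates()
        .sort_values(["genotype", "treatment"])
        .reset_index(drop=True)
    )
    X_cell = np.asarray(dmatrix(design.design_info, cells))
    cells = cells.assign(
        estimate=X_cell @ beta,
        se=np.sqrt(np.einsum("ij,jk,ik->i", X_cell, cov, X_cell)),
    )

    test_rows = []
    for term, name in _TERM_NAMES.items():
        sl = design.design_info.term_name_slices[term]
        b = beta[sl]
        V = cov[sl, sl]
        df_num = len(b)
        try:
            stat = float(b @ np.linalg.solve(V, b))
            pval = float(sps.chi2.sf(stat, df_num))
        except np.linalg.LinAlgError:
            # degenerate covariance (e.g. noise-free response): the Wald
            # statistic is undefined, the estimates remain valid
            log.warning("singular covariance for term %s; no Wald test", name)
            stat, pval = float("nan"), float("nan")
        test_rows.append(
            {"term": name, "df": df_num, "statistic": stat, "pvalue": pval}
        )

    return BLUEResult(
        cells=cells,
        tests=pd.DataFrame(test_rows),
        method=method,
        response=response,
    )


def fit_blues_by_phase(df: pd.DataFrame, response: str) -> dict[str, BLUEResult]:
    """BLUEs per experimental phase (each phase analysed separately)."""
    return {
        phase: fit_blues(grp, response)
        for phase, grp in df.groupby("phase", sort=True)
        if grp[response].notna().any()
    }


# ---------------------------------------------------------------------------
# parameter recovery against synthetic ground truth
# ---------------------------------------------------------------------------

def recover_parameters(
    cells: pd.DataFrame,
    genotype_multipliers: np.ndarray,
    interaction_multipliers: np.ndarray | None = None,
    treatments: list[float] | None = None,
    top_fraction: float = 0.1,
) -> dict:
    """Compare estimated genotype effects with the generator's truth.

    For each treatment, correlates the estimated cell BLUEs across
    genotypes with the true per-treatment genotype effect — the genotype
    multiplier times, when supplied, that treatment's interaction
    multiplier — reporting Pearson and Spearman correlations and the
    overlap of the top decile of genotypes under truth vs estimate.  In
    the noise-free limit the Spearman correlation is exactly 1.
    """
    truth = np.asarray(genotype_multipliers, dtype=float)
    inter = (
        np.asarray(interaction_multipliers, dtype=float)
        if interaction_multipliers is not None
        else None
    )
    report: dict = {"per_treatment": {}}
    n_top = max(int(round(top_fraction * len(truth))), 1)
    for trt, grp in cells.groupby("treatment", sort=True):
        grp = grp.sort_values("genotype")
        geno = grp["genotype"].to_numpy(dtype=int)
        est = grp["estimate"].to_numpy(dtype=float)
        true_vals = truth[geno - 1]
        if inter is not None:
            t_idx = treatments.index(trt) if treatments is not None else 0
            true_vals = true_vals * inter[geno - 1, t_idx]
        if np.allclose(true_vals, true_vals[0]) or np.allclose(est, est[0]):
            pearson = spearman = np.nan
        else:
            pearson = float(sps.pearsonr(true_vals, est).statistic)
            spearman = float(sps.spearmanr(true_vals, est).statistic)
        top_true = set(geno[np.argsort(true_vals)[-n_top:]])
        top_est = set(geno[np.argsort(est)[-n_top:]])
        report["per_treatment"][str(trt)] = {
            "pearson": pearson,
            "spearman": spearman,
            "top_decile_overlap": len(top_true & top_est) / n_top,
            "n_genotypes": int(len(geno)),
        }
    report["n_top"] = n_top
    return report
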