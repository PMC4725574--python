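"""Genotype-phenotype association: OLS of clinical phenotypes on per-sample
CNV burden, spectral-decomposition multiple-testing correction, and the
study-design power calculations.

The multiple-testing layer computes the effective number of independent
tests among correlated phenotypes from the eigenvalue spectrum of their
correlation matrix, by two conventions:

* Nyholt:  v_eff = 1 + (M-1) * (1 - Var(lambda)/M)   (Var with ddof=1)
* Li & Ji: v_eff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]

and derives corrected per-test alpha levels (Bonferroni alpha/v_eff and the
Sidak variant 1-(1-alpha)^(1/v_eff)).

Power calculations cover the two designs used in array CNV studies: the
1-numerator-df F test of a linear burden-phenotype model at effect size
f2 (noncentral F with ncp = f2 * n), and the comparison of two carrier
proportions (normal approximation or exact simulation through the Fisher
test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .burden_stats import ContingencyTable, fisher_exact
from .io_formats import PHENOTYPES


@dataclass(frozen=True)
class RegressionResult:
    phenotype: str
    cnv_class: str
    beta: float
    se: float
    t: float
    p: float
    n: int


def regress_burden(
    phenotype_values: Sequence[float] | pd.Series,
    burden: Sequence[float] | pd.Series,
    covariates: pd.DataFrame | None = None,
    phenotype: str = "",
    cnv_class: str = "",
    min_cases: int = 10,
) -> RegressionResult:
    """OLS of a phenotype on per-sample CNV burden (plus optional covariates).

    Rows with any missing value are dropped listwise; the complete-case n is
    reported. The t statistic and p-value are the burden coefficient's.
    """
    y = np.asarray(phenotype_values, dtype=float)
    x = np.asarray(burden, dtype=float)
    if len(y) != len(x):
        raise ValueError("phenotype and burden vectors differ in length")
    X = pd.DataFrame({"burden": x})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    complete = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[complete], X.loc[complete]
    if len(y) < min_cases:
        raise ValueError(f"only {len(y)} complete cases; need >= {min_cases}")
    if np.ptp(X["burden"].to_numpy()) == 0:
        raise ValueError("no variance in predictor")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        phenotype=phenotype, cnv_class=cnv_class,
        beta=float(model.params["burden"]), se=float(model.bse["burden"]),
        t=float(model.tvalues["burden"]), p=float(model.pvalues["burden"]),
        n=int(len(y)),
    )


def run_phenotype_grid(
    phenotypes: pd.DataFrame,
    stats_by_class: Mapping[str, pd.DataFrame],
    statistic: str = "count",
) -> pd.DataFrame:
    """The phenotype x CNV-class association grid (5 phenotypes x 3 classes).

    ``phenotypes`` is indexed by sample_id with the five phenotype columns;
    ``stats_by_class`` maps cnv_class -> per-sample burden statistics. Each
    cell regresses the phenotype on the chosen burden statistic over the
    samples present in both tables.
    """
    rows = []
    for pheno in PHENOTYPES:
        for klass, burden_df in stats_by_class.items():
            common = phenotypes.index.intersection(burden_df.index)
            try:
                res = regress_burden(
                    phenotypes.loc[common, pheno],
                    burden_df.loc[common, statistic],
                    phenotype=pheno, cnv_class=klass,
                )
                rows.append(res.__dict__)
            except ValueError as e:
                rows.append(
                    dict(phenotype=pheno, cnv_class=klass, beta=math.nan,
                         se=math.nan, t=math.nan, p=math.nan, n=0)
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# effective number of tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatSpDResult:
    eigenvalues: tuple[float, ...]
    v_eff_nyholt: float
    v_eff_liji: float
    alpha: float
    alpha_corrected: float       # alpha / v_eff (Nyholt, default downstream)
    alpha_sidak: float           # 1 - (1-alpha)^(1/v_eff) (Nyholt)
    alpha_corrected_liji: float


def matspd(correlation_matrix: np.ndarray | pd.DataFrame,
           alpha: float = 0.05) -> MatSpDResult:
    """Effective number of independent tests from the eigenvalue spectrum.

    Requires a symmetric positive semi-definite matrix with unit diagonal
    (within 1e-8). Eigenvalues sum to the trace M; v_eff lies in [1, M] and
    equals M exactly when the traits are uncorrelated.
    """
    R = np.asarray(correlation_matrix, dtype=float)
    M = R.shape[0]
    if R.shape != (M, M) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(R)[::-1]
    if lam[-1] < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    var = float(np.var(lam, ddof=1)) if M > 1 else 0.0
    v_nyholt = 1.0 + (M - 1) * (1.0 - var / M)
    v_liji = float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    return MatSpDResult(
        eigenvalues=tuple(float(x) for x in lam),
        v_eff_nyholt=v_nyholt,
        v_eff_liji=v_liji,
        alpha=alpha,
        alpha_corrected=alpha / v_nyholt,
        alpha_sidak=1.0 - (1.0 - alpha) ** (1.0 / v_nyholt),
        alpha_corrected_liji=alpha / v_liji,
    )


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def power_linear(f2: float, n: int, alpha: float = 0.05) -> float:
    """Power of the 1-numerator-df F test of a linear association.

    P(F'(1, n-2; ncp = f2*n) > F_{1-alpha}(1, n-2)) — the standard fixed-n
    power of detecting a regression effect of size f2 = R2/(1-R2).
    """
    if f2 <= 0:
        raise ValueError("f2 must be > 0")
    if n <= 2:
        raise ValueError("n must be > 2")
    crit = stats.f.ppf(1.0 - alpha, 1, n - 2)
    return float(stats.ncf.sf(crit, 1, n - 2, f2 * n))


@dataclass(frozen=True)
class ProportionPower:
    power: float
    mc_se: float | None = None
    warning: str = ""


def power_two_proportion(
    p_case: float,
    p_control: float,
    n_case: int,
    n_control: int,
    alpha: float = 0.05,
    method: str = "normal_approx",
    n_sim: int = 2_000,
    seed: int = 0,
) -> ProportionPower:
    """Power to detect a difference in two carrier proportions.

    ``normal_approx`` uses the two-proportion z formula (two-sided);
    ``exact_sim`` simulates binomial cohorts and counts two-sided Fisher
    rejections, returning a Monte-Carlo standard error.
    """
    if not (0 < p_case < 1 and 0 < p_control < 1):
        raise ValueError("rates must be in (0, 1)")
    warning = ""
    if p_case * n_case < 1 and p_control * n_control < 1:
        warning = "expected carrier count < 1 in both arms; unreliable"
    if method == "normal_approx":
        pbar = (p_case * n_case + p_control * n_control) / (n_case + n_control)
        se0 = math.sqrt(pbar * (1 - pbar) * (1 / n_case + 1 / n_control))
        se1 = math.sqrt(
            p_case * (1 - p_case) / n_case + p_control * (1 - p_control) / n_control
        )
        z_a = stats.norm.ppf(1 - alpha / 2)
        delta = abs(p_case - p_control)
        power = float(
            stats.norm.sf((z_a * se0 - delta) / se1)
            + stats.norm.cdf((-z_a * se0 - delta) / se1)
        )
        return ProportionPower(power=power, warning=warning)
    if method == "exact_sim":
        rng = np.random.default_rng(seed)
        a = rng.binomial(n_case, p_case, size=n_sim)
        c = rng.binomial(n_control, p_control, size=n_sim)
        reject = np.fromiter(
            (
                fisher_exact(
                    ContingencyTable(int(ai), n_case - int(ai),
                                     int(ci), n_control - int(ci))
                ).p_two <= alpha
                for ai, ci in zip(a, c)
            ),
            dtype=bool, count=n_sim,
        )
        power = float(np.mean(reject))
        mc_se = float(math.sqrt(power * (1 - power) / n_sim))
        return ProportionPower(power=power, mc_se=mc_se, warning=warning)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# synthetic phenotypes with a planted burden effect
# ---------------------------------------------------------------------------

# moderate positive correlation between neuroticism/psychoticism and weak
# links elsewhere: a plausible questionnaire-trait structure
DEFAULT_TRAIT_CORR = np.array(
    [
        [1.00, 0.10, 0.15, -0.05, 0.05],
        [0.10, 1.00, 0.20, -0.10, 0.10],
        [0.15, 0.20, 1.00, -0.30, 0.40],
        [-0.05, -0.10, -0.30, 1.00, -0.15],
        [0.05, 0.10, 0.40, -0.15, 1.00],
    ]
)  # order: age_of_onset, duration, neuroticism, extraversion, psychoticism


def simulate_phenotypes(
    burden: pd.Series,
    f2: float = 0.0,
    target: str = "age_of_onset",
    trait_corr: np.ndarray = DEFAULT_TRAIT_CORR,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlated phenotype table with a linear burden effect planted on one
    trait at effect size f2 (f2 = 0 gives the null).

    Burden is standardized internally; the planted slope on the standardized
    scale is sqrt(f2), giving the requested f2 against unit residual noise.
    """
    rng = np.random.default_rng(seed)
    n = len(burden)
    L = np.linalg.cholesky(trait_corr)
    traits = rng.standard_normal((n, len(PHENOTYPES))) @ L.T
    df = pd.DataFrame(traits, columns=PHENOTYPES, index=burden.index)
    if f2 > 0:
        b = burden.to_numpy(dtype=float)
        sd = b.std()
        if sd > 0:
            df[target] = df[target] + math.sqrt(f2) * (b - b.mean()) / sd
    if missing_rate > 0:
        mask = rng.uniform(size=df.shape) < missing_rate
        df = df.mask(mask)
    df.index.name = "sample_id"
    return df
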