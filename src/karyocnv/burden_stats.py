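"""Case-control statistics: exact 2x2 tests with odds ratios, per-sample CNV
burden statistics, and label-permutation burden testing with Bonferroni
control over the 63-test grid (3 cohort contrasts x 3 CNV classes x 7
burden statistics).

``fisher_exact`` follows the standard exact-distribution conventions: the
two-sided p sums the hypergeometric probabilities of every table (margins
fixed) no more probable than the observed one; the sample odds ratio is the
cross-product (a*d)/(b*c); the conditional-MLE odds ratio maximizes the
noncentral hypergeometric likelihood, with its exact tail-inversion 95% CI
(upper bound +inf when a margin is saturated).

Permutation burden p-values use the add-one empirical estimator
p = (1 + #{perm >= observed}) / (n_perm + 1), one-sided with cases
exceeding controls as the default alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cnv_consensus import ConsensusCnv

CNV_CLASSES = ("all", "deletions", "duplications")
BURDEN_STATISTICS = (
    "carrier",            # >= 1 CNV
    "count",              # number of CNVs
    "total_kb",           # summed length
    "mean_length_kb",     # per-CNV mean length (NaN when no CNVs)
    "genes_total",        # genes covered, summed over CNVs
    "mean_genes_per_cnv", # per-CNV mean gene count (NaN when no CNVs)
    "genic_count",        # CNVs overlapping >= 1 gene
)
CONTRASTS = ("cases_vs_all_controls", "cases_vs_screened", "cases_vs_wtccc2")


# ---------------------------------------------------------------------------
# exact 2x2 tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier/non-carrier x case/control counts:

    a = case carriers, b = case non-carriers,
    c = control carriers, d = control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    p_one: float
    p_two: float
    or_sample: float
    or_cmle: float
    ci95: tuple[float, float]


def odds_ratio_sample(t: ContingencyTable) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    +inf when b*c = 0 with a*d > 0; NaN (undefined) when both cross
    products vanish.
    """
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        return math.nan if ad == 0 else math.inf
    return ad / bc


def exact_pvalues(
    a: int, n: int, r1: int, c1: int, alternative: str = "greater"
) -> tuple[float, float]:
    """(one-sided, two-sided) exact p for cell ``a`` given fixed margins.

    The two-sided p sums the probabilities of all admissible tables no more
    probable than the observed one (minimum-likelihood mass convention,
    with a relative tolerance against floating-point ties).
    """
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p_two = float(min(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum(), 1.0))
    if alternative == "greater":
        p_one = float(min(pmf[support >= a].sum(), 1.0))
    elif alternative == "less":
        p_one = float(min(pmf[support <= a].sum(), 1.0))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return p_one, p_two


def fisher_exact(
    t: ContingencyTable, alternative: str = "greater"
) -> FisherResult:
    """Exact conditional test of association in a 2x2 table.

    ``alternative`` orients the one-sided p: "greater" is enrichment of
    carriers among cases (odds ratio > 1), "less" the reverse.
    """
    p_one, p_two = exact_pvalues(
        t.a, t.total, t.a + t.b, t.a + t.c, alternative
    )
    table = [[t.a, t.b], [t.c, t.d]]
    cmle = stats.contingency.odds_ratio(table, kind="conditional")
    ci = cmle.confidence_interval(0.95)
    return FisherResult(
        p_one=p_one,
        p_two=p_two,
        or_sample=odds_ratio_sample(t),
        or_cmle=float(cmle.statistic),
        ci95=(float(ci.low), float(ci.high)),
    )


class BonferroniThreshold(NamedTuple):
    exact: float
    two_sf: float


def bonferroni(alpha: float, n_tests: int) -> BonferroniThreshold:
    """Bonferroni-corrected per-test alpha, with its 2-significant-figure
    presentation value alongside full precision."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    exact = alpha / n_tests
    if exact == 0:
        return BonferroniThreshold(0.0, 0.0)
    digits = -int(math.floor(math.log10(abs(exact)))) + 1
    return BonferroniThreshold(exact, round(exact, digits))


# ---------------------------------------------------------------------------
# per-sample burden statistics
# ---------------------------------------------------------------------------


def burden_statistics(
    cnvs: Sequence[ConsensusCnv], sample_ids: Sequence[str]
) -> dict[str, pd.DataFrame]:
    """Per-sample burden vectors for each CNV class.

    Returns {cnv_class: DataFrame indexed by sample_id with the 7 burden
    statistics}. Samples without CNVs contribute 0 to counts/kb/carrier and
    NaN to the per-CNV means (they are excluded from those tests' means).
    Gene-based statistics require annotated CNVs (gene_count >= 0).
    """
    out: dict[str, pd.DataFrame] = {}
    for klass in CNV_CLASSES:
        sel = [
            c for c in cnvs
            if klass == "all"
            or (klass == "deletions" and c.state == "deletion")
            or (klass == "duplications" and c.state == "duplication")
        ]
        rows = {}
        by_sample: dict[str, list[ConsensusCnv]] = {}
        for c in sel:
            by_sample.setdefault(c.sample_id, []).append(c)
        for sid in sample_ids:
            mine = by_sample.get(sid, [])
            k = len(mine)
            total_kb = sum(c.length_bp for c in mine) / 1_000.0
            genes = [max(c.gene_count, 0) for c in mine]
            rows[sid] = {
                "carrier": float(k > 0),
                "count": float(k),
                "total_kb": total_kb,
                "mean_length_kb": total_kb / k if k else math.nan,
                "genes_total": float(sum(genes)),
                "mean_genes_per_cnv": sum(genes) / k if k else math.nan,
                "genic_count": float(sum(g > 0 for g in genes)),
            }
        out[klass] = pd.DataFrame.from_dict(rows, orient="index").reindex(
            columns=list(BURDEN_STATISTICS)
        )
        out[klass].index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# permutation burden testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurdenResult:
    test_id: tuple[str, str, str]  # (contrast, cnv_class, statistic)
    observed: float
    perm_p: float
    n_perm: int
    case_mean: float
    control_mean: float
    passes_bonferroni: bool | None = None


def permutation_burden(
    values: np.ndarray,
    is_case: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    test_id: tuple[str, str, str] = ("", "", ""),
    alternative: str = "greater",
) -> BurdenResult:
    """One-sided label-permutation test of the difference in arm means.

    NaN values (samples excluded from per-CNV means) are dropped arm-wise;
    permutations preserve arm sizes. The empirical p carries the add-one
    correction so it is never 0. A degenerate (constant) statistic returns
    perm_p = 1.
    """
    values = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need at least 2 samples in each arm")
    valid = ~np.isnan(values)
    v = np.where(valid, values, 0.0)
    sign = 1.0 if alternative == "greater" else -1.0

    def diff(mask: np.ndarray) -> np.ndarray:
        """Difference in arm means for a (stack of) case masks."""
        m = mask.astype(float)
        n_case = m @ valid
        n_ctrl = (1.0 - m) @ valid
        with np.errstate(invalid="ignore", divide="ignore"):
            return (m @ v) / n_case - ((1.0 - m) @ v) / n_ctrl

    obs = float(diff(is_case[None, :])[0])
    case_vals = values[is_case & valid]
    ctrl_vals = values[~is_case & valid]
    case_mean = float(case_vals.mean()) if len(case_vals) else math.nan
    ctrl_mean = float(ctrl_vals.mean()) if len(ctrl_vals) else math.nan
    if not np.isfinite(obs) or np.nanstd(values[valid]) == 0:
        return BurdenResult(test_id, obs, 1.0, n_perm, case_mean, ctrl_mean)

    rng = np.random.default_rng(seed)
    n = len(values)
    exceed = 0
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        keys = rng.random((k, n))
        order = np.argsort(keys, axis=1)
        masks = np.zeros((k, n), dtype=bool)
        np.put_along_axis(masks, order[:, : int(is_case.sum())], True, axis=1)
        d = diff(masks)
        exceed += int(np.sum(sign * d >= sign * obs - 1e-12))
        done += k
    perm_p = (1 + exceed) / (n_perm + 1)
    return BurdenResult(test_id, obs, perm_p, n_perm, case_mean, ctrl_mean)


def burden_test_grid(
    cohorts: Mapping[str, str] | pd.Series,
) -> list[tuple[str, str, str]]:
    """The full test grid: 3 contrasts x 3 CNV classes x 7 statistics = 63."""
    return [
        (contrast, klass, statistic)
        for contrast in CONTRASTS
        for klass in CNV_CLASSES
        for statistic in BURDEN_STATISTICS
    ]


def _contrast_masks(cohort: pd.Series, contrast: str) -> tuple[pd.Index, np.ndarray]:
    case = cohort == "case"
    if contrast == "cases_vs_all_controls":
        keep = cohort.index
    elif contrast == "cases_vs_screened":
        keep = cohort.index[case | (cohort == "screened_control")]
    elif contrast == "cases_vs_wtccc2":
        keep = cohort.index[case | (cohort == "population_control")]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return keep, case.loc[keep].to_numpy()


def run_burden_grid(
    stats_by_class: Mapping[str, pd.DataFrame],
    cohort: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run all 63 permutation burden tests and flag Bonferroni survivors.

    ``cohort`` maps sample_id -> {case, screened_control, population_control}.
    Each test draws its permutations from a child seed of ``seed`` keyed by
    its grid position, so single tests are reproducible in isolation.
    """
    grid = burden_test_grid(cohort)
    thr = bonferroni(alpha, len(grid))
    rows = []
    for i, (contrast, klass, statistic) in enumerate(grid):
        keep, is_case = _contrast_masks(cohort, contrast)
        values = stats_by_class[klass].loc[keep, statistic].to_numpy()
        res = permutation_burden(
            values, is_case, n_perm=n_perm,
            seed=np.random.SeedSequence((seed, i)),
            test_id=(contrast, klass, statistic),
        )
        rows.append(
            {
                "contrast": contrast, "cnv_class": klass, "statistic": statistic,
                "observed": res.observed, "case_mean": res.case_mean,
                "control_mean": res.control_mean, "perm_p": res.perm_p,
                "n_perm": res.n_perm,
                "passes_bonferroni": res.perm_p <= thr.exact,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    df.attrs["alpha_bonferroni"] = thr.exact
    return df
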