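"""Statistical battery linking subjective and objective sleepiness.

The battery mirrors common practice in observational sleep research:

* Kruskal-Wallis tests for univariate between-group location differences;
* Spearman rank correlations with small-sample significance handling;
* Fisher-z tests for differences between correlations estimated in
  independent groups;
* a canonical correlation analysis between the subjective block
  (SSS/KSS/VAS pre and post, their change scores, ASLEEP) and the
  objective block (stage proportions, MVV, ASS), tested globally with
  the Pillai-Bartlett trace whose null distribution is approximated by
  resampling (row permutation of one block, 9999 replications by
  default) instead of relying on Gaussianity;
* Gaussian regressions with ANOVA F-tests for metric outcomes (VAS,
  ESS) on age, gender, sleep quality, depression, obesity, an objective
  measure (MVV or ASS) and all their interactions;
* proportional-odds cumulative logit models with likelihood-ratio
  chi-square tests for ordinal outcomes (KSS, SSS, ASLEEP);
* Wilcoxon rank-sum tests for pairwise group contrasts.

P-values are reported uncorrected for multiplicity throughout; callers
that screen many tests should apply their own correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as scl
from scipy import stats as sct

__all__ = [
    "StatResult",
    "SUBJECTIVE_VARS",
    "OBJECTIVE_VARS",
    "variable_blocks",
    "kruskal_wallis",
    "spearman_with_p",
    "correlation_difference_test",
    "cca_pillai_bootstrap",
    "fit_linear_interaction_model",
    "fit_proportional_odds",
    "proportional_odds_null_thresholds",
    "rank_sum_test",
    "FitFailure",
]

SUBJECTIVE_VARS = (
    "sss_pre",
    "kss_pre",
    "vas_pre",
    "sss_post",
    "kss_post",
    "vas_post",
    "d_sss",
    "d_kss",
    "d_vas",
    "asleep",
)
OBJECTIVE_VARS = ("prop_0", "prop_a", "prop_b", "prop_c", "mvv", "ass")


class FitFailure(RuntimeError):
    """A model fit failed to converge or the design is degenerate."""


@dataclass(frozen=True)
class StatResult:
    """One test: statistic, df where applicable, uncorrected p-value."""

    name: str
    statistic: float
    p: float
    df: float | tuple[float, float] | None = None
    context: str | None = None
    method: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def variable_blocks(
    df: pd.DataFrame,
    subjective=SUBJECTIVE_VARS,
    objective=OBJECTIVE_VARS,
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-case subjective/objective matrices, rows aligned."""
    cols = list(subjective) + list(objective)
    complete = df[cols].dropna()
    return complete[list(subjective)].to_numpy(float), complete[
        list(objective)
    ].to_numpy(float)


def kruskal_wallis(values, group_labels) -> StatResult:
    """Kruskal-Wallis H across groups (tie-corrected, chi-square p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    if np.ptp(values) == 0:
        # identical values everywhere: H = 0 by definition
        return StatResult("kruskal_wallis", 0.0, 1.0, df=len(groups) - 1,
                          method="rank chi-square")
    h, p = sct.kruskal(*groups)
    return StatResult(
        "kruskal_wallis", float(h), float(p), df=len(groups) - 1,
        method="rank chi-square",
    )


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sct.rankdata(x)
    ry = sct.rankdata(y)
    n = rx.size
    if np.unique(rx).size == n and np.unique(ry).size == n:
        # tie-free: the exact rational formula avoids rounding at |rho|=1
        d = rx - ry
        return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1)))
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_with_p(x, y, seed: int = 0) -> StatResult:
    """Spearman rank correlation with small-sample significance.

    Average ranks handle ties.  The p-value ladder: exact enumeration of
    all rank permutations for n <= 8 without ties; a seeded permutation
    approximation (9999 replications) for n <= 13 or small tied samples;
    the usual t approximation for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = _spearman_rho(x, y)
    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= 8 and not has_ties:
        ry = sct.rankdata(y)
        count = 0
        total = 0
        rx0 = sct.rankdata(x)
        for perm in itertools.permutations(rx0):
            r = np.corrcoef(perm, ry)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return StatResult("spearman", rho, count / total, context=f"n={n}",
                          method="exact permutation")
    if n <= 13:
        rng = np.random.default_rng(seed)
        reps = 9999
        rx = sct.rankdata(x)
        ry = sct.rankdata(y)
        exceed = 0
        for _ in range(reps):
            r = np.corrcoef(rng.permutation(rx), ry)[0, 1]
            exceed += abs(r) >= abs(rho) - 1e-12
        p = (1 + exceed) / (reps + 1)
        return StatResult("spearman", rho, p, context=f"n={n}",
                          method="monte-carlo permutation")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
        p = 2 * sct.t.sf(abs(t), df=n - 2)
    return StatResult("spearman", rho, min(p, 1.0), df=n - 2, context=f"n={n}",
                      method="t approximation")


def correlation_difference_test(r1: float, n1: int, r2: float, n2: int) -> StatResult:
    """Test equality of two correlations from independent groups.

    Fisher z-transforms each correlation; the statistic is
    (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)) with a two-sided normal
    p-value.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
        if n < 4:
            raise ValueError("each group needs n >= 4")
    z1 = math.atanh(r1)
    z2 = math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2 * sct.norm.sf(abs(z))
    return StatResult(
        "correlation_difference", float(z), float(min(p, 1.0)),
        context=f"n1={n1}, n2={n2}", method="fisher z",
        extra={"difference": r1 - r2},
    )


def _orthonormal_basis(block: np.ndarray, name: str) -> np.ndarray:
    """Orthonormal basis of a standardized block's column space.

    Exact linear dependencies (the change scores are post minus pre by
    construction) are resolved by a rank-revealing QR: the analysis runs
    on the block's effective rank, as R's ``cancor`` does.  A constant
    column is an error naming the offending block.
    """
    std = block.std(axis=0, ddof=1)
    if np.any(std == 0):
        bad = np.flatnonzero(std == 0).tolist()
        raise ValueError(f"{name} block has constant column(s) at index {bad}")
    z = (block - block.mean(axis=0)) / std
    q, r, _ = scl.qr(z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * max(z.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank == 0:
        raise ValueError(f"{name} block is rank zero")
    return q[:, :rank]


def cca_pillai_bootstrap(
    subjective: np.ndarray,
    objective: np.ndarray,
    replications: int = 9999,
    seed: int | None = None,
) -> StatResult:
    """Global subjective-objective association via canonical correlation.

    Columns are standardized; canonical correlations are the singular
    values between the orthonormal bases of the two blocks, and the
    Pillai-Bartlett trace is the sum of their squares.  The null
    distribution is approximated by resampling: the rows of one block
    are permuted, which preserves each block's internal correlation
    structure while breaking the between-block link.  The p-value uses
    the add-one rule (1 + #{trace* >= trace}) / (replications + 1).
    """
    x = np.asarray(subjective, dtype=float)
    y = np.asarray(objective, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("blocks must be 2-d with equal row counts")
    n = x.shape[0]
    if n <= x.shape[1] + y.shape[1]:
        raise ValueError("need more observations than total variables")
    qx = _orthonormal_basis(x, "subjective")
    qy = _orthonormal_basis(y, "objective")
    sv = np.linalg.svd(qx.T @ qy, compute_uv=False)
    sv = np.clip(sv, 0.0, 1.0)
    trace = float(np.sum(sv**2))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(replications):
        perm = rng.permutation(n)
        sv_null = np.linalg.svd(qx.T @ qy[perm], compute_uv=False)
        exceed += np.sum(np.clip(sv_null, 0, 1) ** 2) >= trace - 1e-12
    p = (1 + exceed) / (replications + 1)
    return StatResult(
        "cca_pillai", trace, float(p),
        method=f"permutation bootstrap ({replications} replications)",
        extra={"canonical_correlations": sv.tolist()},
    )


def _interaction_formula(dv: str, objective: str) -> str:
    return f"{dv} ~ age + C(gender) + ssq + depressed * obese * {objective}"


def fit_linear_interaction_model(df: pd.DataFrame, dv: str, objective: str = "mvv"):
    """Gaussian regression of a metric subjective measure on covariates,
    depression, obesity, the objective measure and all their
    interactions; per-term type-II ANOVA F-tests.

    Returns the fitted statsmodels results object with the ANOVA table
    attached as ``.anova`` (columns F and PR(>F) per term).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = df.dropna(subset=[dv, "age", "gender", "ssq", "depressed", "obese",
                             objective])
    model = smf.ols(_interaction_formula(dv, objective), data=data)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        _, _, pivot = scl.qr(model.exog, mode="economic", pivoting=True)
        aliased = [model.exog_names[i] for i in pivot[rank:]]
        raise FitFailure(f"collinear design; aliased terms: {aliased}")
    res = model.fit()
    res.anova = anova_lm(res, typ=2)
    return res


def _po_design(df: pd.DataFrame, objective: str, terms: list[str]) -> pd.DataFrame:
    gender = (df["gender"] == "male").astype(float)
    base = {
        "age": df["age"].astype(float),
        "gender_male": gender,
        "ssq": df["ssq"].astype(float),
        "depressed": df["depressed"].astype(float),
        "obese": df["obese"].astype(float),
        "objective": df[objective].astype(float),
    }
    design = pd.DataFrame(base, index=df.index)
    for term in terms:
        parts = term.split(":")
        design[term] = np.prod([design[p] if p in design else base[p] for p in parts],
                               axis=0)
    return design


_PO_INTERACTIONS = [
    "depressed:obese",
    "depressed:objective",
    "obese:objective",
    "depressed:obese:objective",
]


def _po_fit(endog: pd.Series, exog: pd.DataFrame):
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    model = OrderedModel(endog.astype(float), exog, distr="logit")
    with np.errstate(over="ignore", invalid="ignore"):
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    if not res.mle_retvals.get("converged", False):
        raise FitFailure(
            f"proportional-odds fit did not converge "
            f"(iterations={res.mle_retvals.get('iterations')}, "
            f"gradient norm unavailable); possible separation"
        )
    return res


@dataclass(frozen=True)
class ProportionalOddsFit:
    """Cumulative-logit fit with likelihood-ratio interaction tests."""

    params: pd.Series
    llf: float
    lr_tests: pd.DataFrame
    result: object  # statsmodels results, for diagnostics


def fit_proportional_odds(
    df: pd.DataFrame,
    dv: str,
    objective: str = "mvv",
    interactions: tuple[str, ...] = tuple(_PO_INTERACTIONS),
) -> ProportionalOddsFit:
    """Proportional-odds cumulative logit model for an ordinal outcome.

    The linear predictor contains age, gender, SSQ, depression, obesity,
    the objective measure, all two-way interactions among
    {depression, obesity, objective} and their three-way interaction;
    slopes are shared across thresholds.  Each interaction term is
    tested with a likelihood-ratio chi-square comparing the model with
    and without it (higher-order terms containing it are excluded from
    both models, respecting marginality).
    """
    data = df.dropna(subset=[dv, "age", "gender", "ssq", "depressed", "obese",
                             objective])
    endog = data[dv].astype(float)
    if endog.nunique() < 3:
        raise ValueError("ordinal outcome needs at least 3 observed levels")
    interactions = list(interactions)
    full_exog = _po_design(data, objective, interactions)
    full = _po_fit(endog, full_exog)
    rows = []
    for term in interactions:
        containing = [t for t in interactions if t != term
                      and set(term.split(":")) < set(t.split(":"))]
        kept = [t for t in interactions if t != term and t not in containing]
        if not containing:
            with_term = full
        else:
            with_term = _po_fit(endog, _po_design(data, objective, kept + [term]))
        without = _po_fit(endog, _po_design(data, objective, kept))
        lr = 2.0 * (with_term.llf - without.llf)
        lr = max(lr, 0.0)
        p = sct.chi2.sf(lr, df=1)
        rows.append({"term": term, "lr_chi2": lr, "df": 1, "p": float(p)})
    if rows:
        lr_tests = pd.DataFrame(rows).set_index("term")
    else:
        lr_tests = pd.DataFrame(columns=["lr_chi2", "df", "p"])
    return ProportionalOddsFit(
        params=full.params, llf=float(full.llf), lr_tests=lr_tests, result=full
    )


def proportional_odds_null_thresholds(values) -> np.ndarray:
    """Closed-form thresholds of the predictor-free cumulative logit
    model: the logits of the cumulative observed frequencies."""
    values = np.asarray(values)
    levels = np.sort(np.unique(values))
    n = values.size
    cum = np.cumsum([np.sum(values == lv) for lv in levels[:-1]]) / n
    return np.array([math.log(c / (1 - c)) for c in cum])


def rank_sum_test(a, b) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample is small (n <= 20) and
    tie-free; the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return StatResult(
            "rank_sum", a.size * b.size / 2.0, 1.0,
            context=f"n1={a.size}, n2={b.size}", method="degenerate",
        )
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and tie_free) else "asymptotic"
    res = sct.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        "rank_sum", float(res.statistic), float(min(res.pvalue, 1.0)),
        context=f"n1={a.size}, n2={b.size}", method=method,
    )
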