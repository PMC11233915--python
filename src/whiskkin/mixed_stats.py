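"""Linear mixed-model inference for clip-level whisker metrics.

Implements the analysis plan used for whisker object-exploration cohorts:
each metric is modelled with fixed factorial effects (treatment x sex on
the combined data, then treatment x object texture within each sex) and a
random intercept per animal, since an animal contributes 1-4 clips.  Fits
use restricted maximum likelihood (REML) with the variance ratio profiled
out, type-III F-tests under sum-to-zero factor coding, Kenward-Roger
small-sample adjustment of the fixed-effect covariance and denominator
degrees of freedom, and Tukey (studentized-range) adjustment of pairwise
comparisons of estimated marginal means.

The Kenward-Roger machinery is implemented directly: the model's marginal
covariance V = sigma_a^2 ZZ' + sigma_e^2 I is linear in its two variance
parameters, so the second-derivative terms of the adjusted covariance
vanish and the first-order adjusted covariance
Phi_A = Phi + 2 Phi {sum_ij W_ij (Q_ij - P_i Phi P_j)} Phi together with
the scaled-F degrees-of-freedom formulas gives the complete test.  For
the degenerate design with one clip per animal the model is
OLS-equivalent (the two variance components are confounded, only their
sum is identified) and the classical F-test with df2 = n - rank(X) is
returned exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trace_io import METRIC_NAMES

__all__ = [
    "LmmSpec",
    "TermTest",
    "LmmResult",
    "PairwiseComparison",
    "SingularDesignError",
    "fit_lmm",
    "tukey_pairwise",
    "analysis_suite",
    "AnalysisReport",
    "PC_RESPONSES",
    "DELTA_RESPONSES",
]

PC_RESPONSES = [f"pc_{m}" for m in METRIC_NAMES]
DELTA_RESPONSES = [f"delta_{m}" for m in METRIC_NAMES]


class SingularDesignError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """The REML profile optimisation failed to converge."""


@dataclass(frozen=True)
class LmmSpec:
    """Model specification: response ~ factor1 * factor2 + (1 | group).

    Factors are coded sum-to-zero so the type-III F-tests match the
    factorial ANOVA presentation; ``interaction=False`` drops the
    interaction term.
    """

    response: str
    factors: tuple[str, ...]
    group: str = "animal_id"
    interaction: bool = True

    def __post_init__(self) -> None:
        if not (1 <= len(self.factors) <= 2):
            raise ValueError("LmmSpec supports one or two fixed factors")

    @property
    def formula(self) -> str:
        coded = [f"C({f}, Sum)" for f in self.factors]
        if len(coded) == 1:
            return coded[0]
        op = "*" if self.interaction else "+"
        return f"{coded[0]} {op} {coded[1]}"

    def term_names(self) -> list[str]:
        terms = list(self.factors)
        if self.interaction and len(self.factors) == 2:
            terms.append(":".join(self.factors))
        return terms


@dataclass
class TermTest:
    """Type-III F-test for one fixed-effect term."""

    term: str
    f_stat: float
    df1: int
    df2: float
    p_value: float
    method: str  # "KR", "OLS" or "Satterthwaite"


@dataclass
class LmmResult:
    """A fitted random-intercept model with small-sample F-tests."""

    spec: LmmSpec
    n_obs: int
    n_groups: int
    n_dropped: int
    beta: np.ndarray
    beta_se: np.ndarray
    coef_names: list[str]
    sigma2_animal: float
    sigma2_resid: float
    converged: bool
    boundary: bool  # animal-intercept variance estimated at zero
    ols_equivalent: bool  # one observation per group: variance split not identified
    tests: dict[str, TermTest]
    _internals: dict = field(default_factory=dict, repr=False)

    @property
    def rank(self) -> int:
        return len(self.beta)


@dataclass
class PairwiseComparison:
    """One Tukey-adjusted pairwise contrast of estimated marginal means."""

    contrast: str
    estimate: float
    se: float
    t_stat: float
    df: float
    p_raw: float
    p_tukey: float
    family_size: int


# ---------------------------------------------------------------------------
# REML fitting


def _design(table: pd.DataFrame, spec: LmmSpec):
    from patsy import dmatrix

    cols = [spec.response, spec.group, *spec.factors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"model columns missing from table: {missing}")
    data = table[cols].dropna()
    n_dropped = len(table) - len(data)
    for f in spec.factors:
        if data[f].nunique() < 2:
            raise SingularDesignError(
                f"factor {f!r} has fewer than 2 observed levels"
            )
    y = data[spec.response].to_numpy(float)
    dm = dmatrix(self_formula := spec.formula, data, return_type="dataframe")
    X = dm.to_numpy(float)
    design_info = dm.design_info
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify aliased columns by pivoted QR
        r = np.linalg.qr(X, mode="r")
        aliased = [
            design_info.column_names[j]
            for j in range(X.shape[1])
            if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))
        ]
        raise SingularDesignError(
            f"design matrix for {self_formula!r} is rank deficient; "
            f"aliased column(s): {aliased}"
        )
    groups, group_idx = np.unique(data[spec.group].to_numpy(), return_inverse=True)
    return y, X, design_info, group_idx, len(groups), n_dropped, data


def _profile_reml(y: np.ndarray, X: np.ndarray, group_idx: np.ndarray):
    """Profiled REML for y = X b + Z u + e with a single grouping factor.

    The ratio lam = sigma_a^2 / sigma_e^2 is profiled: for fixed lam,
    H = I + lam ZZ' and sigma_e^2 has a closed form.  Returns
    (lam, sigma_e2, converged).  The criterion is minimised on log(lam)
    with a bounded scalar search (tolerance 1e-8 on the criterion scale)
    and compared against the lam = 0 boundary.
    """
    n, p = X.shape
    Z = np.zeros((n, group_idx.max() + 1))
    Z[np.arange(n), group_idx] = 1.0
    G = Z @ Z.T

    def neg2_restricted_ll(lam: float) -> float:
        H = np.eye(n) + lam * G
        cho = np.linalg.cholesky(H)
        logdet_h = 2.0 * np.sum(np.log(np.diag(cho)))
        Hi_y = np.linalg.solve(H, y)
        Hi_X = np.linalg.solve(H, X)
        XtHiX = X.T @ Hi_X
        beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
        r = y - X @ beta
        rss = float(r @ np.linalg.solve(H, r))
        sign, logdet_x = np.linalg.slogdet(XtHiX)
        return logdet_h + logdet_x + (n - p) * math.log(max(rss, 1e-300))

    res = optimize.minimize_scalar(
        lambda u: neg2_restricted_ll(math.exp(u)),
        bounds=(-25.0, 25.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam_hat = math.exp(res.x)
    crit_hat = res.fun
    crit_zero = neg2_restricted_ll(0.0)
    if crit_zero <= crit_hat + 1e-8:
        lam_hat, crit_hat = 0.0, crit_zero
    H = np.eye(n) + lam_hat * G
    Hi_y = np.linalg.solve(H, y)
    Hi_X = np.linalg.solve(H, X)
    beta = np.linalg.solve(X.T @ Hi_X, X.T @ Hi_y)
    r = y - X @ beta
    sigma_e2 = float(r @ np.linalg.solve(H, r)) / (n - p)
    return lam_hat, sigma_e2, bool(res.success), G


def _kr_machinery(X: np.ndarray, G: np.ndarray, sigma_a2: float, sigma_e2: float):
    """Kenward-Roger building blocks for V = sigma_a2 G + sigma_e2 I."""
    n, p = X.shape
    V = sigma_a2 * G + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    Phi = np.linalg.inv(XtViX)
    Proj = Vi - ViX @ Phi @ ViX.T  # REML projection

    derivs = (G, np.eye(n))
    info = np.empty((2, 2))
    PV = [Proj @ Vd for Vd in derivs]
    for i in range(2):
        for j in range(2):
            info[i, j] = 0.5 * np.trace(PV[i] @ PV[j])
    W = np.linalg.pinv(info)

    P_mats = [ViX.T @ Vd @ ViX for Vd in derivs]  # X' Vi V_i Vi X
    # Q_ij = X' Vi V_i Vi V_j Vi X
    VdViX = [Vd @ ViX for Vd in derivs]
    Q_mats = {
        (i, j): VdViX[i].T @ Vi @ VdViX[j] for i in range(2) for j in range(2)
    }

    adj = np.zeros((p, p))
    for i in range(2):
        for j in range(2):
            adj += W[i, j] * (Q_mats[i, j] - P_mats[i] @ Phi @ P_mats[j])
    Phi_A = Phi + 2.0 * Phi @ adj @ Phi
    return {"Phi": Phi, "Phi_A": Phi_A, "W": W, "P": P_mats}


def _kr_ftest(L: np.ndarray, beta: np.ndarray, kr: dict) -> tuple[float, float, float, str]:
    """Scaled F statistic, KR denominator df and p-value for H0: L beta = 0."""
    Phi, Phi_A, W, P = kr["Phi"], kr["Phi_A"], kr["W"], kr["P"]
    L = np.atleast_2d(L)
    ell = L.shape[0]
    M = L @ Phi_A @ L.T
    # fall back to the unadjusted covariance if the adjustment overshoots
    method = "KR"
    if np.any(np.linalg.eigvalsh((M + M.T) / 2) <= 0):
        M = L @ Phi @ L.T
        method = "KR-unadjusted"
    Lb = L @ beta
    f0 = float(Lb @ np.linalg.solve(M, Lb)) / ell

    Theta = L.T @ np.linalg.solve(L @ Phi @ L.T, L)
    TP = [Theta @ Phi @ Pi @ Phi for Pi in P]
    A1 = A2 = 0.0
    for i in range(2):
        for j in range(2):
            A1 += W[i, j] * np.trace(TP[i]) * np.trace(TP[j])
            A2 += W[i, j] * np.trace(TP[i] @ TP[j])
    B = (A1 + 6.0 * A2) / (2.0 * ell)
    denom_g = (ell + 2.0) * A2
    if abs(denom_g) < 1e-300:
        # no sampling variability in the variance estimates: classical F
        df2 = float("inf")
        scale = 1.0
    else:
        g = ((ell + 1.0) * A1 - (ell + 4.0) * A2) / denom_g
        c1 = g / (3.0 * ell + 2.0 * (1.0 - g))
        c2 = (ell - g) / (3.0 * ell + 2.0 * (1.0 - g))
        c3 = (ell + 2.0 - g) / (3.0 * ell + 2.0 * (1.0 - g))
        e_star = 1.0 / (1.0 - A2 / ell)
        v_star = (
            (2.0 / ell)
            * (1.0 + c1 * B)
            / ((1.0 - c2 * B) ** 2 * (1.0 - c3 * B))
        )
        rho = v_star / (2.0 * e_star**2)
        if ell * rho > 1.0:
            df2 = 4.0 + (ell + 2.0) / (ell * rho - 1.0)
        else:
            df2 = float("inf")
        scale = df2 / (e_star * (df2 - 2.0)) if math.isfinite(df2) else 1.0
    f_kr = scale * f0
    if math.isfinite(df2):
        p = float(stats.f.sf(f_kr, ell, df2))
    else:
        p = float(stats.chi2.sf(ell * f_kr, ell))
        df2 = float("inf")
    return f_kr, df2, p, method


def fit_lmm(table: pd.DataFrame, spec: LmmSpec) -> LmmResult:
    """Fit a random-intercept LMM by REML and run type-III KR F-tests.

    Rows with missing values in any model column are dropped (count
    recorded in ``n_dropped``).  When every animal contributes exactly one
    clip the model is OLS-equivalent: classical F-tests with
    df2 = n - rank(X) are reported and ``ols_equivalent`` is set.
    A fit with the animal-intercept variance at the zero boundary is
    allowed and flagged via ``boundary``.
    """
    y, X, design_info, group_idx, n_groups, n_dropped, data = _design(table, spec)
    n, p = X.shape
    if n <= p:
        raise SingularDesignError(
            f"{n} usable rows cannot identify {p} fixed effects plus variance"
        )
    cell_counts = data.groupby(list(spec.factors), observed=True)[spec.group].nunique()
    if (cell_counts < 2).any():
        import warnings

        warnings.warn(
            f"fewer than 2 animals in some {spec.factors} cell(s); "
            "F-tests will be unstable",
            stacklevel=2,
        )

    ols_equivalent = bool(np.bincount(group_idx).max() == 1)
    term_slices = _term_slices(design_info, spec)

    if ols_equivalent:
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sigma2 = float(r @ r) / (n - p)
        Phi = sigma2 * np.linalg.inv(X.T @ X)
        tests = {}
        for term, sl in term_slices.items():
            L = np.eye(p)[sl]
            M = L @ Phi @ L.T
            Lb = L @ beta
            ell = L.shape[0]
            if np.linalg.norm(Lb) <= 1e-10 * max(1.0, float(np.linalg.norm(y))):
                f0 = 0.0  # contrast at round-off scale: no evidence
            else:
                f0 = float(Lb @ np.linalg.pinv(M) @ Lb) / ell
            df2 = float(n - p)
            tests[term] = TermTest(
                term, f0, ell, df2, float(stats.f.sf(f0, ell, df2)), "OLS"
            )
        return LmmResult(
            spec=spec,
            n_obs=n,
            n_groups=n_groups,
            n_dropped=n_dropped,
            beta=beta,
            beta_se=np.sqrt(np.diag(Phi)),
            coef_names=list(design_info.column_names),
            sigma2_animal=float("nan"),
            sigma2_resid=sigma2,
            converged=True,
            boundary=False,
            ols_equivalent=True,
            tests=tests,
            _internals={
                "Phi": Phi,
                "Phi_A": Phi,
                "beta": beta,
                "design_info": design_info,
                "data": data,
                "ols_df2": float(n - p),
            },
        )

    lam, sigma_e2, converged, G = _profile_reml(y, X, group_idx)
    if not converged:
        raise ConvergenceError("REML profile optimisation did not converge")
    # floor keeps V invertible for degenerate (near-constant) responses
    sigma_e2 = max(sigma_e2, 1e-10 * (float(np.var(y)) + 1e-12))
    sigma_a2 = lam * sigma_e2
    kr = _kr_machinery(X, G, sigma_a2, sigma_e2)
    H = np.eye(n) + lam * G
    Hi_X = np.linalg.solve(H, X)
    beta = np.linalg.solve(X.T @ Hi_X, Hi_X.T @ y)

    tests = {}
    for term, sl in term_slices.items():
        L = np.eye(p)[sl]
        f_kr, df2, pval, method = _kr_ftest(L, beta, kr)
        tests[term] = TermTest(term, f_kr, L.shape[0], df2, pval, method)

    return LmmResult(
        spec=spec,
        n_obs=n,
        n_groups=n_groups,
        n_dropped=n_dropped,
        beta=beta,
        beta_se=np.sqrt(np.diag(kr["Phi_A"])),
        coef_names=list(design_info.column_names),
        sigma2_animal=sigma_a2,
        sigma2_resid=sigma_e2,
        converged=converged,
        boundary=bool(lam == 0.0),
        ols_equivalent=False,
        tests=tests,
        _internals={
            **kr,
            "beta": beta,
            "design_info": design_info,
            "data": data,
            "G": G,
        },
    )


def _term_slices(design_info, spec: LmmSpec) -> dict[str, slice]:
    """Map friendly term names (treatment, sex, treatment:sex) to columns."""
    rename = {f"C({f}, Sum)": f for f in spec.factors}
    if len(spec.factors) == 2:
        f1, f2 = spec.factors
        rename[f"C({f1}, Sum):C({f2}, Sum)"] = f"{f1}:{f2}"
    out = {}
    for name, sl in design_info.term_name_slices.items():
        if name == "Intercept":
            continue
        out[rename.get(name, name)] = sl
    return out


# ---------------------------------------------------------------------------
# Tukey pairwise comparisons on estimated marginal means


def tukey_pairwise(
    fit: LmmResult, factors: tuple[str, str] | None = None
) -> list[PairwiseComparison]:
    """All pairwise contrasts of estimated marginal means over factor cells.

    Cells are the observed level combinations of the two model factors.
    Each contrast uses its own Kenward-Roger denominator df; the family
    p-values come from the studentized-range distribution with family size
    k = number of cells, so with two cells the adjusted p equals the raw p.
    Output order (and tie-break) is by sorted cell label, deterministic.
    """
    from patsy import build_design_matrices

    from itertools import product

    factors = tuple(factors or fit.spec.factors)
    design_info = fit._internals["design_info"]
    data = fit._internals["data"]
    level_sets = [sorted(data[f].astype(str).unique()) for f in factors]
    cells = list(product(*level_sets))
    grid = pd.DataFrame([dict(zip(factors, cell)) for cell in cells])
    try:
        (Xg,) = build_design_matrices([design_info], grid)
    except Exception as err:  # pragma: no cover - patsy raises various types
        raise ValueError(f"non-estimable cell in grid {cells}: {err}") from err
    Xg = np.asarray(Xg)
    beta = fit._internals["beta"]
    k = len(cells)
    out: list[PairwiseComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            c = Xg[i] - Xg[j]
            est = float(c @ beta)
            if fit.ols_equivalent:
                Phi = fit._internals["Phi"]
                se = math.sqrt(float(c @ Phi @ c))
                df2 = fit._internals["ols_df2"]
                t = est / se
            else:
                f_kr, df2, _, _ = _kr_ftest(c[None, :], beta, fit._internals)
                Phi_A = fit._internals["Phi_A"]
                se = math.sqrt(float(c @ Phi_A @ c))
                t = math.copysign(math.sqrt(max(f_kr, 0.0)), est)
            p_raw = float(2.0 * stats.t.sf(abs(t), df2)) if math.isfinite(df2) else float(
                2.0 * stats.norm.sf(abs(t))
            )
            if math.isfinite(df2):
                p_tuk = float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df2))
            else:
                p_tuk = p_raw
            p_tuk = min(max(p_tuk, p_raw), 1.0)
            fmt = lambda cell: ",".join(f"{f}={v}" for f, v in zip(factors, cell))
            label = f"{fmt(cells[i])} - {fmt(cells[j])}"
            out.append(
                PairwiseComparison(
                    contrast=label,
                    estimate=est,
                    se=se,
                    t_stat=t,
                    df=df2,
                    p_raw=p_raw,
                    p_tukey=p_tuk,
                    family_size=k,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Full analysis plan


@dataclass
class AnalysisReport:
    """Structured results of the staged mixed-model analysis.

    ``models`` has one row per fitted term (stage, stratum, response, term,
    F, df1, df2, p, method, variance components); ``posthoc`` one row per
    Tukey contrast; ``errors`` one row per model that failed.
    """

    models: pd.DataFrame
    posthoc: pd.DataFrame
    errors: pd.DataFrame
    alpha: float

    def significant(self) -> pd.DataFrame:
        return self.models[self.models["p"] < self.alpha]


def _result_rows(
    fit: LmmResult, stage: str, stratum: str, response: str
) -> list[dict[str, object]]:
    rows = []
    for term, tt in fit.tests.items():
        rows.append(
            {
                "stage": stage,
                "stratum": stratum,
                "response": response,
                "term": term,
                "F": tt.f_stat,
                "df1": tt.df1,
                "df2": tt.df2,
                "p": tt.p_value,
                "method": tt.method,
                "n_obs": fit.n_obs,
                "n_animals": fit.n_groups,
                "sigma2_animal": fit.sigma2_animal,
                "sigma2_resid": fit.sigma2_resid,
                "boundary": fit.boundary,
            }
        )
    return rows


def analysis_suite(
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    responses: list[str] | None = None,
) -> AnalysisReport:
    """Run the staged inference plan on a QC-passed metrics table.

    Stage 1: for each of the 12 responses (6 pre-contact metrics and their
    6 contact-related deltas), treatment x sex with a random intercept per
    animal.  Stage 2: the same responses modelled treatment x object
    texture within each sex.  Stage 3: Tukey pairwise comparisons of the
    four treatment x texture cells wherever a stage-2 interaction has
    p < alpha.  A failing model is recorded and the remaining models still
    run.
    """
    responses = responses or (PC_RESPONSES + DELTA_RESPONSES)
    model_rows: list[dict[str, object]] = []
    posthoc_rows: list[dict[str, object]] = []
    error_rows: list[dict[str, object]] = []

    for response in responses:
        spec = LmmSpec(response=response, factors=("treatment", "sex"))
        try:
            fit = fit_lmm(metrics, spec)
            model_rows += _result_rows(fit, "combined", "all", response)
        except Exception as err:
            error_rows.append(
                {"stage": "combined", "stratum": "all", "response": response,
                 "error": f"{type(err).__name__}: {err}"}
            )

    for sex in ("female", "male"):
        stratum = metrics[metrics["sex"] == sex]
        for response in responses:
            spec = LmmSpec(response=response, factors=("treatment", "object_texture"))
            try:
                fit = fit_lmm(stratum, spec)
            except Exception as err:
                error_rows.append(
                    {"stage": "stratified", "stratum": sex, "response": response,
                     "error": f"{type(err).__name__}: {err}"}
                )
                continue
            model_rows += _result_rows(fit, "stratified", sex, response)
            inter = fit.tests.get("treatment:object_texture")
            if inter is not None and inter.p_value < alpha:
                try:
                    comps = tukey_pairwise(fit)
                except Exception as err:
                    error_rows.append(
                        {"stage": "posthoc", "stratum": sex, "response": response,
                         "error": f"{type(err).__name__}: {err}"}
                    )
                    continue
                for c in comps:
                    posthoc_rows.append(
                        {
                            "stratum": sex,
                            "response": response,
                            "contrast": c.contrast,
                            "estimate": c.estimate,
                            "se": c.se,
                            "t": c.t_stat,
                            "df": c.df,
                            "p_raw": c.p_raw,
                            "p_tukey": c.p_tukey,
                            "family_size": c.family_size,
                        }
                    )

    model_cols = ["stage", "stratum", "response", "term", "F", "df1", "df2", "p",
                  "method", "n_obs", "n_animals", "sigma2_animal", "sigma2_resid",
                  "boundary"]
    posthoc_cols = ["stratum", "response", "contrast", "estimate", "se", "t", "df",
                    "p_raw", "p_tukey", "family_size"]
    error_cols = ["stage", "stratum", "response", "error"]
    return AnalysisReport(
        models=pd.DataFrame(model_rows, columns=model_cols),
        posthoc=pd.DataFrame(posthoc_rows, columns=posthoc_cols),
        errors=pd.DataFrame(error_rows, columns=error_cols),
        alpha=alpha,
    )
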