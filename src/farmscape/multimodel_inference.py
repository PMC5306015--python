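"""Two-stage information-theoretic multimodel inference.

Stage 1 screens six *sets* of landscape variables: all 2^6 - 1 = 63 non-empty
combinations of the sets form the candidate list, every candidate is fitted
as a GLM (Poisson/log for richness counts, Gaussian/identity for temporal
differences), and each set's importance is the summed Akaike weight w_i+ of
the candidates containing it.  Sets with w_i+ > 0.5 are carried forward.

Stage 2 enumerates all subsets of the retained sets' variables (null model
included), computes within every model the *partial standardized coefficient*
of each variable — the unstandardized coefficient times the variable's
partial standard deviation

    s*_j = s_j * sqrt(1 / VIF_j) * sqrt((n - 1) / (n - p)),

where s_j is the sample SD, VIF_j the variance inflation factor of x_j given
the other predictors in that model, and p the number of mean-structure
coefficients including the intercept — and each variable's *relative
importance*, the ratio of its |partial standardized coefficient| to the
largest one in the model.  Both are averaged across the models containing the
variable with Akaike weights renormalised over those models (conditional
averaging).  The partial-SD standardization keeps standardized coefficients
meaningful when predictors are intercorrelated.

AICc is the small-sample-corrected criterion
``-2 LL + 2k + 2k(k+1)/(n-k-1)`` and Akaike weights are
``exp(-delta_i/2) / sum_j exp(-delta_j/2)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design_matrix import AnalysisMatrix

__all__ = [
    "ModelFit",
    "SetImportance",
    "AveragedModel",
    "fit_glm",
    "aicc",
    "akaike_weights",
    "enumerate_stage1",
    "stage1_screen",
    "vif",
    "partial_sd",
    "standardized_coefficients",
    "stage2_average",
]

FAMILIES = ("poisson_log", "gaussian_identity")
W_PLUS_THRESHOLD = 0.5
STAGE2_VARIABLE_CAP = 20


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is not full column rank."""


@dataclass
class ModelFit:
    """One fitted GLM in a candidate list."""

    variables: tuple[str, ...]
    params: pd.Series              # intercept ("const") + slopes
    llf: float                     # exact maximised log-likelihood
    k: int                         # estimated parameters (incl. Gaussian sigma)
    n: int
    aicc: float
    family: str
    deviance: float
    null_deviance: float
    dispersion: float              # Pearson chi^2 / (n - p)
    weight: float = field(default=float("nan"))

    @property
    def pseudo_r2(self) -> float:
        """Deviance-based 1 - D/D0 (classic R^2 for Gaussian models)."""
        if self.null_deviance == 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.params["const"] + X[list(self.variables)].to_numpy() @ self.params[
            list(self.variables)
        ].to_numpy()
        return np.exp(eta) if self.family == "poisson_log" else eta

    def deviance_residuals(self, X: pd.DataFrame, y: pd.Series) -> np.ndarray:
        mu = self.predict(X)
        yv = y.to_numpy(dtype=float)
        if self.family == "gaussian_identity":
            return yv - mu
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(yv > 0, yv * np.log(yv / mu), 0.0)
        d2 = 2.0 * (term - (yv - mu))
        return np.sign(yv - mu) * np.sqrt(np.maximum(d2, 0.0))

    def pearson_residuals(self, X: pd.DataFrame, y: pd.Series) -> np.ndarray:
        mu = self.predict(X)
        yv = y.to_numpy(dtype=float)
        if self.family == "gaussian_identity":
            return yv - mu
        return (yv - mu) / np.sqrt(mu)


def _check_full_rank(design: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via pivoted QR: the trailing pivots are
        # the columns that failed to add rank
        from scipy.linalg import qr

        _, _, piv = qr(design, pivoting=True, mode="economic")
        culprit = [names[i] for i in piv[rank:]]
        raise RankDeficientError(f"design matrix rank deficient; collinear columns: {culprit}")


def fit_glm(matrix: AnalysisMatrix, variables: Sequence[str], family: str | None = None) -> ModelFit:
    """Fit one GLM by maximum likelihood and attach its AICc.

    ``k`` counts the intercept and slopes, plus one for the Gaussian variance
    parameter.  The Gaussian log-likelihood is the exact profile ML value
    ``-n/2 (ln 2*pi + ln(RSS/n) + 1)``, matching the value R reports for
    ``glm`` fits, so AICc values are comparable across software.
    """
    family = matrix.family if family is None else family
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    variables = tuple(variables)
    X = matrix.X[list(variables)] if variables else matrix.X[[]]
    y = matrix.y
    n = len(y)
    design = np.column_stack([np.ones(n)] + [X[v].to_numpy(dtype=float) for v in variables])
    names = ["const", *variables]
    p = design.shape[1]
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} coefficients (need n > k + 1)")
    _check_full_rank(design, names)

    if family == "poisson_log":
        model = sm.GLM(y.to_numpy(dtype=float), design, family=sm.families.Poisson())
        res = model.fit(maxiter=200, tol=1e-10)
        if not res.converged:
            raise RuntimeError(
                f"Poisson GLM failed to converge for variables {list(variables)} "
                f"(deviance trace: {getattr(res, 'fit_history', {}).get('deviance', [])[-5:]})"
            )
        llf = float(res.llf)
        k = p
        mu = res.fittedvalues
        deviance = float(res.deviance)
        null_dev = float(res.null_deviance)
        pearson = float(np.sum((y.to_numpy() - mu) ** 2 / mu))
    else:
        beta, _, _, _ = np.linalg.lstsq(design, y.to_numpy(dtype=float), rcond=None)
        resid = y.to_numpy(dtype=float) - design @ beta
        rss = float(resid @ resid)
        sigma2 = rss / n
        llf = -0.5 * n * (math.log(2 * math.pi) + math.log(sigma2) + 1.0) if sigma2 > 0 else math.inf
        k = p + 1  # variance parameter is estimated
        res_params = beta
        deviance = rss
        yv = y.to_numpy(dtype=float)
        null_dev = float(np.sum((yv - yv.mean()) ** 2))
        pearson = rss

    params = pd.Series(res.params if family == "poisson_log" else res_params, index=names)
    dispersion = pearson / (n - p) if n > p else float("nan")
    return ModelFit(
        variables=variables,
        params=params,
        llf=llf,
        k=k,
        n=n,
        aicc=aicc(llf, k, n),
        family=family,
        deviance=deviance,
        null_deviance=null_dev,
        dispersion=dispersion,
    )


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Iterable[float]) -> np.ndarray:
    """Normalised model probabilities from a list of AICc values."""
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0:
        raise ValueError("empty candidate list")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite AICc values")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def enumerate_stage1(
    sets: Mapping[str, Sequence[str]],
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All non-empty combinations of variable sets.

    Returns ``[(set_names, variables), ...]`` with 2^m - 1 entries for m sets;
    each set occurs in exactly 2^(m-1) candidates.  Sets must be disjoint and
    non-empty.
    """
    names = list(sets)
    seen: dict[str, str] = {}
    for s in names:
        if not sets[s]:
            raise ValueError(f"variable set {s!r} is empty")
        for v in sets[s]:
            if v in seen:
                raise ValueError(f"variable {v!r} appears in sets {seen[v]!r} and {s!r}")
            seen[v] = s
    out = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            variables = tuple(v for s in combo for v in sets[s])
            out.append((combo, variables))
    return out


def stage1_screen(
    matrix: AnalysisMatrix,
    sets: Mapping[str, Sequence[str]],
    family: str | None = None,
) -> tuple[pd.DataFrame, list[ModelFit]]:
    """Fit every set combination and score each set by its summed Akaike weight.

    Returns ``(importance, fits)`` where ``importance`` has one row per set
    with columns ``set, w_plus, retained`` (retained when w_plus > 0.5), and
    ``fits`` carries every candidate with its weight filled in.
    """
    candidates = enumerate_stage1(sets)
    fits: list[ModelFit] = []
    for combo, variables in candidates:
        try:
            fits.append(fit_glm(matrix, variables, family))
        except Exception as exc:
            raise RuntimeError(f"candidate {combo} failed to fit: {exc}") from exc
    weights = akaike_weights([f.aicc for f in fits])
    for f, w in zip(fits, weights):
        f.weight = float(w)
    rows = []
    for set_name in sets:
        w_plus = float(sum(w for (combo, _), w in zip(candidates, weights) if set_name in combo))
        rows.append({"set": set_name, "w_plus": w_plus, "retained": w_plus > W_PLUS_THRESHOLD})
    return pd.DataFrame(rows), fits


def vif(X: pd.DataFrame, j: str) -> float:
    """Variance inflation factor 1 / (1 - R^2_j) of predictor ``j``.

    R^2_j comes from the OLS regression of x_j on the other predictors plus an
    intercept; a lone predictor has VIF exactly 1.  Perfect collinearity
    raises.
    """
    others = [c for c in X.columns if c != j]
    xj = X[j].to_numpy(dtype=float)
    if not others:
        return 1.0
    design = np.column_stack([np.ones(len(xj))] + [X[c].to_numpy(dtype=float) for c in others])
    beta, _, _, _ = np.linalg.lstsq(design, xj, rcond=None)
    resid = xj - design @ beta
    tss = float(np.sum((xj - xj.mean()) ** 2))
    if tss == 0:
        raise ValueError(f"predictor {j!r} is constant")
    r2 = 1.0 - float(resid @ resid) / tss
    if r2 >= 1.0 - 1e-12:
        raise ValueError(f"predictor {j!r} is perfectly collinear with the others (VIF infinite)")
    return 1.0 / (1.0 - r2)


def partial_sd(X: pd.DataFrame, j: str, n: int | None = None) -> float:
    """Partial standard deviation s*_j = s_j sqrt(1/VIF_j) sqrt((n-1)/(n-p)).

    ``p`` counts the mean-structure coefficients of the model the predictor
    sits in, i.e. the number of columns of ``X`` plus the intercept.
    """
    n = len(X) if n is None else n
    p = X.shape[1] + 1
    if n <= p:
        raise ValueError(f"partial SD undefined: n={n} <= p={p}")
    s_j = float(X[j].std(ddof=1))
    return s_j * math.sqrt(1.0 / vif(X, j)) * math.sqrt((n - 1) / (n - p))


def standardized_coefficients(
    fit: ModelFit,
    matrix: AnalysisMatrix,
    *,
    scale_by_response_sd: bool | None = None,
) -> pd.Series:
    """Partial standardized coefficients b_j * s*_j for one fitted model.

    For Gaussian (temporal-difference) models the coefficient is additionally
    divided by the response sample SD by default, so magnitudes are comparable
    across responses; Poisson log-link coefficients are already on the
    response's log scale and are left as is.
    """
    if scale_by_response_sd is None:
        scale_by_response_sd = fit.family == "gaussian_identity"
    X = matrix.X[list(fit.variables)]
    denom = float(matrix.y.std(ddof=1)) if scale_by_response_sd else 1.0
    if denom == 0:
        raise ValueError("response has zero variance")
    vals = {v: fit.params[v] * partial_sd(X, v) / denom for v in fit.variables}
    return pd.Series(vals, dtype=float)


@dataclass
class AveragedModel:
    """Conditional model-averaged standardized coefficients and importances.

    ``table`` has one row per variable: the weighted-average partial
    standardized coefficient and relative importance over models containing
    the variable (weights renormalised over those models), and the variable's
    summed Akaike weight over the whole stage-2 candidate list.
    """

    table: pd.DataFrame
    pseudo_r2: float          # of the global model (all retained variables)
    n_models: int
    fits: list[ModelFit] = field(repr=False, default_factory=list)


def stage2_average(
    matrix: AnalysisMatrix,
    variables: Sequence[str],
    family: str | None = None,
    *,
    include_null: bool = True,
    variable_cap: int = STAGE2_VARIABLE_CAP,
    scale_by_response_sd: bool | None = None,
) -> AveragedModel:
    """Enumerate all subsets of ``variables``, fit, and average per variable.

    Within each model the relative importance of a variable is
    ``|b_j s*_j| / max_m |b_m s*_m|`` (ties: every maximiser gets 1.0); the
    variable with the largest magnitude always scores exactly 1.  Averages
    are conditional: weights are renormalised over the models containing the
    variable.
    """
    variables = list(dict.fromkeys(variables))
    if not variables:
        raise ValueError("stage-2 averaging needs at least one variable")
    if len(variables) > variable_cap:
        raise ValueError(
            f"{len(variables)} variables would enumerate 2^{len(variables)} models; "
            f"raise variable_cap (currently {variable_cap}) explicitly to proceed"
        )
    subsets: list[tuple[str, ...]] = []
    for r in range(0 if include_null else 1, len(variables) + 1):
        subsets.extend(itertools.combinations(variables, r))
    fits = [fit_glm(matrix, sub, family) for sub in subsets]
    weights = akaike_weights([f.aicc for f in fits])
    for f, w in zip(fits, weights):
        f.weight = float(w)

    std_coefs: list[pd.Series] = []
    importances: list[pd.Series] = []
    for f in fits:
        if not f.variables:
            std_coefs.append(pd.Series(dtype=float))
            importances.append(pd.Series(dtype=float))
            continue
        sc = standardized_coefficients(f, matrix, scale_by_response_sd=scale_by_response_sd)
        top = sc.abs().max()
        imp = sc.abs() / top if top > 0 else pd.Series(1.0, index=sc.index)
        std_coefs.append(sc)
        importances.append(imp)

    rows = []
    for v in variables:
        idx = [i for i, f in enumerate(fits) if v in f.variables]
        w = np.array([fits[i].weight for i in idx])
        wsum = float(w.sum())
        wn = w / wsum if wsum > 0 else np.full(len(idx), 1.0 / len(idx))
        coef = float(np.sum(wn * np.array([std_coefs[i][v] for i in idx])))
        imp = float(np.sum(wn * np.array([importances[i][v] for i in idx])))
        rows.append(
            {"variable": v, "coefficient": coef, "importance": imp, "sum_weight": wsum}
        )
    global_fit = next(f for f in fits if len(f.variables) == len(variables))
    return AveragedModel(
        table=pd.DataFrame(rows),
        pseudo_r2=global_fit.pseudo_r2,
        n_models=len(fits),
        fits=fits,
    )
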