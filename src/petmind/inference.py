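"""Cohort-level inference: age effects on MC-MIND coupling.

Global and regional coupling indices are related to age, sex and total
intracranial volume (TIV) by ordinary least squares. Continuous
predictors and the response are z-scored before fitting (so betas are
standardized and unit changes in covariates are absorbed); sex stays
binary 0/1. Stability of the betas is assessed by a subject-level
percentile bootstrap, effect sizes are reported as partial correlations
(each predictor adjusted for the remaining two), and for regional
analyses the age-term p-values are Benjamini-Hochberg adjusted across
regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .datatypes import validate_cohort
from .errors import ValidationError

logger = logging.getLogger(__name__)

PREDICTORS = ("age", "sex", "tiv")
_COND_THRESHOLD = 1e8


@dataclass
class GLMResult:
    """OLS fit of one coupling index on age + sex + TIV."""

    target_id: str
    n_obs: int
    betas: dict[str, float]
    p_values: dict[str, float]
    partial_r: dict[str, float]
    bootstrap_ci: dict[str, tuple[float, float]] | None = None
    q_value: float | None = None  # BH-adjusted p for the age term
    significant: bool | None = None


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot z-score a constant variable")
    return (x - x.mean()) / sd


def _design(cohort: pd.DataFrame) -> np.ndarray:
    """Design matrix [1, z(age), sex, z(tiv)] in fixed column order."""
    return np.column_stack([
        np.ones(len(cohort)),
        _zscore(cohort["age"].to_numpy()),
        cohort["sex"].to_numpy(dtype=float),
        _zscore(cohort["tiv"].to_numpy()),
    ])


def _check_conditioning(X: np.ndarray) -> None:
    cond = np.linalg.cond(X)
    if cond > _COND_THRESHOLD:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValidationError(
            f"collinear predictors: design condition number {cond:.2e}; "
            f"worst pair {PREDICTORS[i]!r}/{PREDICTORS[j]!r} (|r|={abs(corr[i, j]):.4f})"
        )


def fit_glm(y: np.ndarray, cohort: pd.DataFrame, target_id: str = "global") -> GLMResult:
    """OLS of a z-scored response on intercept + z(age) + sex + z(TIV).

    Partial correlations come from the t statistics,
    r_partial = t / sqrt(t^2 + df_resid), which equals the correlation of
    the response and predictor after both are residualised on the other
    predictors.
    """
    cohort = validate_cohort(cohort)
    y = np.asarray(y, dtype=float)
    if y.shape != (len(cohort),):
        raise ValidationError("response length does not match cohort size")
    if np.any(~np.isfinite(y)):
        raise ValidationError("response contains non-finite values")
    n = len(cohort)
    if n <= len(PREDICTORS) + 1:
        raise ValidationError(f"need more subjects ({n}) than predictors plus intercept")
    X = _design(cohort)
    _check_conditioning(X)
    model = sm.OLS(_zscore(y), X).fit()
    df_resid = model.df_resid
    betas, pvals, partial = {}, {}, {}
    for col, name in enumerate(PREDICTORS, start=1):
        t = model.tvalues[col]
        betas[name] = float(model.params[col])
        pvals[name] = float(model.pvalues[col])
        partial[name] = float(t / np.sqrt(t**2 + df_resid))
    return GLMResult(target_id=target_id, n_obs=n, betas=betas, p_values=pvals,
                     partial_r=partial)


def bootstrap_ci(
    y: np.ndarray,
    cohort: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    max_redraws: int = 1000,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for the standardized betas.

    Subjects (rows) are resampled with replacement and the full estimator
    -- including within-resample z-scoring -- is re-run. Resamples with a
    degenerate design (e.g. a single sex) are redrawn and counted.
    """
    cohort = validate_cohort(cohort)
    y = np.asarray(y, dtype=float)
    n = len(cohort)
    rng = np.random.default_rng(seed)
    age = cohort["age"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=float)
    tiv = cohort["tiv"].to_numpy(dtype=float)
    betas = np.empty((n_boot, 3))
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            ys, ag, sx, tv = y[idx], age[idx], sex[idx], tiv[idx]
            if ag.std(ddof=1) == 0 or tv.std(ddof=1) == 0 or sx.std(ddof=1) == 0 \
                    or ys.std(ddof=1) == 0:
                redraws += 1
                continue
            X = np.column_stack([np.ones(n), _zscore(ag), sx, _zscore(tv)])
            coef, *_ = np.linalg.lstsq(X, _zscore(ys), rcond=None)
            betas[b] = coef[1:]
            break
        else:  # pragma: no cover - pathological cohorts only
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
    if redraws:
        logger.warning("bootstrap_ci: redrew %d degenerate resamples", redraws)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        name: (float(np.percentile(betas[:, i], lo)), float(np.percentile(betas[:, i], hi)))
        for i, name in enumerate(PREDICTORS)
    }


def benjamini_hochberg(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up adjusted q-values and the significance mask at level q."""
    p_values = np.asarray(p_values, dtype=float)
    reject, q_values, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return q_values, reject


def regional_age_effects(
    local_rho_by_subject: pd.DataFrame | np.ndarray,
    cohort: pd.DataFrame,
    q: float = 0.05,
    region_ids: list[str] | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-region GLMs of local coupling on age/sex/TIV with FDR control.

    Parameters
    ----------
    local_rho_by_subject : (n_subjects, n_regions) array or DataFrame
        Local coupling per subject and region, aligned with `cohort` rows.
        DataFrame columns supply region ids. NaNs (regions with undefined
        coupling for some subjects) are handled by complete-case fitting;
        the per-region n is reported.
    q : float
        FDR level for the BH adjustment of the age-term p-values.
    n_boot : int
        If > 0, percentile bootstrap CIs for the age beta are computed per
        region (seeded per region from `seed`).

    Returns
    -------
    DataFrame with one row per region: beta/p/partial_r for age (and sex,
    tiv), the BH q-value, the significance flag at level `q`, bootstrap
    bounds when requested, and the complete-case n.
    """
    cohort = validate_cohort(cohort)
    if isinstance(local_rho_by_subject, pd.DataFrame):
        if region_ids is None:
            region_ids = list(local_rho_by_subject.columns)
        values = local_rho_by_subject.to_numpy(dtype=float)
    else:
        values = np.asarray(local_rho_by_subject, dtype=float)
        if region_ids is None:
            region_ids = [f"region_{i}" for i in range(values.shape[1])]
    n_sub, n_reg = values.shape
    if n_sub != len(cohort):
        raise ValidationError("subject dimension does not match cohort table")
    if n_reg < 2:
        raise ValidationError("regional analysis needs >= 2 regions")

    rows = []
    seeds = None
    if n_boot > 0:
        seeds = np.random.SeedSequence(seed).spawn(n_reg)
    for j, region in enumerate(region_ids):
        yj = values[:, j]
        mask = np.isfinite(yj)
        sub = cohort.loc[mask].reset_index(drop=True)
        if mask.sum() <= len(PREDICTORS) + 1:
            logger.warning("region %s: only %d complete cases; skipped", region, mask.sum())
            rows.append({"region_id": region, "n": int(mask.sum())})
            continue
        res = fit_glm(yj[mask], sub, target_id=str(region))
        row = {"region_id": region, "n": res.n_obs}
        for name in PREDICTORS:
            row[f"beta_{name}"] = res.betas[name]
            row[f"p_{name}"] = res.p_values[name]
            row[f"partial_r_{name}"] = res.partial_r[name]
        if n_boot > 0:
            ci = bootstrap_ci(yj[mask], sub, n_boot=n_boot,
                              seed=seeds[j].generate_state(1)[0])
            row["ci_age_lo"], row["ci_age_hi"] = ci["age"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table["significant"] = False
    fitted = table["p_age"].notna() if "p_age" in table else pd.Series(False, index=table.index)
    if fitted.any():
        q_values, reject = benjamini_hochberg(table.loc[fitted, "p_age"].to_numpy(), q=q)
        table.loc[fitted, "q_age"] = q_values
        table.loc[fitted, "significant"] = reject
    table["significant"] = table["significant"].astype(bool)
    return table
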