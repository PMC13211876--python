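"""Comparing strategies to a reference dataset: beta regression, bootstrap, Dunnett.

Two response variables are compared across datasets (simulated strategies vs.
a reference): route efficiency, modeled with a beta regression on the logit
scale, and the experienced bird's social weight, modeled linearly.  Contrasts
against the reference are reported as odds ratios (efficiency) or mean
differences (weight), averaged over generations.

Non-independence from reusing the same source birds across simulated chains
is handled by bird-level bootstrap resampling rather than random-effect
terms, and familywise error over the strategy-vs-reference family is
controlled with Dunnett-style max-|z| resampling from the bootstrap null
(Bonferroni available as a conservative fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "EfficiencyModel",
    "WeightModel",
    "ContrastResult",
    "shrink_unit_interval",
    "fit_beta_regression",
    "fit_weight_model",
    "contrast_odds_ratios",
    "contrast_mean_differences",
    "bootstrap_contrasts",
    "dunnett_adjust",
]


@dataclass(frozen=True)
class ContrastResult:
    """One strategy-vs-reference contrast.

    ``estimate`` is an odds ratio (scale ``"odds_ratio"``) or a mean
    difference (scale ``"difference"``).  ``generation`` is an int for
    per-generation contrasts or ``"marginal"`` when averaged over
    generations.
    """

    label: str
    generation: object
    estimate: float
    ci_lo: float
    ci_hi: float
    p_value: float
    scale: str
    adjusted: bool = False
    df: float = float("inf")  # residual df behind the contrast, for small-n studentization

    def __post_init__(self) -> None:
        if self.scale == "odds_ratio" and self.estimate <= 0:
            raise ValueError("odds ratios must be positive")
        if not self.ci_lo <= self.estimate <= self.ci_hi:
            raise ValueError("confidence interval must contain the estimate")


def shrink_unit_interval(y: np.ndarray) -> np.ndarray:
    """Pull exact 0/1 responses into (0, 1): y' = (y (n-1) + 0.5) / n."""
    y = np.asarray(y, float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


def _prepare_table(table: pd.DataFrame, response: str) -> pd.DataFrame:
    table = table.copy()
    y = table[response].to_numpy(float)
    if response == "efficiency" and (np.any(y <= 0) or np.any(y >= 1)):
        warnings.warn(
            "efficiencies at the unit-interval boundary; applying the standard "
            "(y (n-1) + 0.5)/n shrinkage before beta fitting",
            stacklevel=3,
        )
        table[response] = shrink_unit_interval(y)
    return table


@dataclass(frozen=True)
class _FittedModel:
    results: object
    reference: str | None
    datasets: tuple
    generations: tuple
    formula: str

    @property
    def params(self):
        return self.results.params


class EfficiencyModel(_FittedModel):
    """Beta regression (logit mean link) of efficiency on generation x dataset."""


class WeightModel(_FittedModel):
    """Linear model of experienced-bird weight on generation x dataset."""


def _build_formula(response: str, table: pd.DataFrame, reference: str | None) -> str:
    if reference is not None and table["dataset"].nunique() > 1:
        return f"{response} ~ generation * C(dataset, Treatment('{reference}'))"
    return f"{response} ~ generation"


def fit_beta_regression(
    table: pd.DataFrame, reference: str | None = None
) -> EfficiencyModel:
    """ML fit of a beta regression with a logit mean link and constant precision.

    ``table`` holds per-flight rows with columns ``dataset``, ``generation``
    and ``efficiency`` (strictly inside (0,1); boundary values are shrunk
    with a warning).  With more than one dataset the mean structure is
    ``generation * dataset`` with ``reference`` as the treatment baseline;
    a single dataset reduces to intercept + generation.
    """
    from statsmodels.othermod.betareg import BetaModel

    table = _prepare_table(table, "efficiency")
    datasets = tuple(sorted(table["dataset"].unique()))
    if reference is None and len(datasets) > 1:
        raise ValueError("multiple datasets: a reference must be named")
    if reference is not None and len(datasets) > 1 and reference not in datasets:
        raise ValueError(f"reference {reference!r} not among datasets {datasets}")
    formula = _build_formula("efficiency", table, reference)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BetaModel.from_formula(formula, data=table).fit(disp=False)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("beta regression did not converge to finite estimates")
    return EfficiencyModel(
        results=res,
        reference=reference if len(datasets) > 1 else None,
        datasets=datasets,
        generations=tuple(sorted(table["generation"].unique())),
        formula=formula,
    )


def fit_weight_model(table: pd.DataFrame, reference: str | None = None) -> WeightModel:
    """OLS fit of social weight on generation x dataset (same mean structure)."""
    import statsmodels.formula.api as smf

    datasets = tuple(sorted(table["dataset"].unique()))
    if reference is None and len(datasets) > 1:
        raise ValueError("multiple datasets: a reference must be named")
    formula = _build_formula("weight", table, reference)
    res = smf.ols(formula, data=table).fit()
    return WeightModel(
        results=res,
        reference=reference if len(datasets) > 1 else None,
        datasets=datasets,
        generations=tuple(sorted(table["generation"].unique())),
        formula=formula,
    )


def _marginal_contrast_vector(model: _FittedModel, dataset: str) -> np.ndarray:
    """Design-row difference (dataset vs reference), averaged over generations."""
    from patsy import build_design_matrices

    design_info = model.results.model.data.design_info
    gens = list(model.generations)
    new = pd.DataFrame(
        {
            "generation": gens * 2,
            "dataset": [dataset] * len(gens) + [model.reference] * len(gens),
        }
    )
    (mat,) = build_design_matrices([design_info], new)
    mat = np.asarray(mat)
    L = (mat[: len(gens)] - mat[len(gens):]).mean(axis=0)
    # pad for any non-mean parameters (e.g. the beta precision) in the cov
    n_extra = model.results.params.shape[0] - L.shape[0]
    return np.concatenate([L, np.zeros(n_extra)])


def _wald_contrast(model: _FittedModel, L: np.ndarray) -> tuple[float, float]:
    beta = np.asarray(model.results.params, float)
    cov = np.asarray(model.results.cov_params(), float)
    est = float(L @ beta)
    se = float(np.sqrt(L @ cov @ L))
    return est, se


def _normal_ci_p(est: float, se: float, level: float = 0.95):
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    if se == 0:
        return est, est, 1.0 if est == 0 else 0.0
    p = 2.0 * norm.sf(abs(est) / se)
    return est - z * se, est + z * se, float(p)


def contrast_odds_ratios(model: EfficiencyModel) -> list[ContrastResult]:
    """Strategy-vs-reference odds ratios, marginal over generations.

    Each contrast exponentiates the mean logit difference between a dataset
    and the reference averaged over the observed generations (a Wald contrast
    on the fitted beta regression).
    """
    if model.reference is None:
        raise ValueError("model was fitted without a reference dataset")
    out = []
    for ds in model.datasets:
        if ds == model.reference:
            continue
        L = _marginal_contrast_vector(model, ds)
        est, se = _wald_contrast(model, L)
        lo, hi, p = _normal_ci_p(est, se)
        out.append(
            ContrastResult(
                label=ds, generation="marginal",
                estimate=float(np.exp(est)), ci_lo=float(np.exp(lo)),
                ci_hi=float(np.exp(hi)), p_value=p, scale="odds_ratio",
            )
        )
    return out


def contrast_mean_differences(model: WeightModel) -> list[ContrastResult]:
    """Strategy-vs-reference mean weight differences, marginal over generations."""
    if model.reference is None:
        raise ValueError("model was fitted without a reference dataset")
    out = []
    for ds in model.datasets:
        if ds == model.reference:
            continue
        L = _marginal_contrast_vector(model, ds)
        est, se = _wald_contrast(model, L)
        lo, hi, p = _normal_ci_p(est, se)
        out.append(
            ContrastResult(
                label=ds, generation="marginal",
                estimate=est, ci_lo=lo, ci_hi=hi, p_value=p, scale="difference",
            )
        )
    return out


# --------------------------------------------------------------------------
# Bootstrap contrasts (bird-level resampling) and Dunnett-style adjustment


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _cell_bird_means(sub: pd.DataFrame, value_col: str) -> np.ndarray:
    if "bird" in sub.columns:
        return sub.groupby("bird")[value_col].mean().to_numpy(float)
    return sub[value_col].to_numpy(float)


def bootstrap_contrasts(
    table: pd.DataFrame,
    statistic: str = "efficiency",
    reference: str = "reference",
    n_boot: int = 10_000,
    seed: int = 0,
    match_reference_n: bool = True,
):
    """Percentile bootstrap CIs of per-generation strategy-vs-reference contrasts.

    ``table`` columns: ``dataset``, ``generation``, a value column named by
    ``statistic`` (``efficiency`` or ``weight``), and optionally ``bird`` —
    resampling happens at the bird level when present, targeting the
    dependence induced by reusing the same source birds across chains.
    Efficiency contrasts are odds ratios of group mean efficiencies; weight
    contrasts are mean differences.  With ``match_reference_n`` each bootstrap
    draw uses the reference dataset's per-generation sample size for every
    dataset.  Intervals are expanded percentile intervals: the nominal 2.5 %
    tails are widened by the t-quantile and n/(n-1) factors to undo the
    small-sample narrowness of the plain percentile method.  Returns
    ``(results, replicates)`` where ``replicates`` maps
    ``(strategy, generation)`` to the contrast's bootstrap draws (used by
    :func:`dunnett_adjust`).
    """
    from scipy.stats import norm, t as t_dist
    if statistic not in ("efficiency", "weight"):
        raise ValueError("statistic must be 'efficiency' or 'weight'")
    if n_boot == 1:
        warnings.warn("n_boot=1 gives a degenerate single-draw estimate", stacklevel=2)
    rng = np.random.default_rng(int(seed) % 2**31)
    on_log_odds = statistic == "efficiency"
    scale = "odds_ratio" if on_log_odds else "difference"

    results: list[ContrastResult] = []
    replicates: dict[tuple, np.ndarray] = {}
    for gen in sorted(table["generation"].unique()):
        sub_g = table[table["generation"] == gen]
        cells = {
            ds: _cell_bird_means(sub_g[sub_g["dataset"] == ds], statistic)
            for ds in sub_g["dataset"].unique()
        }
        if reference not in cells:
            raise ValueError(f"reference {reference!r} absent in generation {gen}")
        ref_vals = cells[reference]
        n_ref = ref_vals.size

        def boot_means(vals: np.ndarray) -> np.ndarray:
            size = n_ref if match_reference_n else vals.size
            idx = rng.integers(0, vals.size, size=(n_boot, size))
            return vals[idx].mean(axis=1)

        ref_rep = boot_means(ref_vals)
        ref_obs = float(ref_vals.mean())
        for ds, vals in cells.items():
            if ds == reference:
                continue
            rep = boot_means(vals)
            if on_log_odds:
                theta = _logit(rep) - _logit(ref_rep)
                obs = float(_logit(vals.mean()) - _logit(ref_obs))
            else:
                theta = rep - ref_rep
                obs = float(vals.mean() - ref_obs)
            # expanded percentile interval (small-sample width correction)
            df = n_ref + vals.size - 2
            nh = 2.0 / (1.0 / n_ref + 1.0 / vals.size)
            alpha2 = float(norm.sf(t_dist.ppf(0.975, df) * np.sqrt(nh / max(nh - 1, 1))))
            lo, hi = np.quantile(theta, [alpha2, 1 - alpha2])
            p = 2.0 * min(np.mean(theta <= 0), np.mean(theta >= 0))
            p = float(min(1.0, max(p, 1.0 / n_boot)))
            replicates[(ds, gen)] = theta
            if on_log_odds:
                est, lo, hi = np.exp(obs), np.exp(lo), np.exp(hi)
            else:
                est = obs
            lo, hi = min(lo, est), max(hi, est)
            results.append(
                ContrastResult(
                    label=ds, generation=gen, estimate=float(est),
                    ci_lo=float(lo), ci_hi=float(hi), p_value=p, scale=scale,
                    df=float(n_ref + vals.size - 2),
                )
            )
    return results, replicates


def dunnett_adjust(
    contrasts: list[ContrastResult],
    replicates: dict | None = None,
    method: str = "max_t_resampling",
) -> list[ContrastResult]:
    """Familywise adjustment of strategy-vs-reference contrasts per generation.

    ``max_t_resampling`` centers each contrast's bootstrap draws at its own
    mean (the null), standardizes them, and compares each observed |z| to the
    null distribution of the maximum |z| across the family — the resampling
    analogue of Dunnett's many-to-one procedure, preserving the correlation
    induced by the shared reference draws.  Simultaneous CIs use the 95th
    percentile of that max-|z| distribution.  ``bonferroni`` multiplies raw
    p-values by the family size.  Adjusted p-values are never below raw ones.

    Because the un-studentized bootstrap statistic obs/sd* has t-like rather
    than normal tails in small samples, each observed statistic is mapped to
    the normal scale through the t quantile transform at the contrast's
    residual ``df`` (z = Phi^-1(T_df(t))) before comparison with the max-|z|
    null; simultaneous CI half-widths are back-transformed the same way.  The
    correction vanishes as df grows.
    """
    from scipy.stats import norm, t as t_dist
    families: dict = {}
    for c in contrasts:
        families.setdefault(c.generation, []).append(c)

    out: list[ContrastResult] = []
    for gen, fam in families.items():
        k = len(fam)
        if k == 1:
            out.append(replace(fam[0], adjusted=True))
            continue
        if method == "bonferroni" or replicates is None:
            for c in fam:
                out.append(
                    replace(c, p_value=float(min(1.0, k * c.p_value)), adjusted=True)
                )
            continue
        if method != "max_t_resampling":
            raise ValueError(f"unknown method {method!r}")
        reps = np.vstack([replicates[(c.label, c.generation)] for c in fam])
        centered = reps - reps.mean(axis=1, keepdims=True)
        sds = reps.std(axis=1, ddof=1)
        sds[sds == 0] = np.inf
        max_abs_z = np.max(np.abs(centered / sds[:, None]), axis=0)
        q95 = float(np.quantile(max_abs_z, 0.95))
        B = reps.shape[1]
        for c, sd in zip(fam, sds):
            log_scale = c.scale == "odds_ratio"
            obs = np.log(c.estimate) if log_scale else c.estimate
            z_obs = 0.0 if not np.isfinite(sd) else abs(obs) / sd
            width = q95
            if np.isfinite(c.df) and c.df > 0:
                # t -> normal quantile transform of the observed statistic
                z_obs = float(norm.isf(t_dist.sf(z_obs, c.df)))
                width = float(t_dist.isf(norm.sf(q95), c.df))
            p_adj = float((1 + np.sum(max_abs_z >= z_obs)) / (B + 1))
            p_adj = max(p_adj, c.p_value)
            lo, hi = obs - width * sd, obs + width * sd
            if log_scale:
                lo, hi = np.exp(lo), np.exp(hi)
            out.append(
                replace(
                    c, ci_lo=float(min(lo, c.estimate)),
                    ci_hi=float(max(hi, c.estimate)),
                    p_value=min(1.0, p_adj), adjusted=True,
                )
            )
    return out
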