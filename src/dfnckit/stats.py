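"""Cross-subject GLMs for connectivity outcomes.

Three model families over a neonatal cohort table:

* ``ga``    — outcome ~ b0 + b1*GA  + b2*sex + b3*motion, in term infants
              scanned within one week of birth (isolates gestational age);
* ``pna``   — outcome ~ b0 + b1*PNA + b2*sex + b3*motion, in term infants
              with 40-week GA (isolates postnatal experience);
* ``group`` — outcome ~ b0 + b1*group + b2*PMA + b3*sex + b4*motion,
              preterm vs matched term infants.

The effect of interest is always b1; inference is ordinary least squares
with a two-sided t test.  Family-wise error is controlled by Bonferroni
by default (a seeded max-T permutation variant is available).  Group
contrasts are summarised by Cohen's d = 2t/sqrt(df) and the effect-size
correlation r = |d|/sqrt(d^2 + 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GLMResult",
    "EffectSize",
    "validate_cohort",
    "fit_glm",
    "fwe_correct",
    "effect_sizes",
    "run_analysis",
    "select_subgroup",
]

MODELS = {
    "ga": ("ga_weeks", ["sex_code", "mean_fd"]),
    "pna": ("pna_weeks", ["sex_code", "mean_fd"]),
    "group": ("group_code", ["pma_weeks", "sex_code", "mean_fd"]),
}


@dataclass
class GLMResult:
    """OLS result for the effect of interest in one model."""

    model: str
    beta: float
    se: float
    t: float
    p: float
    df: int
    n: int
    all_betas: np.ndarray | None = None

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import t as tdist

        h = tdist.ppf(1 - alpha / 2, self.df) * self.se
        return self.beta - h, self.beta + h


@dataclass
class EffectSize:
    cohens_d: float
    effect_r: float


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check and encode a cohort table.

    Requires columns subject, ga_weeks, pna_weeks, pma_weeks, sex, group,
    mean_fd.  Adds 0/1 codes (sex: F=0, M=1; group: term=0, preterm=1).
    PMA should equal GA + PNA within 0.5 wk (warning, not an error).
    """
    required = ["subject", "ga_weeks", "pna_weeks", "pma_weeks", "sex", "group", "mean_fd"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    t = table.copy()
    if ((t.ga_weeks < 22) | (t.ga_weeks > 45)).any():
        raise ValueError("gestational age outside plausible range [22, 45] weeks")
    if (t.pna_weeks < 0).any():
        raise ValueError("negative postnatal age")
    gap = (t.pma_weeks - (t.ga_weeks + t.pna_weeks)).abs()
    if (gap > 0.5).any():
        import warnings

        warnings.warn("PMA differs from GA + PNA by more than 0.5 weeks for some rows")
    t["sex_code"] = t.sex.map({"F": 0, "M": 1, 0: 0, 1: 1}).astype(float)
    t["group_code"] = t.group.map({"term": 0, "preterm": 1, 0: 0, 1: 1}).astype(float)
    if t.sex_code.isna().any() or t.group_code.isna().any():
        raise ValueError("sex must be M/F and group must be term/preterm")
    return t


def select_subgroup(table: pd.DataFrame, model: str,
                    ga_target: float = 40.0, ga_tol: float = 0.5,
                    pna_max: float = 1.0) -> pd.DataFrame:
    """Row filter mirroring the three analysis designs.

    ``ga``: term infants scanned within ``pna_max`` weeks of birth;
    ``pna``: term infants with GA in [ga_target - ga_tol, ga_target + ga_tol);
    ``group``: all rows (a pre-matched preterm/term table is expected).
    """
    t = validate_cohort(table)
    if model == "ga":
        return t[(t.group_code == 0) & (t.pna_weeks < pna_max)]
    if model == "pna":
        return t[(t.group_code == 0)
                 & (t.ga_weeks >= ga_target - ga_tol)
                 & (t.ga_weeks < ga_target + ga_tol)]
    if model == "group":
        return t
    raise ValueError(f"unknown model {model!r}")


def fit_glm(y: np.ndarray, design: pd.DataFrame, model: str = "ga") -> GLMResult:
    """OLS of one outcome on the design for the given model family.

    ``design`` is a validated cohort table (see :func:`validate_cohort`);
    the effect of interest is the first regressor after the intercept.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {sorted(MODELS)}")
    t = design if "sex_code" in design.columns else validate_cohort(design)
    interest, covars = MODELS[model]
    cols = [interest] + covars
    X = t[cols].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome and design row counts differ")
    n, p = X.shape[0], X.shape[1] + 1
    if n <= p:
        raise ValueError(f"n={n} too small for {p} regressors")
    Xd = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        sds = Xd.std(axis=0)
        bad = [cols[j - 1] for j in range(1, Xd.shape[1]) if sds[j] == 0]
        raise ValueError(f"collinear design (suspect columns: {bad or cols})")
    fit = sm.OLS(y, Xd).fit()
    return GLMResult(
        model=model,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        df=int(fit.df_resid),
        n=n,
        all_betas=np.asarray(fit.params),
    )


def fwe_correct(
    p: np.ndarray,
    alpha: float = 0.05,
    method: str = "bonferroni",
    t_values: np.ndarray | None = None,
    null_t: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Family-wise error correction: adjusted p-values and significance mask.

    ``bonferroni`` (default): p_adj = min(1, m*p).  ``maxt``: permutation
    max-T — requires ``t_values`` (m observed statistics) and ``null_t``
    (n_perm x m statistics under subject-label permutation); adjusted
    p = P(max_j |T_null_j| >= |t_obs|).
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        p_adj = np.minimum(1.0, p * p.size)
    elif method == "maxt":
        if t_values is None or null_t is None:
            raise ValueError("max-T correction needs t_values and null_t")
        maxima = np.abs(np.asarray(null_t)).max(axis=1)
        p_adj = np.array([
            (np.sum(maxima >= abs(t)) + 1) / (maxima.size + 1) for t in t_values
        ])
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    return p_adj, p_adj < alpha


def effect_sizes(t: float, n1: int, n2: int) -> EffectSize:
    """Cohen's d and effect-size r from a two-group GLM t statistic.

    d = 2t / sqrt(df) with df = n1 + n2 - 2 (signed like t);
    r = |d| / sqrt(d^2 + 4) (reported unsigned, as is conventional).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    df = n1 + n2 - 2
    d = 2.0 * t / np.sqrt(df)
    r = abs(d) / np.sqrt(d * d + 4.0)
    return EffectSize(cohens_d=float(d), effect_r=float(r))


def run_analysis(
    cohort: pd.DataFrame,
    outcomes: dict[str, np.ndarray],
    model: str = "ga",
    level_labels: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
    fwe_method: str = "bonferroni",
    **subgroup_kw,
) -> pd.DataFrame:
    """Run one GLM family over outcome arrays at one or more levels.

    ``outcomes`` maps a level name ('whole', 'network', 'edge', or any
    outcome family such as a state metric) to an (n_subjects,) or
    (n_subjects, m) array aligned with the cohort rows.  The subgroup
    filter for the model family is applied to cohort and outcomes alike;
    FWE correction runs within each level's family of m tests.

    Returns a tidy results table with columns outcome, unit, beta, t, p,
    p_fwe, significant, d, r, n, df.
    """
    t = select_subgroup(cohort, model, **subgroup_kw)
    if len(t) < 8:
        raise ValueError(f"subgroup for model {model!r} has only {len(t)} subjects")
    idx = t.index.to_numpy()
    n1 = int((t.group_code == 1).sum())
    n0 = int((t.group_code == 0).sum())
    rows = []
    for level, arr in outcomes.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        sub = arr[idx]
        labels = (level_labels or {}).get(level) or [
            f"{level}{'' if arr.shape[1] == 1 else f'_{j}'}" for j in range(arr.shape[1])
        ]
        results = [fit_glm(sub[:, j], t, model) for j in range(sub.shape[1])]
        p_adj, sig = fwe_correct(np.array([r.p for r in results]),
                                 alpha=alpha, method=fwe_method)
        for j, res in enumerate(results):
            if model == "group" and n1 >= 2 and n0 >= 2:
                es = effect_sizes(res.t, n1, n0)
                d, r = es.cohens_d, es.effect_r
            else:
                d = r = np.nan
            rows.append({
                "level": level, "outcome": labels[j], "beta": res.beta,
                "t": res.t, "p": res.p, "p_fwe": p_adj[j],
                "significant": bool(sig[j]), "d": d, "r": r,
                "n": res.n, "df": res.df,
            })
    return pd.DataFrame(rows)
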