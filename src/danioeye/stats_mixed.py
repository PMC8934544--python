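"""Repeated-measures statistics for paired-eye cohort data.

Both eyes of one fish are correlated; the genotype effect on a per-eye
metric is therefore estimated with a linear mixed model with a random
intercept per fish, which for two eyes per fish induces exactly the
compound-symmetry covariance structure (equal variance, equal within-fish
covariance), fitted by restricted maximum likelihood (REML).

For a perfectly balanced table (every fish contributing both eyes) the REML
variance components have a closed form — the classic ANOVA estimators — and
the GLS genotype effect reduces to ordinary least squares on the per-fish
eye means; that exact path is used whenever the data allow, with
``statsmodels`` MixedLM as the general fallback.  The fixed-effect p value
uses a t reference distribution on between-fish degrees of freedom
(n_fish − n_genotypes), the conservative choice matching the
repeated-measures structure.

Per-fish metrics (optokinetic gain, ETM counts, body length) are compared
with Welch's heteroscedastic ANOVA instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Significance star mapping used in effect tables.
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class MixedFit:
    """Genotype effect from the compound-symmetry mixed model."""

    effect_size: float
    se: float
    p_value: float
    sigma_fish_sq: float
    sigma_eye_sq: float
    icc: float
    n_fish: int
    n_eyes: int
    converged: bool
    df: float
    genotype: str
    reference: str
    metric: str


@dataclass
class WelchResult:
    F: float
    df1: float
    df2: float
    p_value: float


@dataclass
class PowerResult:
    power: float
    mc_se: float
    n_reps: int


def _extract_metric(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    cols = {"fish_id", "eye", "genotype", "value"}
    if "metric_name" in table.columns:
        df = table[table["metric_name"] == metric].copy()
    elif metric in table.columns:
        df = table[["fish_id", "eye", "genotype", metric]].rename(columns={metric: "value"})
    else:
        raise KeyError(f"metric {metric!r} not found in table")
    missing = cols - set(df.columns)
    if missing:
        raise KeyError(f"table lacks columns {sorted(missing)}")
    if df["genotype"].astype(str).str.len().eq(0).any():
        raise ValueError("empty genotype labels")
    eyes_per_fish = df.groupby("fish_id")["eye"].nunique()
    if (df.groupby(["fish_id", "eye"]).size() > 1).any():
        raise ValueError("more than one value per fish/eye for this metric")
    if (eyes_per_fish > 2).any():
        raise ValueError("more than 2 eyes per fish")
    return df.dropna(subset=["value"])


def _balanced_cs_fit(df: pd.DataFrame, genotype: str, reference: str, metric: str) -> MixedFit:
    # Closed-form REML/GLS for the balanced two-eye design: the eye
    # difference within each fish estimates the residual variance, and the
    # genotype contrast is OLS on fish means.
    wide = df.pivot_table(index=["fish_id", "genotype"], columns="eye",
                          values="value", aggfunc="first")
    wide = wide.reset_index()
    eye_cols = [c for c in wide.columns if c not in ("fish_id", "genotype")]
    diffs = wide[eye_cols[0]] - wide[eye_cols[1]]
    means = wide[eye_cols].mean(axis=1)
    n_fish = len(wide)
    genos = wide["genotype"]
    n_groups = genos.nunique()

    sigma_eye_sq = float(np.sum(diffs**2) / (2.0 * n_fish))
    group_means = means.groupby(genos).transform("mean")
    sse = float(np.sum((means - group_means) ** 2))
    df_resid = n_fish - n_groups
    s_m_sq = sse / df_resid if df_resid > 0 else 0.0  # var of fish means
    sigma_fish_sq = max(0.0, s_m_sq - sigma_eye_sq / 2.0)

    m_g = float(means[genos == genotype].mean())
    m_ref = float(means[genos == reference].mean())
    n_g = int((genos == genotype).sum())
    n_ref = int((genos == reference).sum())
    effect = m_g - m_ref
    se = float(np.sqrt(s_m_sq * (1.0 / n_g + 1.0 / n_ref)))
    if se == 0.0:
        p = 1.0 if effect == 0.0 else 0.0
    else:
        t = effect / se
        p = float(2.0 * sps.t.sf(abs(t), df_resid))
    total = sigma_fish_sq + sigma_eye_sq
    return MixedFit(
        effect_size=effect, se=se, p_value=p,
        sigma_fish_sq=sigma_fish_sq, sigma_eye_sq=sigma_eye_sq,
        icc=sigma_fish_sq / total if total > 0 else 0.0,
        n_fish=n_fish, n_eyes=int(len(df)), converged=True,
        df=float(df_resid), genotype=genotype, reference=reference, metric=metric,
    )


def _mixedlm_fit(df: pd.DataFrame, genotype: str, reference: str, metric: str) -> MixedFit:
    import statsmodels.formula.api as smf

    data = df.copy()
    data["genotype"] = pd.Categorical(
        data["genotype"],
        categories=[reference] + sorted(set(data["genotype"]) - {reference}),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(genotype)", data, groups=data["fish_id"])
        result = model.fit(reml=True)
    term = f"C(genotype)[T.{genotype}]"
    effect = float(result.params[term])
    se = float(result.bse[term])
    sigma_fish_sq = float(np.asarray(result.cov_re)[0, 0])
    sigma_eye_sq = float(result.scale)
    n_fish = data["fish_id"].nunique()
    n_groups = data["genotype"].nunique()
    df_resid = max(1, n_fish - n_groups)
    p = float(2.0 * sps.t.sf(abs(effect / se), df_resid)) if se > 0 else 1.0
    total = sigma_fish_sq + sigma_eye_sq
    return MixedFit(
        effect_size=effect, se=se, p_value=p,
        sigma_fish_sq=max(0.0, sigma_fish_sq), sigma_eye_sq=sigma_eye_sq,
        icc=sigma_fish_sq / total if total > 0 else 0.0,
        n_fish=n_fish, n_eyes=int(len(data)),
        converged=bool(getattr(result, "converged", True)),
        df=float(df_resid), genotype=genotype, reference=reference, metric=metric,
    )


def fit_cs_mixed(
    table: pd.DataFrame,
    metric: str,
    reference: str,
    genotype: str | None = None,
) -> MixedFit:
    """Genotype effect on a per-eye metric under the compound-symmetry model.

    Parameters
    ----------
    table
        Long-format measurement table with columns fish_id, eye, genotype
        and either a ``metric_name``/``value`` pair or ``metric`` as a
        column.
    metric
        Which metric to analyze.
    reference
        Reference genotype (effects are coefficients relative to it).
    genotype
        Genotype whose coefficient to report; may be omitted when exactly
        one non-reference genotype is present.
    """
    df = _extract_metric(table, metric)
    genos = sorted(df["genotype"].unique())
    if reference not in genos:
        raise ValueError(f"reference genotype {reference!r} not present in {genos}")
    if len(genos) < 2:
        raise ValueError("need at least 2 genotypes")
    others = [g for g in genos if g != reference]
    if genotype is None:
        if len(others) > 1:
            raise ValueError(f"genotype to report is ambiguous among {others}")
        genotype = others[0]
    elif genotype not in others:
        raise ValueError(f"genotype {genotype!r} not present (have {others})")
    fish_per_geno = df.groupby("genotype")["fish_id"].nunique()
    if (fish_per_geno < 3).any():
        raise ValueError("need at least 3 fish per genotype")

    if df["value"].nunique() == 1:
        n_fish = df["fish_id"].nunique()
        return MixedFit(
            effect_size=0.0, se=0.0, p_value=1.0, sigma_fish_sq=0.0,
            sigma_eye_sq=0.0, icc=0.0, n_fish=n_fish, n_eyes=len(df),
            converged=True, df=float(n_fish - len(genos)),
            genotype=genotype, reference=reference, metric=metric,
        )

    balanced = (df.groupby("fish_id")["eye"].nunique() == 2).all()
    if balanced:
        return _balanced_cs_fit(df, genotype, reference, metric)
    return _mixedlm_fit(df, genotype, reference, metric)


def welch_anova(groups: list) -> WelchResult:
    """Welch's heteroscedastic one-way ANOVA.

    Welch's F statistic with Welch–Satterthwaite denominator degrees of
    freedom; robust to unequal group variances (used for per-fish OKR
    metrics and body length)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
        if np.var(g, ddof=1) == 0:
            raise ValueError("a group has zero variance; Welch weights are undefined")
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    w_sum = w.sum()
    m_w = float((w * m).sum() / w_sum)
    a = float((w * (m - m_w) ** 2).sum()) / (k - 1)
    lam = float((((1.0 - w / w_sum) ** 2) / (n - 1.0)).sum())
    b = 1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * lam
    F = a / b
    df1 = float(k - 1)
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(F, df1, df2))
    return WelchResult(F=float(F), df1=df1, df2=df2, p_value=p)


def size_match_filter(
    table: pd.DataFrame,
    reference: str,
    tolerance: float = 0.01,
) -> tuple[bool, pd.DataFrame]:
    """Body-length matching rule: each mutant genotype's mean body length
    must lie within ``tolerance`` (default 1%, inclusive) of the reference
    genotype's mean.

    ``table`` needs columns fish_id, genotype, body_length (per-eye rows are
    collapsed to one row per fish).  Returns (all passed, per-genotype
    report).
    """
    if "body_length" not in table.columns:
        raise KeyError("table lacks body_length")
    per_fish = table.groupby(["fish_id", "genotype"], as_index=False)["body_length"].mean()
    if reference not in set(per_fish["genotype"]):
        raise ValueError(f"reference genotype {reference!r} missing")
    ref_mean = float(per_fish.loc[per_fish["genotype"] == reference, "body_length"].mean())
    rows = []
    for genotype, group in per_fish.groupby("genotype"):
        if genotype == reference:
            continue
        mean = float(group["body_length"].mean())
        rel = abs(mean - ref_mean) / ref_mean
        rows.append({
            "genotype": genotype,
            "mean_body_length": mean,
            "reference_mean": ref_mean,
            "relative_difference": rel,
            "passed": bool(rel <= tolerance * (1.0 + 1e-9)),  # inclusive bound
        })
    report = pd.DataFrame(rows)
    return bool(report["passed"].all()) if len(report) else True, report


def power_sim(
    effect: float,
    sigma_fish: float,
    sigma_eye: float,
    n_fish_per_group: int = 10,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> PowerResult:
    """Monte-Carlo power of the compound-symmetry design (two eyes/fish,
    two genotypes, ``n_fish_per_group`` fish each) to detect ``effect``.

    Simulates cohorts under the random-intercept model, applies the balanced
    closed-form fit, and reports the fraction of replicates with
    p < ``alpha`` together with the binomial Monte-Carlo standard error.
    """
    if sigma_fish <= 0 or sigma_eye <= 0:
        raise ValueError("variance components must be positive")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    n = n_fish_per_group
    # (reps, group, fish): fish means already averaged over the two eyes
    fish_means = (
        rng.normal(0.0, sigma_fish, size=(n_reps, 2, n))
        + rng.normal(0.0, sigma_eye, size=(n_reps, 2, n, 2)).mean(axis=3)
    )
    fish_means[:, 1, :] += effect
    gm = fish_means.mean(axis=2, keepdims=True)
    sse = ((fish_means - gm) ** 2).sum(axis=(1, 2))
    df_resid = 2 * n - 2
    s_m_sq = sse / df_resid
    diff = fish_means[:, 1].mean(axis=1) - fish_means[:, 0].mean(axis=1)
    se = np.sqrt(s_m_sq * (2.0 / n))
    t = np.divide(diff, se, out=np.zeros_like(diff), where=se > 0)
    p = 2.0 * sps.t.sf(np.abs(t), df_resid)
    power = float(np.mean(p < alpha))
    return PowerResult(
        power=power,
        mc_se=float(np.sqrt(power * (1.0 - power) / n_reps)),
        n_reps=n_reps,
    )
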