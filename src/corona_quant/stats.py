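"""Statistical layer: control normalization, nested and repeated-measures
ANOVA with Dunnett many-to-one comparisons, and flow-cytometry gating.

The two ANOVA designs mirror the study's imaging and plate-reader analyses:

* *Nested one-way ANOVA*: condition is a fixed factor; technical sub-values
  are nested within biological replicates, which form the error stratum.  The
  omnibus F is MS(condition) / MS(replicate-within-condition); equivalently
  (for balanced sub-counts) a one-way ANOVA on biological-replicate means,
  which is also how unbalanced designs are handled.
* *Repeated-measures one-way ANOVA* with the Geisser-Greenhouse correction:
  complete blocks (every condition in every biological replicate); the
  epsilon from the double-centered sample covariance deflates the F degrees
  of freedom.

Dunnett adjusted p values come from a Monte-Carlo reference distribution of
max|T| over the many-to-one contrasts in the group-means model (shared
chi-square scale, 200k draws, fixed internal seed, cached per design), per
the documented design choice that exact quadrature is not required at the
working alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "AnovaResult",
    "DunnettReference",
    "dunnett_reference",
    "normalize_to_control",
    "nested_anova_dunnett",
    "rm_anova_gg_dunnett",
    "FlowGateResult",
    "flow_gate",
]

_DUNNETT_DRAWS = 200_000
_DUNNETT_SEED = 1969  # fixed: the reference distribution is part of the method


@dataclass
class ComparisonResult:
    condition: str
    estimate: float  # difference vs control
    t_statistic: float
    unadjusted_p: float
    adjusted_p: float
    significant: bool  # at alpha = 0.05


@dataclass
class AnovaResult:
    f_statistic: float
    df_num: float
    df_den: float
    p_value: float
    ms_error: float
    comparisons: list[ComparisonResult] = field(default_factory=list)
    gg_epsilon: float | None = None


class DunnettReference:
    """Monte-Carlo null distribution of max|T| for many-to-one comparisons.

    Simulates group means X_i ~ N(0, 1/n_i) for the control and each
    treatment, a shared scale S^2 ~ chi2(df)/df, and the statistics
    T_i = (X_i - X_0) / (S * sqrt(1/n_i + 1/n_0)).  Stores the sorted draws
    of max_i |T_i|; adjusted p and critical values are read off empirically.
    """

    def __init__(
        self,
        n_treat: tuple[int, ...],
        n_control: int,
        df: int,
        n_draws: int = _DUNNETT_DRAWS,
        seed: int = _DUNNETT_SEED,
    ):
        rng = np.random.default_rng(seed)
        k = len(n_treat)
        z0 = rng.normal(0, 1, n_draws) / np.sqrt(n_control)
        zi = rng.normal(0, 1, (n_draws, k)) / np.sqrt(np.asarray(n_treat, float))
        s = np.sqrt(rng.chisquare(df, n_draws) / df)
        se = np.sqrt(1.0 / np.asarray(n_treat, float) + 1.0 / n_control)
        t = (zi - z0[:, None]) / (s[:, None] * se)
        self.max_abs_t = np.sort(np.abs(t).max(axis=1))
        self.n_draws = n_draws

    def adjusted_p(self, t: float) -> float:
        """P(max|T| >= |t|) under the joint null, floored at 1/(draws+1)."""
        exceed = self.n_draws - np.searchsorted(self.max_abs_t, abs(t), side="left")
        return max(float(exceed) / self.n_draws, 1.0 / (self.n_draws + 1))

    def critical_value(self, alpha: float = 0.05) -> float:
        return float(np.quantile(self.max_abs_t, 1.0 - alpha))


_reference_cache: dict[tuple, DunnettReference] = {}


def dunnett_reference(n_treat, n_control: int, df: int) -> DunnettReference:
    """Cached Monte-Carlo reference for a (treatment sizes, control size, df)."""
    key = (tuple(int(n) for n in n_treat), int(n_control), int(df))
    if key not in _reference_cache:
        _reference_cache[key] = DunnettReference(*key)
    return _reference_cache[key]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_to_control(
    table: pd.DataFrame,
    control_condition: str,
    value_col: str = "value",
) -> pd.DataFrame:
    """Divide each value by the mean control value of its biological replicate.

    This is the plate-reader normalization: every measurement is expressed
    relative to the average no-corona control of the same biological
    replicate, so the control's per-replicate mean maps to 1.
    """
    out = table.copy()
    control = table[table["condition"] == control_condition]
    if control.empty:
        raise ValueError(f"control condition {control_condition!r} absent")
    means = control.groupby("biological_replicate")[value_col].mean()
    if (means == 0).any():
        raise ValueError("zero control mean in at least one biological replicate")
    missing = set(out["biological_replicate"]) - set(means.index)
    if missing:
        raise ValueError(f"no control values for biological replicates: {sorted(missing)}")
    out[value_col] = out[value_col] / out["biological_replicate"].map(means)
    return out


# ---------------------------------------------------------------------------
# nested ANOVA + Dunnett
# ---------------------------------------------------------------------------

def _rep_means(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    return (
        table.groupby(["condition", "biological_replicate"], sort=False)[value_col]
        .mean()
        .reset_index()
    )


def nested_anova_dunnett(
    table: pd.DataFrame,
    control: str,
    value_col: str = "value",
    alpha: float = 0.05,
) -> AnovaResult:
    """Nested one-way ANOVA with Dunnett many-to-one comparisons.

    Technical sub-values are first averaged within each biological replicate;
    the replicate means are the error units (for balanced sub-counts this
    yields exactly the classical nested F = MS_condition / MS_rep(condition)).
    Conditions with fewer than two biological replicates are excluded with a
    warning.  Dunnett comparisons use the replicate-stratum mean square and
    its degrees of freedom.
    """
    if control not in set(table["condition"]):
        raise ValueError(f"control condition {control!r} absent")
    means = _rep_means(table, value_col)
    sizes = means.groupby("condition", sort=False).size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        if control in small:
            raise ValueError("control condition has fewer than 2 biological replicates")
        warnings.warn(
            f"excluded conditions with <2 biological replicates: {small}", stacklevel=2
        )
        means = means[~means["condition"].isin(small)]
        sizes = sizes.drop(small)

    groups = {c: g[value_col].to_numpy() for c, g in means.groupby("condition", sort=False)}
    conditions = list(groups)
    k = len(conditions)
    if k < 2:
        raise ValueError("need at least two conditions")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ns = np.array([len(groups[c]) for c in conditions])
    gmeans = np.array([groups[c].mean() for c in conditions])
    ss_between = float((ns * (gmeans - grand) ** 2).sum())
    ss_within = float(sum(((groups[c] - groups[c].mean()) ** 2).sum() for c in conditions))
    df_num = k - 1
    df_den = int(ns.sum()) - k
    if df_den < 1:
        raise ValueError("no residual degrees of freedom")
    ms_between = ss_between / df_num
    ms_error = ss_within / df_den
    f = ms_between / ms_error if ms_error > 0 else np.inf
    p = float(stats.f.sf(f, df_num, df_den))

    treatments = [c for c in conditions if c != control]
    n0 = len(groups[control])
    ref = dunnett_reference([len(groups[c]) for c in treatments], n0, df_den)
    comparisons = []
    for c in treatments:
        est = float(groups[c].mean() - groups[control].mean())
        se = np.sqrt(ms_error * (1.0 / len(groups[c]) + 1.0 / n0))
        t = est / se if se > 0 else np.inf
        p_unadj = 2.0 * float(stats.t.sf(abs(t), df_den))
        p_adj = ref.adjusted_p(t)
        comparisons.append(
            ComparisonResult(
                condition=c,
                estimate=est,
                t_statistic=float(t),
                unadjusted_p=min(p_unadj, 1.0),
                adjusted_p=p_adj,
                significant=p_adj < alpha,
            )
        )
    return AnovaResult(
        f_statistic=float(f),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        ms_error=ms_error,
        comparisons=comparisons,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA + GG + Dunnett
# ---------------------------------------------------------------------------

def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = data.shape[1]
    if k == 2:
        return 1.0
    cov = np.cov(data, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    s = c @ cov @ c
    num = np.trace(s) ** 2
    den = (k - 1) * float((s * s).sum())
    if den == 0:
        return 1.0
    return float(min(max(num / den, 1.0 / (k - 1)), 1.0))


def rm_anova_gg_dunnett(
    table: pd.DataFrame,
    control: str,
    value_col: str = "value",
    alpha: float = 0.05,
) -> AnovaResult:
    """Repeated-measures one-way ANOVA (Geisser-Greenhouse) with Dunnett.

    Requires complete blocks: every condition measured in every biological
    replicate (technical replicates, if present, are averaged first).  The
    omnibus F degrees of freedom are multiplied by the GG epsilon; Dunnett
    comparisons of condition means against the control use the within-
    replicate error mean square with (n-1)(k-1) degrees of freedom.
    """
    means = _rep_means(table, value_col)
    wide = means.pivot(index="biological_replicate", columns="condition", values=value_col)
    if wide.isna().any().any():
        missing = [
            f"{b}:{c}" for b, row in wide.iterrows() for c in wide.columns if pd.isna(row[c])
        ]
        raise ValueError(f"incomplete blocks; missing cells: {missing}")
    if control not in wide.columns:
        raise ValueError(f"control condition {control!r} absent")
    data = wide.to_numpy(dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 biological replicates and >= 2 conditions")

    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_tot = float(((data - grand) ** 2).sum())
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    f = (ss_cond / df_cond) / ms_err if ms_err > 0 else np.inf
    eps = _gg_epsilon(data)
    p = float(stats.f.sf(f, eps * df_cond, eps * df_err))

    conditions = list(wide.columns)
    treatments = [c for c in conditions if c != control]
    ref = dunnett_reference([n] * len(treatments), n, df_err)
    ctrl_mean = float(wide[control].mean())
    comparisons = []
    for c in treatments:
        est = float(wide[c].mean()) - ctrl_mean
        se = np.sqrt(2.0 * ms_err / n)
        t = est / se if se > 0 else np.inf
        p_unadj = 2.0 * float(stats.t.sf(abs(t), df_err))
        p_adj = ref.adjusted_p(t)
        comparisons.append(
            ComparisonResult(
                condition=c,
                estimate=est,
                t_statistic=float(t),
                unadjusted_p=min(p_unadj, 1.0),
                adjusted_p=p_adj,
                significant=p_adj < alpha,
            )
        )
    return AnovaResult(
        f_statistic=float(f),
        df_num=df_cond,
        df_den=df_err,
        p_value=p,
        ms_error=ms_err,
        comparisons=comparisons,
        gg_epsilon=eps,
    )


# ---------------------------------------------------------------------------
# flow gating
# ---------------------------------------------------------------------------

@dataclass
class FlowGateResult:
    gate_threshold: float
    pct_positive: float
    mfi: float  # mean fluorescence intensity over all sample events
    mfi_gated: float  # mean over events above the gate (NaN if none)


def flow_gate(
    control_events: np.ndarray,
    sample_events: np.ndarray,
    gate_quantile: float = 0.995,
) -> FlowGateResult:
    """Percent-positive and MFI with the gate set from non-treated cells.

    The positive gate is the ``gate_quantile`` quantile of the control; by
    construction a sample identical in distribution to the control reads
    (1 - gate_quantile) * 100 percent positive.
    """
    control = np.asarray(control_events, dtype=float)
    sample = np.asarray(sample_events, dtype=float)
    if control.size < 1000 or sample.size < 1000:
        raise ValueError("need >= 1000 events per sample")
    if not 0 < gate_quantile < 1:
        raise ValueError("gate_quantile must be in (0, 1)")
    thr = float(np.quantile(control, gate_quantile))
    positive = sample > thr
    return FlowGateResult(
        gate_threshold=thr,
        pct_positive=100.0 * float(positive.mean()),
        mfi=float(sample.mean()),
        mfi_gated=float(sample[positive].mean()) if positive.any() else float("nan"),
    )
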