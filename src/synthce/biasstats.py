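"""Agreement and bias statistics between predicted and reference intensities.

For each subject, method, ROI and phase the analysis works on the
Bland-Altman coordinates: the mean of predicted and ground-truth ROI
intensities (I_bar) against their difference (delta_I, predicted minus
truth).  Ordinary least squares of delta_I on I_bar distinguishes a constant
bias (significant intercept, non-significant slope) from a proportional one
(significant slope); 95% limits of agreement are +-1.96 SD of the residuals
about the fitted bias model.  Methods are compared with an ANCOVA (general
linear model with the intensity covariate), pairwise contrasts on adjusted
means, Bonferroni control, percentile bootstrap confidence intervals and
nonparametric omnibus/pairwise rank tests.

Exposed statsmodels-style: ``BlandAltman(records).fit()`` and
``AncovaComparison(records).fit()`` return results objects with a
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeans", "BiasResult", "BlandAltman", "bland_altman",
    "Contrast", "AncovaResult", "AncovaComparison", "ancova_compare",
    "bootstrap_ci", "omnibus_and_pairwise", "bonferroni",
]

_SLOPE_TOL = 1e-10


@dataclass(frozen=True)
class PairedMeans:
    """One subject's Bland-Altman point for a (method, roi, phase) cell."""
    subject_id: str
    i_bar: float
    delta_i: float
    method: str = ""
    roi: str = ""
    phase: int = 1

    def __post_init__(self):
        if not (np.isfinite(self.i_bar) and np.isfinite(self.delta_i)):
            raise ValueError("non-finite paired means")

    @classmethod
    def from_values(cls, subject_id: str, predicted: float, truth: float,
                    **kw) -> "PairedMeans":
        return cls(subject_id=subject_id, i_bar=(predicted + truth) / 2.0,
                   delta_i=predicted - truth, **kw)


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([{
        "subject_id": r.subject_id, "i_bar": r.i_bar, "delta_i": r.delta_i,
        "method": r.method, "roi": r.roi, "phase": r.phase,
    } for r in records])


def _t_pvalue(est: float, se: float, dof: int) -> float:
    """Two-tailed t-test p-value with degenerate-SE guards: a zero standard
    error means the data determine the coefficient exactly."""
    if se < _SLOPE_TOL:
        return 0.0 if abs(est) > _SLOPE_TOL else 1.0
    return float(2.0 * stats.t.sf(abs(est) / se, dof))


@dataclass
class BiasResult:
    mean_bias: float
    loa_half_width: float
    slope: float
    intercept: float
    slope_p: float
    intercept_p: float
    classification: str
    n: int
    alpha: float
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def summary(self) -> str:
        return (
            f"Bland-Altman bias analysis (n={self.n})\n"
            f"  mean bias          {self.mean_bias: .2f} HU\n"
            f"  95% LoA            [+-{self.loa_half_width:.2f}] HU\n"
            f"  slope              {self.slope: .3f} (p={self.slope_p:.4g})\n"
            f"  intercept          {self.intercept: .2f} (p={self.intercept_p:.4g})\n"
            f"  classification     {self.classification}\n"
        )

    def cell(self) -> str:
        """'mean bias [+- LoA] (slope)' table cell."""
        return (f"{self.mean_bias:.0f} [+-{self.loa_half_width:.0f}] "
                f"({self.slope:.2f})")


class BlandAltman:
    """Bland-Altman agreement model for one (method, roi, phase) cell.

    Parameters
    ----------
    records : list of PairedMeans or tidy DataFrame with i_bar / delta_i.
    loa_about_line : when True (default) the limits of agreement are taken
        about the fitted regression line (appropriate when proportional bias
        is present); when False, about the constant mean bias.
    """

    def __init__(self, records, loa_about_line: bool = True):
        self.frame = _to_frame(records)
        self.loa_about_line = loa_about_line
        if len(self.frame) < 3:
            raise ValueError("Bland-Altman regression needs >= 3 records")

    def fit(self, alpha: float = 0.05) -> BiasResult:
        ibar = self.frame["i_bar"].to_numpy(dtype=np.float64)
        delta = self.frame["delta_i"].to_numpy(dtype=np.float64)
        n = len(delta)
        mean_bias = float(delta.mean())
        if np.ptp(ibar) < _SLOPE_TOL:
            # zero covariate variance: slope undefined, constant-bias-only
            resid = delta - mean_bias
            sd = float(resid.std(ddof=1))
            se = sd / np.sqrt(n)
            p_int = _t_pvalue(mean_bias, se, n - 1)
            return BiasResult(
                mean_bias=mean_bias, loa_half_width=1.96 * sd,
                slope=float("nan"), intercept=mean_bias,
                slope_p=float("nan"), intercept_p=p_int,
                classification="constant" if p_int < alpha else "none",
                n=n, alpha=alpha, intercept_se=se)
        x = np.column_stack([np.ones(n), ibar])
        beta, *_ = np.linalg.lstsq(x, delta, rcond=None)
        resid = delta - x @ beta
        dof = n - 2
        sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = sigma2 * np.linalg.inv(x.T @ x)
        se = np.sqrt(np.diag(cov))
        p_int = _t_pvalue(beta[0], se[0], dof)
        p_slope = _t_pvalue(beta[1], se[1], dof)
        if p_slope < alpha:
            classification = "proportional"
        elif p_int < alpha:
            classification = "constant"
        else:
            classification = "none"
        spread = resid if self.loa_about_line else delta - mean_bias
        sd = float(spread.std(ddof=1)) if n > 1 else 0.0
        return BiasResult(
            mean_bias=mean_bias, loa_half_width=1.96 * sd,
            slope=float(beta[1]), intercept=float(beta[0]),
            slope_p=p_slope, intercept_p=p_int,
            classification=classification, n=n, alpha=alpha,
            slope_se=float(se[1]), intercept_se=float(se[0]))


def bland_altman(records, alpha: float = 0.05,
                 loa_about_line: bool = True) -> BiasResult:
    return BlandAltman(records, loa_about_line=loa_about_line).fit(alpha=alpha)


@dataclass(frozen=True)
class Contrast:
    """Covariate-adjusted mean-bias difference between two methods."""
    method_a: str
    method_b: str
    estimate: float
    se: float
    p_adj: float


@dataclass
class AncovaResult:
    interaction_p: float
    method_p: float
    pairwise: list[Contrast]
    methods: list[str]
    params: dict = field(default_factory=dict)
    n: int = 0

    def summary(self) -> str:
        lines = [
            f"ANCOVA method comparison (n={self.n}, "
            f"methods={', '.join(self.methods)})",
            f"  interaction (equal slopes) p = {self.interaction_p:.4g}",
            f"  method effect p             = {self.method_p:.4g}",
            "  pairwise contrasts (Bonferroni-adjusted):",
        ]
        for c in self.pairwise:
            lines.append(f"    {c.method_b} - {c.method_a}: "
                         f"{c.estimate: .2f} HU (p={c.p_adj:.4g})")
        return "\n".join(lines) + "\n"


class AncovaComparison:
    """General linear model comparing mean biases between methods while
    controlling for the intensity covariate I_bar."""

    def __init__(self, records):
        self.frame = _to_frame(records)
        counts = self.frame.groupby("method").size()
        if len(counts) < 2:
            raise ValueError("ANCOVA needs >= 2 methods")
        if (counts < 3).any():
            raise ValueError("every method needs >= 3 records")

    def fit(self, alpha: float = 0.05) -> AncovaResult:
        import statsmodels.formula.api as smf

        df = self.frame.copy()
        methods = sorted(df["method"].unique())
        full = smf.ols("delta_i ~ i_bar * C(method)", data=df).fit()
        inter_terms = [t for t in full.params.index if ":" in t]
        interaction_p = float(np.squeeze(
            full.f_test([f"{t} = 0" for t in inter_terms]).pvalue))
        add = smf.ols("delta_i ~ i_bar + C(method)", data=df).fit()
        meth_terms = [t for t in add.params.index if t.startswith("C(method)")]
        method_p = float(np.squeeze(
            add.f_test([f"{t} = 0" for t in meth_terms]).pvalue))
        # pairwise contrasts on covariate-adjusted means: differences of the
        # method dummy coefficients in the additive model
        coef = {methods[0]: 0.0}
        names = {methods[0]: None}
        for m in methods[1:]:
            term = f"C(method)[T.{m}]"
            coef[m] = float(add.params[term])
            names[m] = term
        k = len(add.params)
        pairs = []
        raw = []
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                a, b = methods[i], methods[j]
                vec = np.zeros(k)
                idx = {t: q for q, t in enumerate(add.params.index)}
                if names[b] is not None:
                    vec[idx[names[b]]] += 1.0
                if names[a] is not None:
                    vec[idx[names[a]]] -= 1.0
                est = float(vec @ add.params.to_numpy())
                se = float(np.sqrt(vec @ add.cov_params().to_numpy() @ vec))
                p = _t_pvalue(est, se, int(add.df_resid))
                pairs.append((a, b, est, se))
                raw.append(p)
        adj = bonferroni(raw)
        pairwise = [Contrast(a, b, est, se, p)
                    for (a, b, est, se), p in zip(pairs, adj)]
        return AncovaResult(
            interaction_p=interaction_p, method_p=method_p,
            pairwise=pairwise, methods=methods,
            params={t: float(v) for t, v in add.params.items()},
            n=len(df))


def ancova_compare(records, alpha: float = 0.05) -> AncovaResult:
    return AncovaComparison(records).fit(alpha=alpha)


def bonferroni(pvalues) -> list[float]:
    """Multiply by the number of comparisons, capped at 1 (order-preserving)."""
    m = len(pvalues)
    return [min(1.0, float(p) * m) for p in pvalues]


def bootstrap_ci(samples, statistic=np.median, n_boot: int = 100_000,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for ``statistic``."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e7 // max(1, x.size))))
    pos = 0
    while pos < n_boot:
        take = min(chunk, n_boot - pos)
        idx = rng.integers(0, x.size, size=(take, x.size))
        reps[pos:pos + take] = np.apply_along_axis(statistic, 1, x[idx]) \
            if statistic is not np.median else np.median(x[idx], axis=1)
        pos += take
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(reps, lo)), float(np.quantile(reps, 1.0 - lo)))


def omnibus_and_pairwise(groups, alpha: float = 0.05,
                         use_t: bool = False) -> dict:
    """Kruskal-Wallis omnibus across groups plus two-tailed pairwise
    Mann-Whitney U tests with Bonferroni adjustment.  Normally distributed
    data may be routed to Welch t-tests with ``use_t=True``.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        h_p = 1.0
    elif use_t and len(groups) == 2:
        h_p = float(stats.ttest_ind(groups[0], groups[1], equal_var=False).pvalue)
    else:
        h_p = float(stats.kruskal(*groups).pvalue)
    raw = []
    labels = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            elif use_t:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            raw.append(p)
            labels.append((i, j))
    return {"h_p": h_p,
            "pairwise_u_p": dict(zip(labels, bonferroni(raw)))}
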