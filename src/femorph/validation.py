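"""Agreement statistics between Monte Carlo and traversal proportions.

Descriptive summaries (mean, SD, t-based 95% CI, min, max) of the four
per-slice proportion series and a classical one-way ANOVA between the
paired Monte Carlo / traversal series, with a verdict at the 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementDataset",
    "StatSummary",
    "AnovaResult",
    "describe",
    "one_way_anova",
    "agreement_report",
]

ALPHA = 0.05


@dataclass
class AgreementDataset:
    """Paired per-slice proportion series (MC vs traversal, medullary & cortical)."""

    alpha_mm: np.ndarray
    alpha_mt: np.ndarray
    alpha_cm: np.ndarray
    alpha_ct: np.ndarray

    def __post_init__(self):
        series = {}
        for name in ("alpha_mm", "alpha_mt", "alpha_cm", "alpha_ct"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} contains values outside [0, 1]")
            series[name] = arr
            setattr(self, name, arr)
        lengths = {a.size for a in series.values()}
        if len(lengths) != 1:
            raise ValueError(f"series length mismatch: {sorted(lengths)}")

    @property
    def n_layers(self) -> int:
        return int(self.alpha_mm.size)


@dataclass
class StatSummary:
    n: int
    mean: float
    sd: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    minimum: float
    maximum: float


@dataclass
class AnovaResult:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f: float
    p: float


def describe(series: Sequence[float]) -> StatSummary:
    """Sample mean, SD (n-1 denominator), t-based 95% CI, min, max.

    With fewer than two observations the CI is undefined (None bounds).
    """
    arr = np.asarray(series, dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("empty series")
    mean = float(arr.mean())
    if n < 2:
        return StatSummary(n, mean, float("nan"), None, None, mean, mean)
    sd = float(arr.std(ddof=1))
    half = stats.t.ppf(1 - ALPHA / 2, n - 1) * sd / np.sqrt(n)
    return StatSummary(
        n=n,
        mean=mean,
        sd=sd,
        ci_low=mean - half,
        ci_high=mean + half,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


def one_way_anova(group_a: Sequence[float], group_b: Sequence[float]) -> AnovaResult:
    """Classical one-way ANOVA between two groups (explicit decomposition).

    Degenerate case: zero within-group variance with equal group means gives
    F = 0, p = 1; zero within-group variance with different means gives
    F = inf, p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    grand = np.concatenate([a, b]).mean()
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    dfb = 1
    dfw = a.size + b.size - 2
    msb = ssb / dfb
    msw = ssw / dfw
    if msw == 0.0:
        f = 0.0 if msb == 0.0 else float("inf")
        p = 1.0 if msb == 0.0 else 0.0
    else:
        f = msb / msw
        p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(
        ss_between=float(ssb),
        ss_within=ssw,
        df_between=dfb,
        df_within=dfw,
        ms_between=float(msb),
        ms_within=msw,
        f=float(f),
        p=p,
    )


def agreement_report(dataset: AgreementDataset) -> Dict:
    """Per-series summaries, the two ANOVAs, per-slice differences, verdicts.

    The verdict is ``"no significant difference"`` when the ANOVA p-value
    exceeds the 0.05 significance level, else ``"significant difference"``.
    """
    summaries = {
        name: asdict(describe(getattr(dataset, name)))
        for name in ("alpha_mm", "alpha_mt", "alpha_cm", "alpha_ct")
    }
    anova_m = one_way_anova(dataset.alpha_mm, dataset.alpha_mt)
    anova_c = one_way_anova(dataset.alpha_cm, dataset.alpha_ct)
    diff_m = np.abs(dataset.alpha_mm - dataset.alpha_mt)
    diff_c = np.abs(dataset.alpha_cm - dataset.alpha_ct)

    def verdict(p: float) -> str:
        return "no significant difference" if p > ALPHA else "significant difference"

    return {
        "n_layers": dataset.n_layers,
        "summaries": summaries,
        "anova": {"medullary": asdict(anova_m), "cortical": asdict(anova_c)},
        "abs_difference": {
            "medullary": {"mean": float(diff_m.mean()), "max": float(diff_m.max())},
            "cortical": {"mean": float(diff_c.mean()), "max": float(diff_c.max())},
        },
        "verdict": {
            "medullary": verdict(anova_m.p),
            "cortical": verdict(anova_c.p),
        },
        "significance_level": ALPHA,
    }
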