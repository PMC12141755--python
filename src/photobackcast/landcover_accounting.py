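"""Composition, landscape diversity and paired change statistics.

Turns classified (and aligned) photograph pairs into per-category percent
compositions, Shannon diversity of the categorical landscape, and paired
Wilcoxon signed-rank change tests with bootstrap confidence intervals.

The Wilcoxon signed-rank test is implemented in-package: exact two-sided
p-values by enumeration of the null rank-sum distribution for small samples
without ties, a tie-corrected normal approximation with continuity correction
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from ._core import ClassifiedImage, CompositionVector, EmptyImageError, LandCoverScheme

__all__ = [
    "ChangeTest",
    "WilcoxonResult",
    "UndefinedTestError",
    "composition",
    "merge_categories",
    "shannon_index",
    "wilcoxon_signed_rank",
    "paired_change",
    "bootstrap_mean_ci",
]

SHANNON_KEY = "shannon"


class UndefinedTestError(ValueError):
    """Raised when every paired difference is zero (no test statistic exists)."""


@dataclass
class WilcoxonResult:
    statistic: float  # W = sum of positive-difference ranks
    p_value: float
    n: int  # non-zero differences used
    method: str  # "exact" or "approx"


@dataclass
class ChangeTest:
    """Paired before/after change summary for one category, Shannon, or species."""

    target: str
    n_pairs: int
    mean_before: float
    mean_after: float
    mean_change: float
    se_before: float
    se_after: float
    se_change: float
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    note: str = ""
    classification: str | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if np.isfinite(self.ci_low) and not (
            self.ci_low - 1e-9 <= self.mean_change <= self.ci_high + 1e-9
        ):
            raise ValueError("CI must bracket the mean change")


def composition(image: ClassifiedImage, scheme: LandCoverScheme) -> CompositionVector:
    """Percent of valid pixels per category; absent categories appear as 0."""
    mask = image.valid
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise EmptyImageError("image has no valid pixels")
    labels = image.labels[mask]
    known = set(scheme.ids)
    present = set(np.unique(labels).tolist())
    unknown = present - known
    if unknown:
        raise ValueError(f"valid pixels carry ids outside the scheme: {sorted(unknown)}")
    counts = np.bincount(labels.ravel(), minlength=max(known) + 1)
    values = {name: 100.0 * counts[i] / n_valid for i, name in scheme.categories}
    return CompositionVector(values=values, n_valid=n_valid)


def merge_categories(comp: CompositionVector, scheme: LandCoverScheme) -> CompositionVector:
    """Sum fine-category shares into the scheme's coarse categories."""
    name_map = scheme.merge_name_map()
    unmapped = set(comp.values) - set(name_map)
    if unmapped:
        raise ValueError(f"fine categories without a merge target: {sorted(unmapped)}")
    coarse_names = [n for _, n in scheme.merged_categories]  # type: ignore[union-attr]
    out = {n: 0.0 for n in coarse_names}
    for fine, v in comp.values.items():
        out[name_map[fine]] += v
    return CompositionVector(out, comp.n_valid, comp.truncation_fraction)


def shannon_index(comp: CompositionVector, base: float = np.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over categories with p_i > 0.

    Natural log by default (the convention of vegan's ``diversity``);
    pass ``base=2`` for bits.
    """
    p = np.array([v for v in comp.values.values() if v > 0.0]) / 100.0
    if p.size == 0:
        return 0.0
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base)


def _exact_rank_sum_sf_cdf(n: int, w: float) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) under the signed-rank null (integer ranks 1..n)."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=np.float64)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    total = counts.sum()  # 2**n
    wi = int(round(w))
    cdf = counts[: wi + 1].sum() / total
    sf = counts[wi:].sum() / total
    return cdf, sf


def wilcoxon_signed_rank(
    before: Sequence[float], after: Sequence[float], method: str = "auto"
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences ``after - before`` equal to zero are dropped (the classical
    convention); absolute differences are ranked with midranks for ties and
    ``W`` is the sum of ranks of positive differences.

    ``method="auto"`` uses the exact null distribution (enumeration over all
    sign assignments) when at most 25 non-zero differences carry no tied
    magnitudes, otherwise a normal approximation with tie correction and
    continuity correction.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1 or b.size < 1:
        raise ValueError("before/after must be equal-length 1-D sequences")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    absd = np.abs(d)
    ranks = _sps.rankdata(absd)  # midranks
    w_pos = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if method == "auto":
        method = "exact" if (n <= 25 and not has_ties) else "approx"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method is only defined without tied magnitudes")
        cdf, sf = _exact_rank_sum_sf_cdf(n, w_pos)
        p = min(1.0, 2.0 * min(cdf, sf))
    elif method == "approx":
        mu = n * (n + 1) / 4.0
        tie_counts = np.unique(absd, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        if var <= 0:
            raise UndefinedTestError("degenerate variance (all magnitudes tied to zero)")
        dev = w_pos - mu
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)  # continuity correction
        p = float(2.0 * _sps.norm.sf(abs(z)))
        p = min(1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return WilcoxonResult(statistic=w_pos, p_value=p, n=n, method=method)


def bootstrap_mean_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean, resampling elements (pairs)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def _change_test(
    target: str,
    before: np.ndarray,
    after: np.ndarray,
    n_boot: int,
    ci_level: float,
    rng: np.random.Generator,
    wilcoxon_method: str = "auto",
) -> ChangeTest:
    delta = after - before
    if np.all(delta == 0.0):
        stat, p, note = float("nan"), float("nan"), "undefined: all differences zero"
    else:
        res = wilcoxon_signed_rank(before, after, method=wilcoxon_method)
        stat, p, note = res.statistic, res.p_value, res.method
    if np.all(delta == delta[0]):
        lo = hi = float(delta[0])
    else:
        lo, hi = bootstrap_mean_ci(delta, n_boot=n_boot, ci_level=ci_level, seed=rng)
    return ChangeTest(
        target=target,
        n_pairs=before.size,
        mean_before=float(before.mean()),
        mean_after=float(after.mean()),
        mean_change=float(delta.mean()),
        se_before=_sem(before),
        se_after=_sem(after),
        se_change=_sem(delta),
        statistic=stat,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
        note=note,
    )


def paired_change(
    pairs: Sequence[tuple[CompositionVector, CompositionVector]],
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int = 0,
    relative: bool = False,
    wilcoxon_method: str = "auto",
) -> list[ChangeTest]:
    """Per-category and Shannon change tests across historical/modern pairs.

    "Change" is ``after - before`` in percentage points by default (the
    from-X%-to-Y% framing); set ``relative=True`` for percent-of-baseline
    change. One :class:`ChangeTest` per category present in the compositions,
    plus one for the Shannon index (target ``"shannon"``).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 photo pairs")
    rng = np.random.default_rng(seed)
    categories = list(pairs[0][0].values.keys())
    out: list[ChangeTest] = []
    for cat in categories:
        before = np.array([h.percent(cat) for h, _ in pairs])
        after = np.array([m.percent(cat) for _, m in pairs])
        if relative:
            with np.errstate(divide="ignore", invalid="ignore"):
                after = np.where(before > 0, 100.0 * (after - before) / before, np.nan)
                before = np.zeros_like(before)
        out.append(_change_test(cat, before, after, n_boot, ci_level, rng, wilcoxon_method))
    h_before = np.array([shannon_index(h) for h, _ in pairs])
    h_after = np.array([shannon_index(m) for _, m in pairs])
    out.append(_change_test(SHANNON_KEY, h_before, h_after, n_boot, ci_level, rng, wilcoxon_method))
    return out
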