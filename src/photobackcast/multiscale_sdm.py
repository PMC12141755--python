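"""Multi-scale species distribution models for repeat point-count data.

Per species, detection counts out of ``k`` sampling units are modelled as
binomial with a logit link on buffer land cover percentages. The
characteristic scale of selection is found by extracting covariates in
buffers of radius 250-4500 m (250-m steps), screening collinearity by VIF,
reducing each radius's model by bidirectional stepwise AIC, and keeping the
radius whose selected model minimises AIC.

The binomial GLM is fit by iteratively reweighted least squares implemented
here (standard errors from the inverse Fisher information); tests cross-check
it against independent likelihood maximisation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from ._core import CompositionVector, LandCoverScheme, RasterMap

__all__ = [
    "SDMFit",
    "DetectabilityEstimate",
    "VifResult",
    "ScaleSelection",
    "default_radii",
    "buffer_proportions",
    "build_covariate_table",
    "vif_screen",
    "fit_glm_binomial",
    "stepwise_aic",
    "select_scale",
    "pfa",
    "detectability",
    "validate_model",
]

INTERCEPT = "intercept"


def default_radii(min_m: float = 250.0, max_m: float = 4500.0, step_m: float = 250.0) -> np.ndarray:
    """The analysis radius grid: 250 to 4500 m in 250-m increments."""
    return np.arange(min_m, max_m + 0.5 * step_m, step_m)


@dataclass
class SDMFit:
    """A fitted per-species occurrence model (one spatial scale).

    ``beta``/``se`` are keyed by covariate name; the intercept is carried
    separately. Coefficients are log-odds per percentage point of cover.
    """

    species: str
    scale_m: float
    terms: tuple[str, ...]
    intercept: float
    intercept_se: float
    beta: dict[str, float]
    se: dict[str, float]
    t_values: dict[str, float]
    aic: float
    loglik: float
    n_sites: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.se.items() if not v > 0]
        if bad or not self.intercept_se > 0:
            raise ValueError("standard errors must be positive")

    @property
    def n_params(self) -> int:
        return 1 + len(self.terms)

    def shifted(self, direction: int) -> "SDMFit":
        """Coefficients shifted by ``direction`` * SE (all simultaneously)."""
        return SDMFit(
            species=self.species,
            scale_m=self.scale_m,
            terms=self.terms,
            intercept=self.intercept + direction * self.intercept_se,
            intercept_se=self.intercept_se,
            beta={k: v + direction * self.se[k] for k, v in self.beta.items()},
            se=dict(self.se),
            t_values=dict(self.t_values),
            aic=self.aic,
            loglik=self.loglik,
            n_sites=self.n_sites,
            diagnostics=dict(self.diagnostics),
        )

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["terms"] = list(self.terms)
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "SDMFit":
        payload = json.loads(Path(path).read_text())
        payload["terms"] = tuple(payload["terms"])
        return cls(**payload)


@dataclass
class DetectabilityEstimate:
    """Per-occasion detection probability and the derived false-absence risk."""

    species: str
    p: float
    k: int
    pfa: float
    reliable: bool


@dataclass
class VifResult:
    retained: list[str]
    dropped: list[str]  # in drop order
    vif: pd.DataFrame  # columns: term, vif, step


@dataclass
class ScaleSelection:
    """Outcome of the multi-scale search for one species."""

    fit: "SDMFit"
    profile: pd.DataFrame  # radius_m, aic, n_terms, validated


# --------------------------------------------------------------------------- buffers


def buffer_proportions(
    raster: RasterMap,
    point: tuple[float, float],
    radius_m: float,
    scheme: LandCoverScheme,
    merged: bool = False,
) -> CompositionVector:
    """Land cover percentages over cells whose centers fall within the buffer.

    Cells outside the raster are excluded from the denominator
    (edge-truncated buffer); the excluded fraction of the ideal disc is
    reported as ``truncation_fraction`` on the result.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    if not raster.contains(point):
        raise ValueError(f"site {point} lies outside the raster extent {raster.extent}")
    x, y = point
    cs = raster.cell_size
    x0, y0 = raster.origin
    h, w = raster.shape
    # Cell-index window of the ideal (unclipped) disc.
    c_lo = int(np.floor((x - radius_m - x0) / cs - 0.5))
    c_hi = int(np.ceil((x + radius_m - x0) / cs - 0.5))
    r_lo = int(np.floor((y - radius_m - y0) / cs - 0.5))
    r_hi = int(np.ceil((y + radius_m - y0) / cs - 0.5))
    cols = np.arange(c_lo, c_hi + 1)
    rows = np.arange(r_lo, r_hi + 1)
    cx = x0 + (cols + 0.5) * cs
    cy = y0 + (rows + 0.5) * cs
    dist2 = (cx[None, :] - x) ** 2 + (cy[:, None] - y) ** 2
    in_disc = dist2 <= radius_m**2
    n_ideal = int(in_disc.sum())
    inside_raster = (
        (cols[None, :] >= 0) & (cols[None, :] < w) & (rows[:, None] >= 0) & (rows[:, None] < h)
    )
    usable = in_disc & inside_raster
    n_used = int(usable.sum())
    if n_used == 0:
        raise ValueError("buffer contains no cell centers")
    rr, cc = np.nonzero(usable)
    labels = raster.labels[rows[rr], cols[cc]]
    keep = labels != scheme.invalid_id
    labels = labels[keep]
    if labels.size == 0:
        raise ValueError("buffer contains only invalid cells")
    counts = np.bincount(labels, minlength=max(scheme.ids) + 1)
    values = {name: 100.0 * counts[i] / labels.size for i, name in scheme.categories}
    comp = CompositionVector(values, int(labels.size), truncation_fraction=1.0 - n_used / n_ideal)
    if merged and scheme.merge_map is not None:
        from .landcover_accounting import merge_categories

        comp = merge_categories(comp, scheme)
    return comp


def build_covariate_table(
    raster: RasterMap,
    sites: pd.DataFrame,
    radii: Sequence[float],
    scheme: LandCoverScheme,
) -> pd.DataFrame:
    """The full site x radius covariate grid (percent per category).

    ``sites`` needs columns ``site_id, x, y``. Output columns: ``site_id,
    radius_m, truncation`` plus one percent column per (coarse) category.
    When the scheme has a ``merge_map`` the fine categories are merged.
    """
    merged = scheme.merge_map is not None
    out_scheme = scheme.merged() if merged else scheme
    rows = []
    for rec in sites.itertuples(index=False):
        for radius in radii:
            comp = buffer_proportions(raster, (rec.x, rec.y), radius, scheme, merged=merged)
            row = {"site_id": rec.site_id, "radius_m": float(radius), "truncation": comp.truncation_fraction}
            for name in out_scheme.names:
                row[name] = comp.percent(name)
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- VIF


def _vif_one(X: np.ndarray, j: int) -> float:
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = ((y - y.mean()) ** 2).sum()
    if sst <= 1e-12:  # constant column: no information, infinitely inflated
        return np.inf
    r2 = 1.0 - (resid**2).sum() / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return float(1.0 / (1.0 - r2))


def vif_screen(covariates: pd.DataFrame, threshold: float = 3.0) -> VifResult:
    """Iteratively drop the largest-VIF covariate until all VIFs < threshold.

    VIF_j = 1 / (1 - R^2_j) from an OLS regression of covariate j on the
    remaining covariates (with intercept). Because closed compositions are
    perfectly collinear, at least one category is always shed when all scheme
    categories enter together. Ties for the largest VIF (every VIF is
    infinite in the fully closed case) are broken by dropping the
    least-variable covariate, so rare near-constant categories are shed
    before the informative dominant ones.
    """
    if covariates.shape[1] < 2:
        raise ValueError("VIF screening needs at least 2 covariates")
    if covariates.shape[0] < covariates.shape[1] + 1:
        raise ValueError("VIF screening needs more rows than covariates")
    cols = sorted(covariates.columns)
    records = []
    dropped: list[str] = []
    step = 0
    while True:
        X = covariates[cols].to_numpy(dtype=float)
        vifs = np.array([_vif_one(X, j) for j in range(len(cols))])
        for c, v in zip(cols, vifs):
            records.append({"term": c, "vif": v, "step": step})
        if len(cols) < 2 or np.nanmax(vifs) < threshold:
            break
        vmax = np.nanmax(vifs)
        tied = [
            j
            for j, v in enumerate(vifs)
            if (np.isinf(v) and np.isinf(vmax)) or v >= vmax * (1.0 - 1e-9)
        ]
        worst = min(tied, key=lambda j: X[:, j].var())
        dropped.append(cols[worst])
        cols = cols[:worst] + cols[worst + 1 :]
        step += 1
    return VifResult(retained=cols, dropped=dropped, vif=pd.DataFrame(records))


# --------------------------------------------------------------------------- GLM


def _binom_loglik(y: np.ndarray, k: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    ll = gammaln(k + 1) - gammaln(y + 1) - gammaln(k - y + 1)
    ll = ll + y * np.log(mu) + (k - y) * np.log1p(-mu)
    return float(ll.sum())


def fit_glm_binomial(
    detections: np.ndarray,
    trials: np.ndarray | int,
    covariates: pd.DataFrame | None,
    species: str = "",
    scale_m: float = float("nan"),
    max_iter: int = 100,
    tol: float = 1e-10,
    beta_bound: float = 50.0,
) -> SDMFit:
    """Maximum-likelihood logit-link binomial GLM via IRLS.

    Parameters
    ----------
    detections, trials
        Per-site success counts ``y`` out of ``k`` Bernoulli sampling units.
    covariates
        Per-site covariate percentages (one column per term); ``None`` or an
        empty frame fits the intercept-only model.
    beta_bound
        |beta| beyond this flags quasi-separation.

    Standard errors come from the inverse Fisher information at the optimum;
    AIC = -2 loglik + 2 (number of parameters), with the full binomial
    log-likelihood (including the combinatorial term).
    """
    y = np.asarray(detections, dtype=float)
    k = np.broadcast_to(np.asarray(trials, dtype=float), y.shape).copy()
    if (k <= 0).any():
        raise ValueError("every site needs k >= 1 sampling units")
    if ((y < 0) | (y > k)).any():
        raise ValueError("detections must lie in [0, k]")
    if covariates is None or covariates.shape[1] == 0:
        terms: tuple[str, ...] = ()
        X = np.ones((y.size, 1))
    else:
        terms = tuple(covariates.columns)
        X = np.column_stack([np.ones(y.size), covariates.to_numpy(dtype=float)])
    n, p = X.shape
    if n < p + 1:
        raise ValueError("need at least one more site than parameters")
    col_var = X[:, 1:].var(axis=0) if p > 1 else np.empty(0)
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("rank-deficient design matrix")

    beta = np.zeros(p)
    beta[0] = np.log((y.sum() + 0.5) / (k.sum() - y.sum() + 0.5))
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
        w = k * mu * (1.0 - mu)
        z = eta + (y - k * mu) / w
        Xw = X * w[:, None]
        try:
            new_beta = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        shift = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if np.max(np.abs(beta)) > beta_bound:
            separated = True
            break
        if shift < tol:
            converged = True
            break

    eta = X @ beta
    mu = np.clip(expit(eta), 1e-10, 1.0 - 1e-10)
    w = k * mu * (1.0 - mu)
    fisher = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(fisher)
        se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    loglik = _binom_loglik(y, k, mu)
    aic = -2.0 * loglik + 2.0 * p
    # Residual deviance vs the saturated model, for the dispersion diagnostic.
    sat = _binom_loglik(y, k, np.clip(y / k, 1e-10, 1 - 1e-10))
    deviance = 2.0 * (sat - loglik)
    df_resid = n - p
    dispersion = deviance / df_resid if df_resid > 0 else float("nan")
    tvals = beta / se
    return SDMFit(
        species=species,
        scale_m=scale_m,
        terms=terms,
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        beta={t: float(b) for t, b in zip(terms, beta[1:])},
        se={t: float(s) for t, s in zip(terms, se[1:])},
        t_values={t: float(v) for t, v in zip((INTERCEPT, *terms), tvals)},
        aic=float(aic),
        loglik=float(loglik),
        n_sites=n,
        diagnostics={
            "converged": bool(converged),
            "separation_flag": bool(separated),
            "deviance": float(deviance),
            "dispersion": float(dispersion),
            "df_resid": int(df_resid),
            "term_variances": {t: float(v) for t, v in zip(terms, col_var)},
        },
    )


# --------------------------------------------------------------------------- stepwise


def stepwise_aic(
    detections: np.ndarray,
    trials: np.ndarray | int,
    covariates: pd.DataFrame,
    start_terms: Sequence[str] | None = None,
    species: str = "",
    scale_m: float = float("nan"),
    **fit_kw,
) -> SDMFit:
    """Bidirectional stepwise AIC reduction starting from the full model.

    At each step every single-term deletion and addition is evaluated; the
    move with the lowest AIC is taken and the search stops when no move
    strictly reduces AIC. The intercept is never removed. Ties break
    deterministically: deletion over addition, then alphabetical term order.
    """
    candidates = sorted(covariates.columns)
    current = sorted(candidates if start_terms is None else start_terms)
    cache: dict[frozenset, SDMFit] = {}

    def fit_for(terms: list[str]) -> SDMFit:
        key = frozenset(terms)
        if key not in cache:
            sub = covariates[sorted(terms)] if terms else None
            cache[key] = fit_glm_binomial(
                detections, trials, sub, species=species, scale_m=scale_m, **fit_kw
            )
        return cache[key]

    best = fit_for(current)
    while True:
        moves: list[tuple[float, int, list[str]]] = []
        order = 0
        for t in sorted(current):  # deletions first (preferred on ties)
            trial_terms = [x for x in current if x != t]
            moves.append((fit_for(trial_terms).aic, order, trial_terms))
            order += 1
        for t in sorted(set(candidates) - set(current)):
            trial_terms = sorted(current + [t])
            moves.append((fit_for(trial_terms).aic, order, trial_terms))
            order += 1
        if not moves:
            break
        best_aic, _, best_terms = min(moves, key=lambda m: (m[0], m[1]))
        if best_aic < best.aic - 1e-10:
            current = best_terms
            best = fit_for(current)
        else:
            break
    return best


def select_scale(
    species: str,
    detections: pd.DataFrame,
    covariates: pd.DataFrame,
    vif_threshold: float = 3.0,
    radii: Sequence[float] | None = None,
    min_variance: float = 1e-8,
    **fit_kw,
) -> ScaleSelection:
    """Pick the characteristic scale of selection by minimum AIC over radii.

    Per radius: drop (near-)constant categories, screen the rest by VIF,
    reduce by stepwise AIC; then return the radius whose selected model has
    minimum AIC (ties toward the smaller radius). The per-radius AIC profile
    is retained. Radii whose model fails validation are excluded; if all
    fail the species is unmodelable.

    ``detections`` needs columns ``site_id, count, k``; ``covariates`` is a
    :func:`build_covariate_table` frame.
    """
    if radii is None:
        radii = sorted(covariates["radius_m"].unique())
    det = detections.sort_values("site_id").reset_index(drop=True)
    y = det["count"].to_numpy()
    k = det["k"].to_numpy()
    meta = {"site_id", "radius_m", "truncation"}
    categories = [c for c in covariates.columns if c not in meta]
    records = []
    fits: list[tuple[float, SDMFit]] = []
    for radius in radii:
        sub = (
            covariates[covariates["radius_m"] == radius]
            .sort_values("site_id")
            .reset_index(drop=True)
        )
        if not (sub["site_id"].to_numpy() == det["site_id"].to_numpy()).all():
            raise ValueError("covariate table and detections disagree on sites")
        X = sub[categories]
        X = X.loc[:, X.var(axis=0) > min_variance]
        if X.shape[1] >= 2:
            X = X[vif_screen(X, threshold=vif_threshold).retained]
        fit = stepwise_aic(y, k, X, species=species, scale_m=float(radius), **fit_kw)
        ok, reasons = validate_model(fit)
        records.append(
            {
                "radius_m": float(radius),
                "aic": fit.aic,
                "n_terms": len(fit.terms),
                "validated": ok,
                "reasons": ";".join(reasons),
            }
        )
        if ok:
            fits.append((float(radius), fit))
    profile = pd.DataFrame(records)
    if not fits:
        raise ValueError(f"species {species!r} is unmodelable: no radius passed validation")
    # min AIC; ties toward the smaller radius (fits is in increasing radius order)
    best_radius, best_fit = min(fits, key=lambda rf: (rf[1].aic, rf[0]))
    best_fit.diagnostics["aic_profile"] = {str(r["radius_m"]): r["aic"] for r in records}
    return ScaleSelection(fit=best_fit, profile=profile)


# --------------------------------------------------------------------------- detectability


def pfa(p: float, k: int) -> float:
    """Probability of false absence: missing a present species on all k occasions.

    PFA = (1 - p)^k for per-occasion detection probability p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float((1.0 - p) ** k)


def detectability(
    species: str, p: float, k: int = 9, reliable_below: float = 0.15
) -> DetectabilityEstimate:
    """PFA summary with a reliability flag (default threshold 0.15)."""
    value = pfa(p, k)
    return DetectabilityEstimate(species=species, p=p, k=k, pfa=value, reliable=value < reliable_below)


def validate_model(
    fit: SDMFit, dispersion_band: tuple[float, float] = (0.3, 3.0)
) -> tuple[bool, list[str]]:
    """Model validation: convergence, no separation, sane dispersion, full-rank terms."""
    reasons: list[str] = []
    d = fit.diagnostics
    if not d.get("converged", False):
        reasons.append("non-convergence")
    if d.get("separation_flag", False):
        reasons.append("separation")
    disp = d.get("dispersion", float("nan"))
    if np.isfinite(disp) and not (dispersion_band[0] <= disp <= dispersion_band[1]):
        reasons.append(f"dispersion {disp:.3g} outside {dispersion_band}")
    term_var = d.get("term_variances", {})
    if any(v <= 1e-12 for v in term_var.values()) or any(
        not np.isfinite(v) or v <= 0 for v in fit.se.values()
    ):
        reasons.append("degenerate design")
    ok = not reasons
    fit.diagnostics["validated"] = ok
    fit.diagnostics["validation_reasons"] = reasons
    return ok, reasons
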