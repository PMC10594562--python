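"""Variance stabilization, batch correction, moderated testing, and score FDR.

Four statistical workhorses shared by the single-tube and ladder pipelines:

* a generalized-log (glog2) variance-stabilizing transform with per-channel
  affine calibration, fitted robustly by least-trimmed squares — the affine
  offset doubles as the background correction;
* removal of additive batch effects by a per-protein linear model that keeps
  the condition contrast intact;
* an empirical-Bayes moderated t-test: per-protein variances are shrunk
  toward a pooled prior whose degrees of freedom and scale are estimated by
  moment-matching a scaled-F distribution on the log sample variances
  (Smyth's closed-form estimator), with Benjamini-Hochberg adjustment;
* a tail-area false-discovery-rate estimate for score statistics, fitting a
  central truncated-normal null to robustly z-scored values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from .io_filters import DesignError, IntensityMatrix

LN2 = math.log(2.0)


class DegenerateDistributionError(ValueError):
    """The score distribution has no spread; FDR estimation is impossible."""


# ---------------------------------------------------------------------------
# Variance-stabilizing transform
# ---------------------------------------------------------------------------


def glog2(y):
    """Generalized log2: glog2(y) = log2(y + sqrt(y^2 + 1)) = asinh(y)/ln 2.

    Behaves like log2(2y) for large y but stays finite (and defined) at and
    below zero, which tames the additive-background regime of reporter
    intensities.
    """
    return np.arcsinh(np.asarray(y, dtype=float)) / LN2


def glog2_inverse(t):
    """Inverse of :func:`glog2`: sinh(t * ln 2)."""
    return np.sinh(np.asarray(t, dtype=float) * LN2)


@dataclass(frozen=True)
class VSTParams:
    """Per-channel affine calibration of the glog2 transform.

    Channel ``c`` is transformed as h_c(x) = glog2((x - offset_c) / scale_c)
    with scale_c > 0, so h_c is monotone increasing.  ``groups`` records the
    channel grouping the parameters were fitted within (normalization is
    independent per group, e.g. per ladder temperature).
    """

    offsets: np.ndarray
    scales: np.ndarray
    groups: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))
        if np.any(self.scales <= 0):
            raise ValueError("VST scales must be > 0")

    def transform(self, intensities: np.ndarray) -> np.ndarray:
        return glog2((np.asarray(intensities, dtype=float) - self.offsets) / self.scales)


def _fit_group_affine(x: np.ndarray, trim: float, maxiter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Fit per-channel (offset, scale) for one group by trimmed profile
    likelihood of the calibrated glog model.

    The criterion is the profile negative log-likelihood of the model
    h_c(x_ic) = mu_i + noise: (M/2) log RSS minus the log-Jacobian of the
    transformation, summed over the best (1 - trim) fraction of proteins
    (re-selected a few times).  The Jacobian term is what pins the scale —
    a plain least-squares criterion is degenerate, since inflating every
    scale flattens all transformed values toward zero residuals.  Parameters
    are optimized on a per-channel O(1) scale (offsets relative to the
    channel median).
    """
    from scipy.optimize import minimize

    n, c = x.shape
    med = np.maximum(np.median(x, axis=0), 1e-12)
    ref = np.exp(np.mean(np.log(med)))  # geometric mean of channel medians
    scale0 = med / ref

    def unpack(theta):
        offsets = theta[:c] * med
        scales = np.exp(theta[c:]) * scale0
        return offsets, scales

    theta = np.concatenate([np.zeros(c), np.zeros(c)])
    keep = np.ones(n, dtype=bool)
    n_keep = max(int(round(n * (1.0 - trim))), 2)
    # The background offset is only weakly identified in channels whose
    # signal dwarfs it; cap |a_c| below the smallest observed intensity so
    # the Jacobian term cannot drift it into the data and crush the dimmest
    # proteins (in near-floor channels the minimum sits just below the true
    # background, so the cap still admits a good fit there).
    min_pos = np.array([x[x[:, j] > 0, j].min() if np.any(x[:, j] > 0) else 0.0
                        for j in range(c)])
    a_cap = 0.999 * min_pos / med
    bounds = [(-a_cap[j], a_cap[j]) for j in range(c)] + [(-25.0, 25.0)] * c

    for _ in range(3):
        xs = x[keep]
        m_vals = xs.size

        def objective(th, xs=xs, m_vals=m_vals):
            offsets, scales = unpack(th)
            y = (xs - offsets) / scales
            s2 = y * y + 1.0
            h = np.arcsinh(y) / LN2
            r = h - h.mean(axis=1, keepdims=True)
            rss = float(np.sum(r * r)) + 1e-300
            # profile -log L: (M/2) ln RSS - sum ln h'(x)
            log_jac = -m_vals * math.log(LN2) - np.sum(np.log(scales)) * xs.shape[0] \
                - 0.5 * float(np.sum(np.log(s2)))
            f = 0.5 * m_vals * math.log(rss) - log_jac
            # gradient
            dh_da = -(med / scales) / (LN2 * np.sqrt(s2))
            dh_db = -y / (LN2 * np.sqrt(s2))
            drss_da = 2.0 * np.sum(r * dh_da, axis=0)
            drss_db = 2.0 * np.sum(r * dh_db, axis=0)
            # d(log-jacobian) terms
            djac_da = np.sum((y / s2), axis=0) * (med / scales)
            djac_db = np.sum(-1.0 / s2, axis=0)
            grad = np.concatenate([
                0.5 * m_vals * drss_da / rss - djac_da,
                0.5 * m_vals * drss_db / rss - djac_db,
            ])
            return f, grad

        sol = minimize(objective, theta, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12})
        theta = sol.x

        offsets, scales = unpack(theta)
        h_all = glog2((x - offsets) / scales)
        row_rss = np.sum((h_all - h_all.mean(axis=1, keepdims=True)) ** 2, axis=1)
        order = np.argsort(row_rss, kind="stable")
        new_keep = np.zeros(n, dtype=bool)
        new_keep[order[:n_keep]] = True
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep

    offsets, scales = unpack(theta)

    # Exact median alignment: rescale each channel so the median of the
    # transformed channel equals the cross-channel mean of medians.  Solved on
    # the central order statistic(s), so medians agree to root-finder
    # precision for both odd and even n.
    h = glog2((x - offsets) / scales)
    target = float(np.mean(np.median(h, axis=0)))
    lo_idx = (n - 1) // 2
    hi_idx = n // 2
    for j in range(c):
        col = np.sort(x[:, j] - offsets[j])
        x1, x2 = col[lo_idx], col[hi_idx]
        if x1 <= 0 and x2 <= 0:
            continue

        def median_gap(log_b, x1=x1, x2=x2):
            b = math.exp(log_b)
            return 0.5 * (math.asinh(x1 / b) + math.asinh(x2 / b)) / LN2 - target

        lo, hi = math.log(scales[j]) - 40.0, math.log(scales[j]) + 40.0
        try:
            if median_gap(lo) * median_gap(hi) < 0:
                scales[j] = math.exp(brentq(median_gap, lo, hi, xtol=1e-13, rtol=1e-15))
        except ValueError:
            pass
    return offsets, scales


def variance_stabilize(
    matrix: IntensityMatrix,
    groups: Optional[Mapping[str, Sequence[int]]] = None,
    trim: float = 0.10,
) -> tuple[IntensityMatrix, VSTParams]:
    """Variance-stabilize reporter intensities with a calibrated glog2 model.

    ``groups`` maps a group name to the channel indices normalized together
    (default: all channels in one group).  Within each group the per-channel
    affine parameters are fitted by least-trimmed squares (trim fraction
    ``trim``) so that, after transformation, channels agree for the bulk of
    proteins; transformed channel medians within a group are equalized
    exactly.  Returns the transformed matrix (scale ``"glog2"``) and the
    fitted parameters.  A group with fewer than two channels is an error.
    """
    if groups is None:
        groups = {"all": tuple(range(matrix.n_channels))}
    groups = {name: tuple(int(i) for i in idx) for name, idx in groups.items()}

    seen: list[int] = []
    for name, idx in groups.items():
        if len(idx) < 2:
            raise DesignError(f"normalization group {name!r} has fewer than 2 channels")
        seen.extend(idx)
    if sorted(seen) != sorted(set(seen)):
        raise DesignError("normalization groups must not share channels")

    offsets = np.zeros(matrix.n_channels)
    scales = np.ones(matrix.n_channels)
    for name, idx in groups.items():
        sub = matrix.intensities[:, idx]
        if not np.any(sub > 0):
            raise DesignError(f"normalization group {name!r} is all-zero")
        off, sc = _fit_group_affine(sub, trim=trim)
        offsets[list(idx)] = off
        scales[list(idx)] = sc

    params = VSTParams(offsets, scales, groups)
    transformed = params.transform(matrix.intensities)
    return matrix.with_intensities(transformed, scale="glog2"), params


def mean_sd_spearman(values: np.ndarray) -> float:
    """Spearman correlation between per-protein SD and rank of the mean —
    the diagnostic the transform is meant to drive toward zero."""
    sd = np.std(values, axis=1, ddof=1)
    mean = np.mean(values, axis=1)
    rho, _ = stats.spearmanr(mean, sd)
    return float(rho)


# ---------------------------------------------------------------------------
# Batch-effect removal
# ---------------------------------------------------------------------------


def remove_batch_effects(
    matrix: IntensityMatrix,
    batches: Sequence,
    conditions: Optional[Sequence] = None,
) -> IntensityMatrix:
    """Subtract additive per-batch offsets while preserving condition contrasts.

    Per protein, fits intensity ~ condition + batch (batch in sum-to-zero
    coding) and subtracts the fitted batch component.  With a single batch
    this is the identity.  Conditions default to the channel metadata; a
    design in which some batch lacks any condition is confounded and raises
    :class:`DesignError`.
    """
    batches = np.asarray(batches)
    if batches.shape[0] != matrix.n_channels:
        raise DesignError("one batch label required per channel")
    if conditions is None:
        conditions = [ch.condition for ch in matrix.channels]
    conditions = np.asarray(conditions)

    batch_levels = np.unique(batches)
    if batch_levels.size == 1:
        return matrix

    cond_levels = np.unique(conditions)
    for b in batch_levels:
        present = np.unique(conditions[batches == b])
        if present.size < cond_levels.size:
            raise DesignError(
                f"confounded design: batch {b!r} lacks condition(s) "
                f"{sorted(set(cond_levels) - set(present))}"
            )

    # covariates: intercept + condition dummies (first level as reference)
    cov = [np.ones(matrix.n_channels)]
    for lvl in cond_levels[1:]:
        cov.append((conditions == lvl).astype(float))
    cov = np.column_stack(cov)
    # batch block in sum-to-zero coding
    bmat = np.column_stack([
        (batches == lvl).astype(float) - (batches == batch_levels[-1]).astype(float)
        for lvl in batch_levels[:-1]
    ])
    design = np.column_stack([cov, bmat])

    coef, *_ = np.linalg.lstsq(design, matrix.intensities.T, rcond=None)
    batch_component = bmat @ coef[cov.shape[1]:, :]
    return matrix.with_intensities(matrix.intensities - batch_component.T)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeratedTestResult:
    """Per-protein moderated test output plus the shared shrinkage prior."""

    log2fc: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    s2: np.ndarray
    df_residual: float
    df_prior: float
    s2_prior: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "log2fc": self.log2fc, "t": self.t, "p": self.p, "p_adj": self.p_adj,
        })


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on a monotone map)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return x


def _binned_trend(e: np.ndarray, covariate: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Smooth trend of e against a covariate: equal-count bin means joined by
    linear interpolation (a light-weight stand-in for a lowess fit)."""
    n = e.size
    n_bins = max(2, min(n_bins, n // 25))
    if n_bins < 2:
        return np.full(n, float(np.mean(e)))
    order = np.argsort(covariate, kind="stable")
    edges = np.array_split(order, n_bins)
    centers = np.array([np.mean(covariate[idx]) for idx in edges])
    means = np.array([np.mean(e[idx]) for idx in edges])
    return np.interp(covariate, centers, means)


def fit_variance_prior(
    s2: np.ndarray, df: float, covariate: Optional[np.ndarray] = None
) -> tuple[float, np.ndarray]:
    """Estimate the shrinkage prior (d0, s0^2) from per-protein variances.

    Moment-matches the scaled-F model s2 ~ s0^2 F(df, d0) on log variances:
    the excess spread of log s2 over what trigamma(df/2) explains determines
    d0 in closed form; when the observed spread does not exceed it, the prior
    is effectively infinite (complete pooling).

    With ``covariate`` (typically mean log intensity) the prior variance is
    allowed to follow a smooth trend in the covariate — the standard remedy
    when measurement variance depends on signal level, as it does near the
    reporter noise floor; d0 is then estimated from the detrended spread.
    Returns (d0, per-protein s0^2 array).
    """
    s2 = np.asarray(s2, dtype=float)
    n_all = s2.size
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        fill = float(np.mean(s2[ok])) if ok.any() else 0.0
        return math.inf, np.full(n_all, fill)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    n = e.size
    if covariate is not None:
        trend = _binned_trend(e, np.asarray(covariate, dtype=float)[ok])
        trend_all = np.empty(n_all)
        trend_all[ok] = trend
        trend_all[~ok] = float(np.mean(trend))
    else:
        trend = np.full(n, float(np.mean(e)))
        trend_all = np.full(n_all, float(np.mean(e)))
    resid = e - trend
    e_var = float(np.sum((resid - resid.mean()) ** 2) / (n - 1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return math.inf, np.exp(trend_all)
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    if math.isinf(d0):
        return math.inf, np.exp(trend_all)
    s0_sq = np.exp(trend_all + float(special.digamma(half_d0)) - math.log(half_d0))
    return d0, s0_sq


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _moderated_from_effects(
    effect: np.ndarray, s2: np.ndarray, df: float, se_factor: float,
    prior_df: Optional[float], covariate: Optional[np.ndarray] = None,
) -> ModeratedTestResult:
    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, df, covariate=covariate)
    elif prior_df == 0:
        d0, s0_sq = 0.0, np.zeros_like(s2)
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, df, covariate=covariate)

    if math.isinf(d0):
        s2_post = np.asarray(s0_sq) + np.zeros_like(s2)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post) * se_factor
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
        t = np.where(se == 0, np.where(effect == 0, 0.0, np.sign(effect) * np.inf), t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    return ModeratedTestResult(effect, t, p, _bh_adjust(p), s2, df, d0, s0_sq)


def _pooled_mean_covariate(x: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    return x[:, list(cols)].mean(axis=1)


def moderated_ttest(
    values: np.ndarray | IntensityMatrix,
    group_a: Sequence[int],
    group_b: Sequence[int],
    prior_df: Optional[float] = None,
    intensity_trend: bool = False,
    extra_groups: Sequence[Sequence[int]] = (),
) -> ModeratedTestResult:
    """Two-sample moderated t-test of group A minus group B, per protein.

    ``values`` is a proteins x channels array (or an IntensityMatrix) on the
    variance-stabilized (log2-like) scale, so the effect is a log2 fold
    change.  The pooled equal-variance estimate with nA + nB - 2 residual df
    is shrunk toward the prior fitted by :func:`fit_variance_prior`; setting
    ``prior_df=0`` disables moderation (ordinary t-test), a positive value
    forces that prior weight.  ``intensity_trend=True`` lets the prior
    variance follow the mean transformed intensity, which keeps the test
    calibrated when channels span down to the reporter noise floor.

    ``extra_groups`` lists further design cells (channel index groups) whose
    within-group residuals are pooled into the variance estimate without
    entering the contrast — the single-variance linear model a limma-style
    fit of the whole design uses, which buys residual degrees of freedom.
    Raises on zero residual degrees of freedom.
    """
    x = values.intensities if isinstance(values, IntensityMatrix) else np.asarray(values, dtype=float)
    a = x[:, list(group_a)]
    b = x[:, list(group_b)]
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    if na < 2 or nb < 2:
        raise DesignError("need at least 2 channels per side")
    effect = a.mean(axis=1) - b.mean(axis=1)
    rss = np.sum((a - a.mean(axis=1, keepdims=True)) ** 2, axis=1)
    rss += np.sum((b - b.mean(axis=1, keepdims=True)) ** 2, axis=1)
    for grp in extra_groups:
        g = x[:, list(grp)]
        if g.shape[1] >= 2:
            rss = rss + np.sum((g - g.mean(axis=1, keepdims=True)) ** 2, axis=1)
            df += g.shape[1] - 1
    s2 = rss / df
    se_factor = math.sqrt(1.0 / na + 1.0 / nb)
    covariate = _pooled_mean_covariate(x, list(group_a) + list(group_b)) if intensity_trend else None
    return _moderated_from_effects(effect, s2, float(df), se_factor, prior_df, covariate)


def moderated_one_sample(
    values: np.ndarray,
    prior_df: Optional[float] = None,
) -> ModeratedTestResult:
    """One-sample moderated test of per-protein replicate values against 0.

    ``values`` is proteins x replicates; the replicate mean is tested against
    zero with the same empirical-Bayes variance shrinkage as the two-sample
    test.  Needs at least 2 replicates (1 residual df).
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[1]
    if n < 2:
        raise DesignError("need at least 2 replicates for a one-sample test")
    df = n - 1
    effect = x.mean(axis=1)
    s2 = np.sum((x - effect[:, None]) ** 2, axis=1) / df
    return _moderated_from_effects(effect, s2, float(df), math.sqrt(1.0 / n), prior_df)


# ---------------------------------------------------------------------------
# Score-based tail-area FDR
# ---------------------------------------------------------------------------


def score_fdr(scores: np.ndarray, central_quantile: float = 0.75) -> np.ndarray:
    """Tail-area FDR for score statistics under an empirical central null.

    Scores are robustly z-transformed (median / MAD); the null scale is
    estimated from the central band |z| <= c, where c is the
    ``central_quantile`` quantile of |z| (the truncation heuristic: the
    central bulk is assumed null), by matching c to the corresponding
    half-normal quantile.  The returned
    per-score FDR is eta0 * P0(|Z| >= |z|) / Pemp(|Z| >= |z|), clipped to
    [0, 1] and made monotone non-increasing in |z|.

    Needs >= 50 finite scores; a zero MAD raises
    :class:`DegenerateDistributionError`.
    """
    scores = np.asarray(scores, dtype=float)
    if np.sum(np.isfinite(scores)) < 50:
        raise ValueError("score_fdr needs at least 50 finite scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med)))
    if mad == 0:
        raise DegenerateDistributionError("MAD of scores is zero")
    z = (scores - med) / (1.4826 * mad)
    az = np.abs(z)
    n = az.size

    # Null scale from the central band: the |z| quantile at
    # ``central_quantile`` matched to the same quantile of a half-normal.
    # Quantile matching is consistent for a normal null and, unlike a
    # truncated MLE, insensitive to mild shape mismatch in the bulk (a 20%
    # scale error changes far-tail FDRs by orders of magnitude).
    c = float(np.quantile(az, central_quantile))
    sigma = c / float(stats.norm.ppf(0.5 + central_quantile / 2.0))
    sigma = max(sigma, 1e-12)

    band_mass = 2.0 * stats.norm.cdf(c / sigma) - 1.0
    n_central = int(np.sum(az <= c))
    eta0 = min(1.0, (n_central / n) / band_mass) if band_mass > 0 else 1.0

    order = np.argsort(az, kind="stable")
    # empirical survival P(|Z| >= |z_i|), computed on the sorted grid
    surv_emp = (n - np.searchsorted(az[order], az[order], side="left")) / n
    surv_null = 2.0 * stats.norm.sf(az[order] / sigma)
    fdr_sorted = np.clip(eta0 * surv_null / surv_emp, 0.0, 1.0)
    # enforce monotone non-increasing in |z| (conservative: running max from
    # the largest |z| downward)
    fdr_sorted = np.maximum.accumulate(fdr_sorted[::-1])[::-1]
    out = np.empty(n)
    out[order] = fdr_sorted
    return out
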