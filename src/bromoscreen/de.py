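"""Control-gene-anchored negative-binomial differential expression.

A compact NB DE engine in the DESeq2 mold, with one deliberate twist: size
factors are computed by median-of-ratios over *control rows only* (the
spike-ins), so that a coordinated global change of the endogenous
transcriptome — the signature of transcriptional amplification or collapse —
shows up as differential expression instead of being normalized away.

Per gene the model is NB(mu, alpha) with log link, design intercept +
condition, and offset log(size factor):

    log mu_s = beta0 + beta1 * 1[s treated] + log f_s

``beta1 / ln 2`` is the log2 fold change; the Wald statistic uses the
expected-information standard error. Dispersions are method-of-moments
estimates shrunk in log space toward a fitted ``alpha(mu) = a0 + a1/mu``
trend. This approximates DESeq2's behaviour on simulated data; it does not
reproduce its exact numerics (no MAP dispersion estimator, no Cook's
outlier handling, no LFC shrinkage, no independent filtering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NS = "ns"


@dataclass(frozen=True)
class Contrast:
    """Treated vs control sample groups for one comparison."""

    treated: tuple[str, ...]
    control: tuple[str, ...]
    label: str = "treated_vs_control"

    def __post_init__(self):
        treated, control = tuple(self.treated), tuple(self.control)
        object.__setattr__(self, "treated", treated)
        object.__setattr__(self, "control", control)
        if set(treated) & set(control):
            raise ValueError("treated and control groups overlap")
        if len(treated) < 2 or len(control) < 2:
            raise ValueError("each group needs >= 2 samples")


@dataclass
class DeConfig:
    alpha: float = 0.05
    control_ids: tuple[str, ...] = field(default_factory=tuple)
    dispersion_floor: float = 1e-8
    shrinkage_weight: float = 0.5
    trend_min_mean: float = 5.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def median_of_ratios_size_factors(counts: pd.DataFrame, rows=None) -> pd.Series:
    """Median-of-ratios size factors over the given rows (default: all).

    Rows with a zero in any sample are excluded from the reference (their
    geometric mean is degenerate). Factors are rescaled so their geometric
    mean is 1, making them comparable across factor sets.
    """
    sub = counts if rows is None else counts.loc[counts.index.intersection(rows)]
    arr = sub.to_numpy(dtype=float)
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise ValueError("no rows without zeros available for the reference")
    arr = arr[eligible]
    log_ref = np.log(arr).mean(axis=1)
    log_ratios = np.log(arr) - log_ref[:, None]
    log_factors = np.median(log_ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def control_gene_size_factors(
    counts: pd.DataFrame, control_ids, min_controls: int = 8
) -> pd.Series:
    """Spike-in-anchored size factors: median-of-ratios over control rows only."""
    control_ids = [c for c in control_ids if c in counts.index]
    nonzero = [
        c for c in control_ids if (counts.loc[c].to_numpy(dtype=float) > 0).all()
    ]
    if len(nonzero) < min_controls:
        raise ValueError(
            f"need >= {min_controls} control rows with nonzero counts in every "
            f"sample, found {len(nonzero)}"
        )
    return median_of_ratios_size_factors(counts, rows=nonzero)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    conditions: pd.Series,
    config: DeConfig | None = None,
) -> pd.DataFrame:
    """Per-gene NB dispersions: method-of-moments shrunk toward a mean trend.

    The gene-wise estimate is ``(s^2 - mu) / mu^2`` on size-factor-normalized
    counts, with the variance pooled within conditions so planted fold
    changes do not masquerade as dispersion. The trend ``a0 + a1/mu`` is fit
    by non-negative least squares over genes with mean >= trend_min_mean
    (raw, unfloored estimates, so sampling zeros do not bias the fit). The
    final value blends gene and trend estimates geometrically; genes whose
    moment estimate is at or below the floor carry no usable overdispersion
    information and take the trend value.

    Returns a frame with columns mom (floored), trend, final.
    """
    config = config or DeConfig()
    conditions = pd.Series(conditions)
    if not set(counts.columns) <= set(conditions.index):
        raise ValueError("every sample needs a condition label")
    conditions = conditions.reindex(counts.columns)
    sizes = conditions.value_counts()
    if (sizes < 2).any():
        raise ValueError("every condition needs >= 2 samples for dispersion estimation")

    q = counts.to_numpy(dtype=float) / size_factors.reindex(counts.columns).to_numpy()
    mu = q.mean(axis=1)

    # pooled within-condition variance
    n_total = q.shape[1]
    ss = np.zeros(q.shape[0])
    for cond in sizes.index:
        cols = np.flatnonzero((conditions == cond).to_numpy())
        grp = q[:, cols]
        ss += ((grp - grp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / (n_total - len(sizes))

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu) / mu**2
    raw[~np.isfinite(raw)] = 0.0
    mom = np.maximum(raw, config.dispersion_floor)

    trend_mask = mu >= config.trend_min_mean
    if trend_mask.sum() >= 10:
        design = np.column_stack([np.ones(trend_mask.sum()), 1.0 / mu[trend_mask]])
        coef, _ = optimize.nnls(design, np.maximum(raw[trend_mask], 0.0))
        a0, a1 = coef
    else:  # too few informative genes: flat fallback at the median moment estimate
        a0, a1 = float(np.median(mom)), 0.0
    with np.errstate(divide="ignore"):
        trend = np.maximum(a0 + a1 / np.maximum(mu, 1e-8), config.dispersion_floor)

    w = config.shrinkage_weight
    informative = raw > config.dispersion_floor
    final = np.where(
        informative,
        np.exp(w * np.log(trend) + (1 - w) * np.log(mom)),
        trend,
    )
    return pd.DataFrame(
        {"mom": mom, "trend": trend, "final": final, "base_mean": mu}, index=counts.index
    )


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def _irls_two_group(
    y: np.ndarray,
    alpha: np.ndarray,
    offset: np.ndarray,
    treated: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    eta_bound: float = 30.0,
):
    """Vectorized IRLS for the two-group NB GLM with log link and offsets.

    y: genes x samples counts; alpha: per-gene dispersion; offset: per-sample
    log size factor; treated: boolean per sample. Returns (beta0, beta1,
    se_beta1, converged). The design shares structure across genes, so the
    2x2 normal equations have a closed-form solve.
    """
    n_genes, _ = y.shape
    t = treated.astype(float)

    # initial values from group means on the offset-adjusted scale
    adj = y / np.exp(offset)[None, :]
    eps = 0.5
    mc = adj[:, ~treated].mean(axis=1) + eps
    mt = adj[:, treated].mean(axis=1) + eps
    beta0 = np.log(mc)
    beta1 = np.log(mt) - np.log(mc)

    converged = np.zeros(n_genes, dtype=bool)
    active = np.ones(n_genes, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(beta0[:, None] + beta1[:, None] * t[None, :] + offset[None, :],
                      -eta_bound, eta_bound)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu

        sw = w.sum(axis=1)
        swt = (w * t[None, :]).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swtz = (w * z * t[None, :]).sum(axis=1)
        det = swt * (sw - swt)  # = wt * wc
        det = np.where(det <= 0, np.nan, det)
        new_b1 = (sw * swtz - swt * swz) / det
        new_b0 = (swz - swt * new_b1) / sw

        delta = np.maximum(np.abs(new_b0 - beta0), np.abs(new_b1 - beta1))
        beta0, beta1 = np.where(active, new_b0, beta0), np.where(active, new_b1, beta1)
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly
        if not active.any():
            break

    eta = np.clip(beta0[:, None] + beta1[:, None] * t[None, :] + offset[None, :],
                  -eta_bound, eta_bound)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    wc = (w * (1 - t)[None, :]).sum(axis=1)
    wt = (w * t[None, :]).sum(axis=1)
    with np.errstate(divide="ignore"):
        se_b1 = np.sqrt(1.0 / wc + 1.0 / wt)
    return beta0, beta1, se_b1, converged


def wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series | pd.DataFrame,
    contrast: Contrast,
) -> pd.DataFrame:
    """Per-gene NB Wald test for the given contrast.

    Returns a DeResult table indexed by gene: base_mean, log2fc (treated vs
    control), se, wald, p, padj, direction. Genes with all-zero counts across
    the contrast's samples get NA p-values and are excluded from the BH
    multiplicity count m, as are non-converged fits.
    """
    samples = list(contrast.control) + list(contrast.treated)
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise ValueError(f"contrast samples absent from counts: {missing}")
    if isinstance(dispersions, pd.DataFrame):
        dispersions = dispersions["final"]

    sub = counts[samples]
    y = sub.to_numpy(dtype=float)
    sf = size_factors.reindex(samples).to_numpy(dtype=float)
    alpha = dispersions.reindex(sub.index).to_numpy(dtype=float)
    if np.isnan(alpha).any():
        raise ValueError("dispersions missing for some genes")
    treated = np.array([s in set(contrast.treated) for s in samples])

    all_zero = (y == 0).all(axis=1)
    beta0, beta1, se_b1, converged = _irls_two_group(y, alpha, np.log(sf), treated)
    if (~converged & ~all_zero).any():
        logger.warning(
            "%d gene fit(s) did not converge; p set to NA", int((~converged & ~all_zero).sum())
        )

    log2fc = beta1 / LN2
    se_log2 = se_b1 / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = beta1 / se_b1
    p = 2.0 * stats.norm.sf(np.abs(wald))
    invalid = all_zero | ~converged | ~np.isfinite(p)
    p = np.where(invalid, np.nan, p)

    padj = bh_adjust(p)
    base_mean = (y / sf[None, :]).mean(axis=1)
    direction = np.where(
        np.isnan(padj) | (padj >= 0.05),
        DIRECTION_NS,
        np.where(log2fc > 0, DIRECTION_UP, DIRECTION_DOWN),
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(all_zero, np.nan, log2fc),
            "se": np.where(all_zero, np.nan, se_log2),
            "wald": np.where(invalid, np.nan, wald),
            "p": p,
            "padj": padj,
            "direction": direction,
        },
        index=sub.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NAs excluded from m."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def relabel_directions(result: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Recompute the direction column at a non-default significance level."""
    result = result.copy()
    sig = result["padj"].notna() & (result["padj"] < alpha)
    result["direction"] = np.where(
        ~sig, DIRECTION_NS, np.where(result["log2fc"] > 0, DIRECTION_UP, DIRECTION_DOWN)
    )
    return result


# ---------------------------------------------------------------------------
# pipeline + cross-line sets
# ---------------------------------------------------------------------------

def run_de(
    counts: pd.DataFrame,
    contrast: Contrast,
    config: DeConfig,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Size factors (from control rows), dispersions, Wald test — in one call."""
    samples = list(contrast.control) + list(contrast.treated)
    sub = counts[samples]
    if size_factors is None:
        if not config.control_ids:
            raise ValueError("config.control_ids required when size_factors not given")
        size_factors = control_gene_size_factors(sub, config.control_ids)
    conditions = pd.Series(
        ["treated" if s in set(contrast.treated) else "control" for s in samples],
        index=samples,
    )
    disp = estimate_dispersions(sub, size_factors, conditions, config)
    result = wald_test(sub, size_factors, disp["final"], contrast)
    return relabel_directions(result, config.alpha)


def high_confidence_sets(
    results_by_line: dict[str, pd.DataFrame], alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Cross-cell-line concordant significant gene sets for one treatment.

    A gene enters the down set iff padj < alpha AND log2fc < 0 in *every*
    line's result table (symmetrically for up); genes significant in only
    some lines, or significant with discordant directions, are excluded.
    """
    if len(results_by_line) < 2:
        raise ValueError("need result tables from >= 2 cell lines")
    tables = list(results_by_line.values())
    universe = tables[0].index
    for t in tables[1:]:
        if not universe.equals(t.index):
            logger.warning("gene universes differ between lines; intersecting")
            universe = universe.intersection(t.index)
    up = set(universe)
    down = set(universe)
    for t in tables:
        t = t.loc[universe]
        sig = t["padj"].notna() & (t["padj"] < alpha)
        up &= set(universe[(sig & (t["log2fc"] > 0)).to_numpy()])
        down &= set(universe[(sig & (t["log2fc"] < 0)).to_numpy()])
    return up, down
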