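"""P_ST estimation and the P_ST-vs-F_ST divergence classification.

P_ST is the phenotypic analogue of Q_ST for wild populations:

    P_ST = sigma2_b / (sigma2_b + 2 * h2 * sigma2_w)

where sigma2_b is the between-habitat variance component of a trait,
sigma2_w the within-habitat (residual) variance, and h2 a plug-in
heritability (default 0.5, chosen low to avoid overstating P_ST). A trait's
divergence is classified against neutral expectation by comparing bootstrap
CIs: P_ST CI entirely above the F_ST CI means adaptive divergence, entirely
below means homogenizing selection, overlap means drift cannot be excluded.

With only two habitat levels the between-group variance from any estimator
has large sampling variance; REML in particular is fragile with a 2-level
random effect, so a method-of-moments (one-way ANOVA expected-mean-squares)
estimator backs it up and drives the bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

DEFAULT_H2 = 0.5


@dataclass
class PstEstimate:
    trait: str
    sigma2_between: float
    sigma2_within: float
    h2: float
    pst: float
    ci95: Tuple[float, float]
    n_boot: int
    seed: int
    method: str = "mom"
    n_dropped_replicates: int = 0
    sensitivity: Optional[Dict[float, float]] = None


@dataclass
class Verdict:
    trait: str
    relation: str              # adaptive_divergence | drift | homogenizing
    pst_ci: Tuple[float, float]
    fst_ci: Tuple[float, float]


def _mom_components(values: np.ndarray, groups: np.ndarray) -> Tuple[float, float]:
    """One-way random-effects variance components via expected mean squares.

    sigma2_w = MSW; sigma2_b = max(0, (MSB - MSW) / n0) with
    n0 = (N - sum n_i^2 / N) / (r - 1).
    """
    uniq = np.unique(groups)
    r = len(uniq)
    n_i = np.array([(groups == g).sum() for g in uniq], float)
    N = n_i.sum()
    means = np.array([values[groups == g].mean() for g in uniq])
    grand = float(values.mean())
    msb = float((n_i * (means - grand) ** 2).sum() / (r - 1))
    ssw = sum(float(((values[groups == g] - m) ** 2).sum())
              for g, m in zip(uniq, means))
    msw = ssw / (N - r)
    n0 = (N - (n_i**2).sum() / N) / (r - 1)
    s2b = max(0.0, (msb - msw) / n0)
    return s2b, msw


def _reml_components(values: np.ndarray, groups: np.ndarray) -> Tuple[float, float]:
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(values, np.ones((len(values), 1)), groups=groups)
        fit = model.fit(reml=True)
    if not fit.converged:
        raise RuntimeError("REML did not converge")
    s2b = float(np.asarray(fit.cov_re)[0, 0])
    s2w = float(fit.scale)
    return s2b, s2w


def variance_components(values: Sequence[float], groups: Sequence[str],
                        method: str = "auto") -> Tuple[float, float, str]:
    """Between- and within-group variance of a trait over habitat groups.

    ``method``: ``"reml"`` (random-intercept model, restricted maximum
    likelihood), ``"mom"`` (ANOVA expected mean squares), or ``"auto"``
    (REML with MoM fallback on non-convergence). Returns
    ``(sigma2_between, sigma2_within, method_used)``.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two habitat groups")
    for g in uniq:
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    if method == "mom":
        s2b, s2w = _mom_components(values, groups)
        return s2b, s2w, "mom"
    if method in ("reml", "auto"):
        try:
            s2b, s2w = _reml_components(values, groups)
            return s2b, s2w, "reml"
        except Exception:
            if method == "reml":
                raise
            s2b, s2w = _mom_components(values, groups)
            return s2b, s2w, "mom_fallback"
    raise ValueError(f"unknown method {method!r}")


def pst(sigma2_b: float, sigma2_w: float, h2: float = DEFAULT_H2) -> float:
    """P_ST = s2b / (s2b + 2 h2 s2w)."""
    if sigma2_b < 0 or sigma2_w < 0:
        raise ValueError("variance components must be nonnegative")
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    denom = sigma2_b + 2 * h2 * sigma2_w
    if denom == 0:
        raise ValueError("both variance components are zero: P_ST undefined")
    return sigma2_b / denom


def pst_sensitivity(sigma2_b: float, sigma2_w: float,
                    h2_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
                    ) -> Dict[float, float]:
    """P_ST over a grid of heritability plug-ins (the plug-in dominates)."""
    return {float(h): pst(sigma2_b, sigma2_w, float(h)) for h in h2_grid}


def _stratified_bootstrap_pst(values: np.ndarray, groups: np.ndarray, h2: float,
                              n_boot: int, rng: np.random.Generator
                              ) -> Tuple[np.ndarray, int]:
    """Vectorized stratified bootstrap of the MoM P_ST (two or more groups)."""
    uniq = np.unique(groups)
    r = len(uniq)
    n_i = np.array([(groups == g).sum() for g in uniq])
    N = int(n_i.sum())
    n0 = (N - (n_i.astype(float)**2).sum() / N) / (r - 1)

    sums = np.zeros((n_boot, r))
    sqs = np.zeros((n_boot, r))
    for j, g in enumerate(uniq):
        v = values[groups == g]
        idx = rng.integers(0, n_i[j], size=(n_boot, n_i[j]))
        res = v[idx]
        sums[:, j] = res.sum(axis=1)
        sqs[:, j] = (res**2).sum(axis=1)
    means = sums / n_i
    grand = sums.sum(axis=1) / N
    msb = ((n_i * (means - grand[:, None]) ** 2).sum(axis=1)) / (r - 1)
    ssw = (sqs - sums**2 / n_i).sum(axis=1)
    msw = ssw / (N - r)
    ok = msw > 0
    n_dropped = int((~ok).sum())
    s2b = np.clip((msb[ok] - msw[ok]) / n0, 0, None)
    s2w = msw[ok]
    return s2b / (s2b + 2 * h2 * s2w), n_dropped


def pst_ci(values: Sequence[float], groups: Sequence[str],
           h2: float = DEFAULT_H2, n_boot: int = 10_000, seed: int = 0,
           stratified: bool = True) -> Tuple[Tuple[float, float], int]:
    """Percentile bootstrap 95% CI for P_ST.

    Individuals are resampled with replacement within each habitat
    (stratified; set ``stratified=False`` to resample the pooled sample) and
    the variance components and P_ST are recomputed each replicate via the
    expected-mean-squares estimator. Replicates with zero within-group
    variance are dropped and counted.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    if stratified:
        boots, n_dropped = _stratified_bootstrap_pst(values, groups, h2, n_boot, rng)
    else:
        n = len(values)
        boots_list = []
        n_dropped = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            v, g = values[idx], groups[idx]
            if len(np.unique(g)) < 2:
                n_dropped += 1
                continue
            s2b, s2w = _mom_components(v, g)
            if s2w == 0:
                n_dropped += 1
                continue
            boots_list.append(pst(s2b, s2w, h2))
        boots = np.array(boots_list)
    if boots.size == 0:
        raise ValueError("all bootstrap replicates degenerate")
    return ((float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))),
            n_dropped)


def pst_estimate(values: Sequence[float], groups: Sequence[str], trait: str,
                 h2: float = DEFAULT_H2, n_boot: int = 10_000, seed: int = 0,
                 method: str = "auto") -> PstEstimate:
    """Full P_ST analysis of one trait: components, point estimate, CI."""
    s2b, s2w, used = variance_components(values, groups, method=method)
    ci, n_dropped = pst_ci(values, groups, h2=h2, n_boot=n_boot, seed=seed)
    return PstEstimate(
        trait=trait, sigma2_between=s2b, sigma2_within=s2w, h2=h2,
        pst=pst(s2b, s2w, h2), ci95=ci, n_boot=n_boot, seed=seed, method=used,
        n_dropped_replicates=n_dropped,
        sensitivity=pst_sensitivity(s2b, s2w),
    )


def classify(pst_ci95: Tuple[float, float], fst_ci95: Tuple[float, float],
             trait: str = "") -> Verdict:
    """Interval-overlap classification of phenotypic vs. neutral divergence."""
    p_lo, p_hi = pst_ci95
    f_lo, f_hi = fst_ci95
    if not all(np.isfinite([p_lo, p_hi, f_lo, f_hi])):
        raise ValueError("both confidence intervals must be finite")
    if p_lo > f_hi:
        relation = "adaptive_divergence"
    elif p_hi < f_lo:
        relation = "homogenizing"
    else:
        relation = "drift"
    return Verdict(trait=trait, relation=relation,
                   pst_ci=tuple(pst_ci95), fst_ci=tuple(fst_ci95))
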