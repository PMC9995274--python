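"""Mutation-rate estimation with callable-genome and FNR correction.

The per-generation rate for a trio is

    mu_generation = m / ((1 - FNR) * 2 * C)

where ``m`` is the number of candidate DNMs, ``C`` the callable genome
(sites where a DNM could have been detected: both parents HomRef and all
three individuals passing the depth and genotype-quality filters) and FNR
the false-negative rate — the fraction of true DNMs the remaining filters
would remove.  The FNR combines

* an analytic site-filter component ``f_site`` from the null
  distributions of the annotations that follow a known law (FS phred-
  scaled uniform, MQRankSum and ReadPosRankSum standard normal), and
* an empirical allelic-balance component ``f_ab``: the fraction of
  transmitted heterozygote sites (HomRef x HomAlt -> Het) whose offspring
  allele balance falls outside the AB window.

Confidence intervals use the Wilson score on (m, 2C), scaled by
1/(1 - FNR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from gmrate.calling import HET, HOM_ALT, HOM_REF, INDIVIDUALS, FilterConfig


@dataclass
class CallableSummary:
    n_callable: int
    n_total: int
    exclusions: dict[str, int]


@dataclass
class FnrEstimate:
    """FNR decomposition; components combine multiplicatively.

    fnr_total = 1 - (1 - f_site)(1 - f_ab), assuming the site filters and
    the allelic-balance filter act independently on a true DNM.
    """

    f_site: float
    f_ab: float
    components: dict[str, float]

    @property
    def fnr_total(self) -> float:
        return 1.0 - (1.0 - self.f_site) * (1.0 - self.f_ab)


@dataclass
class RateEstimate:
    mu: float
    ci_low: float
    ci_high: float
    n_dnm: int
    n_callable: int
    fnr: float


def count_callable_sites(sites: pd.DataFrame, cfg: FilterConfig | None = None) -> CallableSummary:
    """Count sites where a DNM could have been called.

    Callability requires both parents HomRef plus the depth and GQ
    filters in all three individuals.  The site-annotation filters are
    deliberately not applied: they can only be evaluated at polymorphic
    sites and are instead absorbed into the FNR.
    """
    from gmrate.calling import mean_trio_depth

    cfg = cfg or FilterConfig()
    if sites is None or len(sites) == 0:
        raise ValueError(
            "callable-site counting needs an all-sites table (or a callable BED "
            "summarised upstream); got an empty table"
        )
    m_depth = mean_trio_depth(sites)
    lo, hi = cfg.dp_low_factor * m_depth, cfg.dp_high_factor * m_depth

    parents_homref = (
        (sites["father_gt"] == HOM_REF).to_numpy() & (sites["mother_gt"] == HOM_REF).to_numpy()
    )
    dp_ok = np.ones(len(sites), dtype=bool)
    gq_ok = np.ones(len(sites), dtype=bool)
    for ind in INDIVIDUALS:
        dp = sites[f"{ind}_dp"].to_numpy(dtype=float)
        dp_ok &= (dp > lo) & (dp < hi)
        gq_ok &= sites[f"{ind}_gq"].to_numpy(dtype=float) >= cfg.gq_min

    callable_mask = parents_homref & dp_ok & gq_ok
    exclusions = {
        "parents_not_homref": int((~parents_homref).sum()),
        "DP": int((parents_homref & ~dp_ok).sum()),
        "GQ": int((parents_homref & dp_ok & ~gq_ok).sum()),
    }
    return CallableSummary(
        n_callable=int(callable_mask.sum()), n_total=len(sites), exclusions=exclusions
    )


def site_filter_fnr(cfg: FilterConfig | None = None) -> dict[str, float]:
    """Analytic per-annotation loss under the null distributions.

    MQRankSum and ReadPosRankSum are standard normal at true variants, so
    the loss is the two-tailed mass outside the thresholds.  FS is a
    phred-scaled uniform p-value, so P(FS > t) = 10^(-t/10).
    """
    cfg = cfg or FilterConfig()
    q_mqrs = stats.norm.cdf(cfg.mqrs_min) + stats.norm.sf(cfg.mqrs_max)
    q_rprs = stats.norm.cdf(cfg.rprs_min) + stats.norm.sf(cfg.rprs_max)
    q_fs = 10.0 ** (-cfg.fs_max / 10.0)
    return {"FS": float(q_fs), "MQRankSum": float(q_mqrs), "ReadPosRankSum": float(q_rprs)}


def estimate_fnr(
    sites: pd.DataFrame | None,
    cfg: FilterConfig | None = None,
    f_ab: float | None = None,
) -> FnrEstimate:
    """Estimate the false-negative rate of the cascade.

    ``f_site`` is analytic (see :func:`site_filter_fnr`).  ``f_ab`` is the
    observed fraction of transmitted-het sites (one parent HomRef, the
    other HomAlt, offspring Het) with offspring allele balance outside
    the AB window; such sites are guaranteed heterozygous in the
    offspring, so their AB distribution is that of a true het call.

    Provide ``f_ab`` directly when no transmitted-het sites are available.
    """
    cfg = cfg or FilterConfig()
    comp = site_filter_fnr(cfg)
    f_site = 1.0 - math.prod(1.0 - q for q in comp.values())

    if f_ab is None:
        if sites is None or len(sites) == 0:
            raise ValueError(
                "f_ab needs transmitted-het sites (HomRef x HomAlt -> Het); "
                "none supplied and no explicit f_ab given"
            )
        fa = (sites["father_gt"] == HOM_REF).to_numpy()
        fb = (sites["father_gt"] == HOM_ALT).to_numpy()
        ma = (sites["mother_gt"] == HOM_REF).to_numpy()
        mb = (sites["mother_gt"] == HOM_ALT).to_numpy()
        het = (sites["offspring_gt"] == HET).to_numpy()
        transmitted = ((fa & mb) | (fb & ma)) & het
        n_t = int(transmitted.sum())
        if n_t == 0:
            raise ValueError(
                "no transmitted-het sites in table; supply f_ab explicitly"
            )
        ref_n = sites.loc[transmitted, "offspring_ad_ref"].to_numpy(dtype=float)
        alt_n = sites.loc[transmitted, "offspring_ad_alt"].to_numpy(dtype=float)
        tot = ref_n + alt_n
        with np.errstate(invalid="ignore"):
            ab = np.where(tot > 0, alt_n / np.maximum(tot, 1), np.nan)
        outside = (tot == 0) | (ab < cfg.ab_min) | (ab > cfg.ab_max)
        f_ab = float(outside.sum() / n_t)

    if not 0.0 <= f_ab < 1.0:
        raise ValueError("f_ab must be in [0, 1)")
    return FnrEstimate(f_site=float(f_site), f_ab=float(f_ab), components=comp)


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    low, high = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    low = 0.0 if k == 0 else min(max(float(low), 0.0), 1.0)
    high = 1.0 if k == n else min(max(float(high), 0.0), 1.0)
    return low, high


def per_generation_rate(
    m: int, fnr: float, n_callable: float, conf: float = 0.95
) -> RateEstimate:
    """FNR-corrected per-generation mutation rate with a Wilson CI.

    mu = m / ((1 - fnr) * 2 * C); the CI is the Wilson interval on
    (m, 2C) divided by (1 - fnr).
    """
    if n_callable <= 0:
        raise ValueError("callable genome size must be positive")
    if not 0.0 <= fnr < 1.0:
        raise ValueError("fnr must be in [0, 1)")
    if m < 0:
        raise ValueError("DNM count must be non-negative")
    denom = 2.0 * n_callable
    mu = m / ((1.0 - fnr) * denom)
    low, high = wilson_interval(int(m), int(round(denom)), conf=conf)
    return RateEstimate(
        mu=float(mu),
        ci_low=float(low / (1.0 - fnr)),
        ci_high=float(high / (1.0 - fnr)),
        n_dnm=int(m),
        n_callable=int(round(n_callable)),
        fnr=float(fnr),
    )


def naive_yearly_rate(
    mu: float,
    father_age: float | None = None,
    mother_age: float | None = None,
    paternal_fraction: float = 0.5,
    generation_time: float | None = None,
) -> float:
    """Per-year rate: per-generation rate over the effective parental age.

    When both parental ages are known the divisor is the paternal-
    fraction-weighted mean age p*F + (1-p)*M; otherwise the species
    generation time is used.
    """
    if father_age is not None and mother_age is not None:
        if father_age <= 0 or mother_age <= 0:
            raise ValueError("parental ages must be positive")
        if not 0.0 <= paternal_fraction <= 1.0:
            raise ValueError("paternal_fraction must be in [0, 1]")
        divisor = paternal_fraction * father_age + (1.0 - paternal_fraction) * mother_age
    elif generation_time is not None and generation_time > 0:
        divisor = generation_time
    else:
        raise ValueError("need both parental ages or a positive generation time")
    return mu / divisor


def species_rate(trio_rates: list[RateEstimate], conf: float = 0.95) -> RateEstimate:
    """Species-level rate: mean of trio rates, CI by Wilson on pooled counts.

    The pooled interval uses (sum m, sum 2C) and the DNM-weighted mean FNR.
    """
    if not trio_rates:
        raise ValueError("no trio rates")
    mu = float(np.mean([r.mu for r in trio_rates]))
    m = sum(r.n_dnm for r in trio_rates)
    c = sum(r.n_callable for r in trio_rates)
    fnr = (
        float(np.average([r.fnr for r in trio_rates], weights=[max(r.n_dnm, 1) for r in trio_rates]))
    )
    low, high = wilson_interval(m, 2 * c, conf=conf)
    return RateEstimate(
        mu=mu,
        ci_low=low / (1.0 - fnr),
        ci_high=high / (1.0 - fnr),
        n_dnm=m,
        n_callable=c,
        fnr=fnr,
    )
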