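"""End-to-end orchestration: site tables -> DNMs -> rates -> observations.

Thin glue over the analysis modules, shared by the command line and the
reproducibility script.
"""

from __future__ import annotations

import pandas as pd

from gmrate.calling import FilterConfig, call_dnms, candidates_to_frame
from gmrate.rates import (
    RateEstimate,
    count_callable_sites,
    estimate_fnr,
    per_generation_rate,
)
from gmrate.simulate import Cohort


def analyze_trio(
    sites: pd.DataFrame, cfg: FilterConfig | None = None, trio_id: str = "trio"
) -> dict:
    """Call DNMs and estimate the FNR-corrected per-generation rate for one trio."""
    cfg = cfg or FilterConfig()
    candidates, audit = call_dnms(sites, cfg, trio_id=trio_id)
    callable_summary = count_callable_sites(sites, cfg)
    try:
        fnr = estimate_fnr(sites, cfg)
        fnr_total = fnr.fnr_total
    except ValueError:
        # no transmitted hets in this (small) table: site-filter component only
        fnr = estimate_fnr(None, cfg, f_ab=0.0)
        fnr_total = fnr.fnr_total
    rate = per_generation_rate(len(candidates), fnr_total, callable_summary.n_callable)
    return {
        "trio": trio_id,
        "candidates": candidates,
        "dnm_table": candidates_to_frame(candidates),
        "audit": audit,
        "callable": callable_summary,
        "fnr": fnr,
        "rate": rate,
    }


def analyze_cohort(cohort: Cohort, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-trio analysis of a simulated cohort.

    Returns a trio observation table (one row per trio) with DNM count
    ``m``, callable sites ``C``, ``fnr``, the rate and its CI, merged
    with the cohort's trio metadata — ready for the age model.
    """
    cfg = cfg or FilterConfig()
    rows = []
    for trio_id, sites in cohort.site_tables.items():
        res = analyze_trio(sites, cfg, trio_id=trio_id)
        r: RateEstimate = res["rate"]
        rows.append(
            {
                "trio": trio_id,
                "m": r.n_dnm,
                "C": r.n_callable,
                "fnr": r.fnr,
                "mu": r.mu,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
        )
    obs = pd.DataFrame(rows)
    return obs.merge(cohort.trio_meta, on="trio", how="left")
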