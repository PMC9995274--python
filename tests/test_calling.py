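"""Filter-cascade semantics: scalar predicates, vectorised calling, audit."""

import math

import numpy as np
import pandas as pd
import pytest

from gmrate.calling import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    FilterConfig,
    SiteRecord,
    apply_site_filters,
    apply_trio_filters,
    call_dnms,
    mean_trio_depth,
)
from tests.conftest import make_site_row, make_site_table

CFG = FilterConfig()


def site(**kw):
    return SiteRecord.from_row(make_site_row(**kw))


class TestSiteFilters:
    @pytest.mark.parametrize(
        "kw, expected_failed",
        [
            ({"QD": 1.5}, ["QD"]),
            ({"QD": 10.0, "FS": 3.0, "MQ": 60.0, "MQRankSum": 0.0,
              "ReadPosRankSum": 0.0, "SOR": 1.0}, []),
            ({"MQRankSum": 4.5}, ["MQRankSum"]),
            ({"MQRankSum": -2.5}, ["MQRankSum"]),
            ({"FS": 25.0}, ["FS"]),
            ({"MQ": 30.0}, ["MQ"]),
            ({"ReadPosRankSum": 3.5}, ["ReadPosRankSum"]),
            ({"SOR": 4.0}, ["SOR"]),
            ({"QD": 1.0, "FS": 30.0}, ["QD", "FS"]),
        ],
    )
    def test_threshold_semantics(self, kw, expected_failed):
        verdict = apply_site_filters(site(**kw), CFG)
        assert sorted(verdict.failed_filters) == sorted(expected_failed)
        assert verdict.passed == (not expected_failed)

    def test_boundary_values_pass(self):
        # thresholds themselves are not violations (QD < 2 fails, QD == 2 passes)
        v = apply_site_filters(site(QD=2.0, FS=20.0, MQ=40.0, MQRankSum=4.0,
                                    ReadPosRankSum=-3.0, SOR=3.0), CFG)
        assert v.passed

    def test_missing_annotation_passes_subfilter(self):
        v = apply_site_filters(site(MQRankSum=np.nan, ReadPosRankSum=np.nan), CFG)
        assert v.passed


class TestTrioFilters:
    def test_nominal_candidate_passes(self):
        v = apply_trio_filters(site(dp=60, ad_alt_offspring=30, gq=70), CFG, m_depth=60)
        assert v.passed

    def test_allele_balance_low(self):
        v = apply_trio_filters(site(dp=20, ad_alt_offspring=2, gq=70), CFG, m_depth=20)
        assert v.failed_filters == ["AB"]  # 2/20 = 0.10 < 0.30

    def test_allele_balance_bounds_inclusive(self):
        v = apply_trio_filters(site(dp=10, ad_alt_offspring=3), CFG, m_depth=10)
        assert "AB" not in v.failed_filters  # 0.30 exactly
        v = apply_trio_filters(site(dp=10, ad_alt_offspring=7), CFG, m_depth=10)
        assert "AB" not in v.failed_filters  # 0.70 exactly

    def test_parent_het_fails_mendelian(self):
        v = apply_trio_filters(site(gts=(HET, HOM_REF, HET)), CFG, m_depth=60)
        assert "mendelian" in v.failed_filters

    def test_no_informative_reads(self):
        row = make_site_row(dp=60)
        row["offspring_ad_ref"] = row["offspring_ad_alt"] = 0
        v = apply_trio_filters(SiteRecord.from_row(row), CFG, m_depth=60)
        assert "AB" in v.failed_filters
        assert v.reasons["AB"] == "no-informative-reads"

    def test_depth_window_strict(self):
        # DP exactly at 0.5 * m_depth is outside the open interval
        v = apply_trio_filters(site(dp=30), CFG, m_depth=60)
        assert "DP" in v.failed_filters
        v = apply_trio_filters(site(dp=120), CFG, m_depth=60)
        assert "DP" in v.failed_filters

    def test_gq_floor(self):
        v = apply_trio_filters(site(gq=59), CFG, m_depth=60)
        assert "GQ" in v.failed_filters
        v = apply_trio_filters(site(gq=60), CFG, m_depth=60)
        assert "GQ" not in v.failed_filters

    def test_m_depth_required(self):
        with pytest.raises(ValueError):
            apply_trio_filters(site(), CFG, m_depth=0)


def brute_force_pass(row, cfg: FilterConfig, m_depth: float) -> bool:
    """Independent site-by-site re-statement of the whole cascade."""
    def num(x):
        return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)

    if "," in str(row["alt"]) or len(str(row["alt"])) > 1:
        return False
    qd, fs, mq = num(row["QD"]), num(row["FS"]), num(row["MQ"])
    mqrs, rprs, sor = num(row["MQRankSum"]), num(row["ReadPosRankSum"]), num(row["SOR"])
    if qd is not None and qd < cfg.qd_min:
        return False
    if fs is not None and fs > cfg.fs_max:
        return False
    if mq is not None and mq < cfg.mq_min:
        return False
    if mqrs is not None and (mqrs < cfg.mqrs_min or mqrs > cfg.mqrs_max):
        return False
    if rprs is not None and (rprs < cfg.rprs_min or rprs > cfg.rprs_max):
        return False
    if sor is not None and sor > cfg.sor_max:
        return False
    if not (row["father_gt"] == HOM_REF and row["mother_gt"] == HOM_REF
            and row["offspring_gt"] == HET):
        return False
    tot = row["offspring_ad_ref"] + row["offspring_ad_alt"]
    if tot == 0:
        return False
    ab = row["offspring_ad_alt"] / tot
    if not (cfg.ab_min <= ab <= cfg.ab_max):
        return False
    for ind in ("father", "mother", "offspring"):
        if not (cfg.dp_low_factor * m_depth < row[f"{ind}_dp"] < cfg.dp_high_factor * m_depth):
            return False
        if row[f"{ind}_gq"] < cfg.gq_min:
            return False
    return True


def random_site_table(n, seed):
    rng = np.random.default_rng(seed)
    gts = np.array([HOM_REF, HET, HOM_ALT, MISSING])
    rows = []
    for i in range(n):
        row = {"chrom": "chr1", "pos": i, "ref": "A",
               "alt": rng.choice(["G", "C", "T", "G,C"], p=[0.6, 0.15, 0.15, 0.1]),
               "context": "unknown"}
        for ann, lo, hi in (("QD", 0, 35), ("FS", 0, 40), ("MQ", 20, 70),
                            ("MQRankSum", -5, 6), ("ReadPosRankSum", -5, 5),
                            ("SOR", 0, 5)):
            row[ann] = rng.uniform(lo, hi) if rng.random() > 0.1 else np.nan
        for ind in ("father", "mother", "offspring"):
            dp = int(rng.integers(5, 140))
            alt_n = int(rng.integers(0, dp + 1)) if rng.random() > 0.1 else 0
            row[f"{ind}_gt"] = rng.choice(gts, p=[0.55, 0.35, 0.05, 0.05])
            row[f"{ind}_dp"] = dp
            row[f"{ind}_ad_ref"] = dp - alt_n
            row[f"{ind}_ad_alt"] = alt_n
            row[f"{ind}_gq"] = int(rng.integers(0, 100))
        rows.append(row)
    return make_site_table(rows)


class TestCallDnms:
    def test_matches_brute_force_on_random_sites(self):
        sites = random_site_table(1000, seed=42)
        cands, _ = call_dnms(sites, CFG)
        got = {c.pos for c in cands}
        m_depth = mean_trio_depth(sites)
        expected = {int(r["pos"]) for _, r in sites.iterrows()
                    if brute_force_pass(r, CFG, m_depth)}
        assert got == expected

    def test_clean_simulation_perfect_recall(self, clean_trio):
        _, sites, truth = clean_trio
        cands, _ = call_dnms(sites, CFG)
        called = {c.pos for c in cands}
        planted = set(truth["pos"])
        # no error sites were planted: everything called must be a real DNM
        assert called <= planted
        # losses are only FNR-style (annotation/AB/DP/GQ draws), never extras
        assert len(planted - called) <= len(planted)
        assert len(called) > 0

    def test_planted_errors_all_rejected(self, noisy_trio):
        _, sites, truth = noisy_trio
        cands, _ = call_dnms(sites, CFG)
        assert {c.pos for c in cands} <= set(truth["pos"])

    def test_monotonicity_in_gq_threshold(self, noisy_trio):
        _, sites, _ = noisy_trio
        n60 = len(call_dnms(sites, FilterConfig(gq_min=60))[0])
        n50 = len(call_dnms(sites, FilterConfig(gq_min=50))[0])
        assert n50 >= n60

    def test_output_is_mendelian_pattern(self, noisy_trio):
        _, sites, _ = noisy_trio
        cands, _ = call_dnms(sites, CFG)
        for c in cands:
            assert c.site.father_gt == HOM_REF
            assert c.site.mother_gt == HOM_REF
            assert c.site.offspring_gt == HET
            assert CFG.ab_min <= c.allele_balance <= CFG.ab_max

    def test_empty_table(self):
        cands, audit = call_dnms(make_site_table([]), CFG)
        assert cands == []
        assert (audit["n_mendelian_removed"] == 0).all()

    def test_audit_counts_mendelian_losses(self):
        rows = [
            make_site_row(pos=0),                         # clean candidate
            make_site_row(pos=1, QD=1.0),                 # lost to QD
            make_site_row(pos=2, ad_alt_offspring=2, dp=40),  # lost to AB
            make_site_row(pos=3, gts=(HET, HOM_REF, HET)),    # not a violation
        ]
        cands, audit = call_dnms(make_site_table(rows), CFG)
        audit = audit.set_index("filter")["n_mendelian_removed"]
        assert audit["QD"] == 1
        assert audit["AB"] == 1
        assert len(cands) == 1 and cands[0].pos == 0

    def test_exclusion_list_hook(self):
        rows = [make_site_row(pos=0), make_site_row(pos=5)]
        cands, _ = call_dnms(make_site_table(rows), CFG,
                             exclude_positions={("chr1", 5)})
        assert [c.pos for c in cands] == [0]

    def test_multiallelic_skipped(self):
        rows = [make_site_row(pos=0, alt="G,T")]
        cands, audit = call_dnms(make_site_table(rows), CFG)
        assert cands == []
        assert audit.set_index("filter")["n_mendelian_removed"]["multiallelic"] == 1


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(ab_min=0.8, ab_max=0.2)
    with pytest.raises(ValueError):
        FilterConfig(dp_low_factor=3.0, dp_high_factor=1.0)
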