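import numpy as np
import pandas as pd
import pytest

from gmrate.calling import HET, HOM_ALT, HOM_REF, MISSING, SITE_COLUMNS
from gmrate.simulate import SimConfig, simulate_cohort, simulate_trio


def make_site_row(
    pos=0,
    ref="A",
    alt="G",
    gts=(HOM_REF, HOM_REF, HET),
    dp=60,
    ad_alt_offspring=None,
    gq=80,
    QD=15.0,
    FS=3.0,
    MQ=55.0,
    MQRankSum=0.0,
    ReadPosRankSum=0.0,
    SOR=1.0,
    context="unknown",
):
    """One site-table row with sensible defaults (a clean candidate DNM)."""
    row = {"chrom": "chr1", "pos": pos, "ref": ref, "alt": alt,
           "QD": QD, "FS": FS, "MQ": MQ, "MQRankSum": MQRankSum,
           "ReadPosRankSum": ReadPosRankSum, "SOR": SOR, "context": context}
    for ind, gt in zip(("father", "mother", "offspring"), gts):
        row[f"{ind}_gt"] = gt
        row[f"{ind}_dp"] = dp
        row[f"{ind}_gq"] = gq
        if gt == HET:
            alt_n = ad_alt_offspring if ad_alt_offspring is not None else dp // 2
            row[f"{ind}_ad_ref"] = dp - alt_n
            row[f"{ind}_ad_alt"] = alt_n
        elif gt == HOM_ALT:
            row[f"{ind}_ad_ref"] = 0
            row[f"{ind}_ad_alt"] = dp
        else:
            row[f"{ind}_ad_ref"] = dp
            row[f"{ind}_ad_alt"] = 0
    return row


def make_site_table(rows):
    return pd.DataFrame(rows, columns=list(SITE_COLUMNS) + ["context"])


@pytest.fixture(scope="session")
def clean_trio():
    """A trio with planted DNMs and no error sites (high rate, small table)."""
    cfg = SimConfig(n_sites=30_000, mu_true=5e-5, error_site_rate=0.0, seed=11)
    sites, truth = simulate_trio(cfg, "clean")
    return cfg, sites, truth


@pytest.fixture(scope="session")
def noisy_trio():
    """A trio with planted DNMs plus error sites carrying filter violations."""
    cfg = SimConfig(n_sites=30_000, mu_true=5e-5, error_site_rate=2e-3, seed=13)
    sites, truth = simulate_trio(cfg, "noisy")
    return cfg, sites, truth


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_sites=15_000, mu_true=5e-5, seed=17, sibling_share_prob=0.1)
    return cfg, simulate_cohort(cfg)
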