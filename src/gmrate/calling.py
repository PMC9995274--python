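"""Trio de novo mutation calling: the five-stage filter cascade.

A candidate DNM is a site where both parents are confidently homozygous
for the reference allele and the offspring is heterozygous, surviving

1. site-annotation filters (QD, FS, MQ, MQRankSum, ReadPosRankSum, SOR),
2. the Mendelian-violation pattern (HomRef x HomRef -> Het),
3. an offspring allelic-balance window (by default 30-70% of reads
   supporting the alternative allele),
4. a per-individual depth window relative to the trio's mean depth, and
5. a per-individual genotype-quality floor (by default GQ >= 60).

Site tables are pandas DataFrames with one row per genomic site (schema in
:data:`SITE_COLUMNS`).  The scalar functions :func:`apply_site_filters` and
:func:`apply_trio_filters` define the per-site semantics; :func:`call_dnms`
applies the identical predicates vectorised over a whole table and keeps a
per-filter audit trail of how many Mendelian-violation sites each filter
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

HOM_REF = "HomRef"
HET = "Het"
HOM_ALT = "HomAlt"
MISSING = "Missing"

GENOTYPES = (HOM_REF, HET, HOM_ALT, MISSING)

INDIVIDUALS = ("father", "mother", "offspring")

ANNOTATIONS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")

#: Column schema of a trio site table (one row per site, 0-based positions).
SITE_COLUMNS = (
    ["chrom", "pos", "ref", "alt"]
    + [f"{ind}_{f}" for ind in INDIVIDUALS for f in ("gt", "ad_ref", "ad_alt", "dp", "gq")]
    + list(ANNOTATIONS)
)


@dataclass(frozen=True)
class SiteRecord:
    """One genomic site with trio genotypes and site-level annotations.

    Positions are 0-based (converted from 1-based VCF on input).  Any
    annotation may be ``None`` (GATK omits RankSum annotations at some
    sites); a missing annotation never fails its sub-filter.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    father_gt: str = HOM_REF
    mother_gt: str = HOM_REF
    offspring_gt: str = HOM_REF
    father_ad: tuple[int, int] = (0, 0)
    mother_ad: tuple[int, int] = (0, 0)
    offspring_ad: tuple[int, int] = (0, 0)
    father_dp: int = 0
    mother_dp: int = 0
    offspring_dp: int = 0
    father_gq: int = 0
    mother_gq: int = 0
    offspring_gq: int = 0
    QD: Optional[float] = None
    FS: Optional[float] = None
    MQ: Optional[float] = None
    MQRankSum: Optional[float] = None
    ReadPosRankSum: Optional[float] = None
    SOR: Optional[float] = None

    @classmethod
    def from_row(cls, row) -> "SiteRecord":
        """Build a record from one site-table row (``pd.Series`` or dict)."""

        def ann(name):
            v = row[name]
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        return cls(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            father_gt=row["father_gt"],
            mother_gt=row["mother_gt"],
            offspring_gt=row["offspring_gt"],
            father_ad=(int(row["father_ad_ref"]), int(row["father_ad_alt"])),
            mother_ad=(int(row["mother_ad_ref"]), int(row["mother_ad_alt"])),
            offspring_ad=(int(row["offspring_ad_ref"]), int(row["offspring_ad_alt"])),
            father_dp=int(row["father_dp"]),
            mother_dp=int(row["mother_dp"]),
            offspring_dp=int(row["offspring_dp"]),
            father_gq=int(row["father_gq"]),
            mother_gq=int(row["mother_gq"]),
            offspring_gq=int(row["offspring_gq"]),
            QD=ann("QD"),
            FS=ann("FS"),
            MQ=ann("MQ"),
            MQRankSum=ann("MQRankSum"),
            ReadPosRankSum=ann("ReadPosRankSum"),
            SOR=ann("SOR"),
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the five-stage cascade.

    The defaults are the standard GATK-style hard filters for trio DNM
    calling: QD < 2, FS > 20, MQ < 40, MQRankSum outside (-2, 4),
    ReadPosRankSum outside (-3, 3), SOR > 3 at the site level; an
    inclusive 30-70% offspring allelic-balance window; per-individual
    depth strictly within (0.5, 2) times the trio mean depth; and a
    per-individual GQ floor of 60.
    """

    qd_min: float = 2.0
    fs_max: float = 20.0
    mq_min: float = 40.0
    mqrs_min: float = -2.0
    mqrs_max: float = 4.0
    rprs_min: float = -3.0
    rprs_max: float = 3.0
    sor_max: float = 3.0
    ab_min: float = 0.30
    ab_max: float = 0.70
    dp_low_factor: float = 0.5
    dp_high_factor: float = 2.0
    gq_min: float = 60.0

    def __post_init__(self):
        if not self.ab_min < self.ab_max:
            raise ValueError("ab_min must be < ab_max")
        if not self.dp_low_factor < self.dp_high_factor:
            raise ValueError("dp_low_factor must be < dp_high_factor")
        for name in (
            "qd_min", "fs_max", "mq_min", "mqrs_min", "mqrs_max",
            "rprs_min", "rprs_max", "sor_max", "ab_min", "ab_max",
            "dp_low_factor", "dp_high_factor", "gq_min",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")


@dataclass
class FilterVerdict:
    """Outcome of a filter stage: pass/fail plus every failed filter id."""

    passed: bool
    failed_filters: list[str] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        assert self.passed == (len(self.failed_filters) == 0)


@dataclass
class CandidateDNM:
    """A de novo mutation candidate surviving the full cascade."""

    site: SiteRecord
    trio_id: str
    allele_balance: float
    parent_of_origin: str = "unphased"  # {paternal, maternal, unphased}
    context: str = "unknown"  # trinucleotide centred on the site, or "unknown"

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos


def apply_site_filters(site: SiteRecord, cfg: FilterConfig | None = None) -> FilterVerdict:
    """Evaluate the site-level annotation filters on one site.

    A missing annotation passes its sub-filter: GATK leaves RankSum
    annotations absent where they cannot be computed, and discarding such
    sites would silently shrink the callable genome.
    """
    cfg = cfg or FilterConfig()
    failed: list[str] = []
    if site.QD is not None and site.QD < cfg.qd_min:
        failed.append("QD")
    if site.FS is not None and site.FS > cfg.fs_max:
        failed.append("FS")
    if site.MQ is not None and site.MQ < cfg.mq_min:
        failed.append("MQ")
    if site.MQRankSum is not None and not (cfg.mqrs_min <= site.MQRankSum <= cfg.mqrs_max):
        failed.append("MQRankSum")
    if site.ReadPosRankSum is not None and not (cfg.rprs_min <= site.ReadPosRankSum <= cfg.rprs_max):
        failed.append("ReadPosRankSum")
    if site.SOR is not None and site.SOR > cfg.sor_max:
        failed.append("SOR")
    return FilterVerdict(passed=not failed, failed_filters=failed)


def apply_trio_filters(
    site: SiteRecord, cfg: FilterConfig | None = None, m_depth: float = None
) -> FilterVerdict:
    """Evaluate the trio-level filters (Mendelian pattern, AB, DP, GQ).

    Parameters
    ----------
    m_depth
        Mean depth of the trio; the depth window is the open interval
        ``(dp_low_factor * m_depth, dp_high_factor * m_depth)`` applied to
        every individual.  The allelic-balance window is closed.
    """
    cfg = cfg or FilterConfig()
    if m_depth is None or m_depth <= 0:
        raise ValueError("m_depth (mean trio depth) must be positive")
    failed: list[str] = []
    reasons: dict[str, str] = {}

    mendelian = (
        site.father_gt == HOM_REF and site.mother_gt == HOM_REF and site.offspring_gt == HET
    )
    if not mendelian:
        failed.append("mendelian")

    ref_n, alt_n = site.offspring_ad
    if ref_n + alt_n == 0:
        failed.append("AB")
        reasons["AB"] = "no-informative-reads"
    else:
        ab = alt_n / (ref_n + alt_n)
        if not (cfg.ab_min <= ab <= cfg.ab_max):
            failed.append("AB")

    lo, hi = cfg.dp_low_factor * m_depth, cfg.dp_high_factor * m_depth
    if not all(lo < dp < hi for dp in (site.father_dp, site.mother_dp, site.offspring_dp)):
        failed.append("DP")

    if any(gq < cfg.gq_min for gq in (site.father_gq, site.mother_gq, site.offspring_gq)):
        failed.append("GQ")

    return FilterVerdict(passed=not failed, failed_filters=failed, reasons=reasons)


# Canonical audit order of the cascade.
FILTER_IDS = ("multiallelic", "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR",
              "mendelian", "AB", "DP", "GQ")


def mean_trio_depth(sites: pd.DataFrame) -> float:
    """Trio mean depth: mean of the three per-individual mean DP values."""
    return float(np.mean([sites[f"{ind}_dp"].mean() for ind in INDIVIDUALS]))


def _filter_masks(sites: pd.DataFrame, cfg: FilterConfig, m_depth: float) -> dict[str, np.ndarray]:
    """Boolean fail-mask per filter id, vectorised over the site table."""
    masks: dict[str, np.ndarray] = {}

    alt = sites["alt"].astype(str)
    masks["multiallelic"] = (alt.str.contains(",") | (alt.str.len() > 1)).to_numpy()

    qd = sites["QD"].to_numpy(dtype=float)
    fs = sites["FS"].to_numpy(dtype=float)
    mq = sites["MQ"].to_numpy(dtype=float)
    mqrs = sites["MQRankSum"].to_numpy(dtype=float)
    rprs = sites["ReadPosRankSum"].to_numpy(dtype=float)
    sor = sites["SOR"].to_numpy(dtype=float)
    # NaN comparisons are False, so missing annotations pass -- same rule
    # as the scalar path.
    masks["QD"] = qd < cfg.qd_min
    masks["FS"] = fs > cfg.fs_max
    masks["MQ"] = mq < cfg.mq_min
    masks["MQRankSum"] = (mqrs < cfg.mqrs_min) | (mqrs > cfg.mqrs_max)
    masks["ReadPosRankSum"] = (rprs < cfg.rprs_min) | (rprs > cfg.rprs_max)
    masks["SOR"] = sor > cfg.sor_max

    masks["mendelian"] = ~(
        (sites["father_gt"] == HOM_REF).to_numpy()
        & (sites["mother_gt"] == HOM_REF).to_numpy()
        & (sites["offspring_gt"] == HET).to_numpy()
    )

    ref_n = sites["offspring_ad_ref"].to_numpy(dtype=float)
    alt_n = sites["offspring_ad_alt"].to_numpy(dtype=float)
    tot = ref_n + alt_n
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(tot > 0, alt_n / np.maximum(tot, 1), np.nan)
    masks["AB"] = (tot == 0) | (ab < cfg.ab_min) | (ab > cfg.ab_max)

    lo, hi = cfg.dp_low_factor * m_depth, cfg.dp_high_factor * m_depth
    dp_ok = np.ones(len(sites), dtype=bool)
    gq_ok = np.ones(len(sites), dtype=bool)
    for ind in INDIVIDUALS:
        dp = sites[f"{ind}_dp"].to_numpy(dtype=float)
        dp_ok &= (dp > lo) & (dp < hi)
        gq_ok &= sites[f"{ind}_gq"].to_numpy(dtype=float) >= cfg.gq_min
    masks["DP"] = ~dp_ok
    masks["GQ"] = ~gq_ok
    return masks


def call_dnms(
    sites: pd.DataFrame,
    cfg: FilterConfig | None = None,
    trio_id: str = "trio",
    exclude_positions: Optional[set[tuple[str, int]]] = None,
    contexts: Optional[pd.Series] = None,
) -> tuple[list[CandidateDNM], pd.DataFrame]:
    """Run the full cascade over a trio site table.

    Parameters
    ----------
    sites
        Site table with the :data:`SITE_COLUMNS` schema.
    exclude_positions
        Optional set of ``(chrom, pos)`` to drop from the candidate list,
        standing in for an external cross-caller false-positive purge.
    contexts
        Optional per-row trinucleotide context strings aligned with
        ``sites`` (e.g. a ``context`` column from a simulated table).

    Returns
    -------
    (candidates, audit)
        ``candidates`` is the list of :class:`CandidateDNM`; ``audit`` is a
        DataFrame with one row per filter giving how many
        Mendelian-violation sites (both parents HomRef, offspring Het)
        that filter removed, plus the trio mean depth used.
    """
    cfg = cfg or FilterConfig()
    if len(sites) == 0:
        audit = pd.DataFrame({"filter": list(FILTER_IDS), "n_mendelian_removed": 0})
        audit.attrs["m_depth"] = float("nan")
        return [], audit

    m_depth = mean_trio_depth(sites)
    masks = _filter_masks(sites, cfg, m_depth)

    mendelian_pattern = ~masks["mendelian"]
    audit_rows = []
    for fid in FILTER_IDS:
        if fid == "mendelian":
            n = 0
        else:
            n = int((mendelian_pattern & masks[fid]).sum())
        audit_rows.append({"filter": fid, "n_mendelian_removed": n})
    audit = pd.DataFrame(audit_rows)
    audit.attrs["m_depth"] = m_depth

    passed = ~np.logical_or.reduce([masks[fid] for fid in FILTER_IDS])
    idx = np.flatnonzero(passed)

    excluded = exclude_positions or set()
    candidates: list[CandidateDNM] = []
    for i in idx:
        row = sites.iloc[i]
        if (str(row["chrom"]), int(row["pos"])) in excluded:
            continue
        rec = SiteRecord.from_row(row)
        ref_n, alt_n = rec.offspring_ad
        ctx = "unknown"
        if contexts is not None:
            ctx = str(contexts.iloc[i])
        elif "context" in sites.columns:
            ctx = str(row["context"])
        candidates.append(
            CandidateDNM(
                site=rec,
                trio_id=trio_id,
                allele_balance=alt_n / (ref_n + alt_n),
                context=ctx,
            )
        )
    return candidates, audit


def candidates_to_frame(candidates: list[CandidateDNM]) -> pd.DataFrame:
    """Tabulate candidates (1-based positions, VCF convention) for export."""
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos + 1,
                "ref": c.site.ref,
                "alt": c.site.alt,
                "trio": c.trio_id,
                "allele_balance": c.allele_balance,
                "parent_of_origin": c.parent_of_origin,
                "context": c.context,
            }
            for c in candidates
        ],
        columns=["chrom", "pos", "ref", "alt", "trio", "allele_balance",
                 "parent_of_origin", "context"],
    )
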