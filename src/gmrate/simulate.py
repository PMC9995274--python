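"""Synthetic trio cohorts with planted truth.

The generator emulates the statistical structure of a multi-species
pedigree sequencing study at desk scale so every downstream stage can be
tested against known truth:

* per-trio all-sites genotype tables with planted DNMs (both parents
  HomRef, offspring Het) at a known per-site rate and a known paternal
  fraction, transmitted heterozygote sites (HomRef x HomAlt -> Het)
  feeding the allelic-balance FNR component, and error sites carrying
  out-of-threshold annotations or non-Mendelian genotypes;
* annotation values at clean variant sites drawn from the null
  distributions the FNR model assumes (MQRankSum and ReadPosRankSum
  standard normal, FS a phred-scaled uniform p-value, QD/MQ/SOR safely
  inside thresholds);
* read-backed phasing evidence at the level of informative linkage
  observations (reads are not simulated);
* cohort metadata (correlated parental ages, generation times,
  life-history traits, domestication flags), a random ultrametric tree
  and piecewise-constant Ne trajectories per species;
* an optional counts mode in which per-trio DNM totals are drawn from
  the identity-link Poisson parental-age model
  m ~ Poisson(2 C (a_true + b_true * tau)) for parameter-recovery tests.

All output is deterministic under the config seed, byte for byte.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from gmrate.calling import HET, HOM_ALT, HOM_REF, SITE_COLUMNS
from gmrate.comparative import NeTrajectory
from gmrate.phasing import LinkageObservation, PhasingEvidence

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror a high-coverage trio design: ~67x depth, a
    per-generation rate around 1.2e-8 per site and a mammal-like
    paternal fraction of 0.7 (alpha ~ 2.3).  ``n_sites`` is the number
    of simulated genomic sites per trio — a scaled-down stand-in for a
    full genome chosen so a 50-trio cohort runs in seconds.
    """

    n_sites: int = 200_000
    mu_true: float = 1.2e-8
    paternal_fraction_true: float = 0.7
    mean_depth: float = 67.0
    gq_mean: float = 85.0
    gq_sd: float = 12.0
    error_site_rate: float = 2e-5
    het_site_rate: float = 5e-4
    sibling_share_prob: float = 0.02
    ab_noise: float = 0.0
    ts_fraction_true: float = 0.7  # transition share among planted DNMs (Ts/Tv ~ 2.3)
    cpg_fraction_true: float = 0.42  # CpG share among planted C:G > T:A DNMs
    seed: int = 0
    species_params: Optional[pd.DataFrame] = None
    n_tree_tips: int = 8
    crown_age: float = 400.0  # Myr
    age_correlation: float = 0.8
    phaseable_prob: float = 0.48
    obs_per_dnm: int = 3
    age_model_mode: bool = False
    a_true: float = 0.6e-8
    b_true: float = 0.4e-9
    ne_mean: float = 1e5
    ne_n_steps: int = 10
    ne_horizon_years: float = 2e6

    def __post_init__(self):
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not 0.0 <= self.mu_true < 1e-3:
            raise ValueError("mu_true must be in [0, 1e-3)")
        if not 0.0 <= self.paternal_fraction_true <= 1.0:
            raise ValueError("paternal_fraction_true must be in [0, 1]")


@dataclass
class TruthSet:
    """Planted truth of a simulated cohort."""

    planted_dnms: pd.DataFrame  # site, trio, parent_of_origin, shared_with_sibling, ...
    true_rates: pd.DataFrame  # species, mu_true, paternal_fraction_true
    true_age_model: tuple[float, float] | None = None  # (a_true, b_true)


@dataclass
class Cohort:
    """A simulated multi-species trio cohort."""

    site_tables: dict[str, pd.DataFrame]
    trio_meta: pd.DataFrame
    species_meta: pd.DataFrame
    tree: dendropy.Tree
    ne_trajectories: dict[str, NeTrajectory]
    truth: TruthSet
    evidence: dict[str, PhasingEvidence] = field(default_factory=dict)
    counts: pd.DataFrame | None = None  # counts-mode trio observations


def _trio_rng(seed: int, trio_id: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(trio_id.encode())]))


def _draw_gq(rng, n, cfg: SimConfig) -> np.ndarray:
    return np.clip(np.round(rng.normal(cfg.gq_mean, cfg.gq_sd, n)), 0, 99).astype(int)


def _het_alt_counts(rng, dp: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Alt-supporting read counts at a true het: binomial around AB=0.5.

    ``ab_noise`` > 0 adds between-site dispersion of the underlying
    allele balance via a symmetric Beta."""
    if cfg.ab_noise > 0:
        a = max(((1.0 / (4.0 * cfg.ab_noise**2)) - 1.0) / 2.0, 0.5)
        p = rng.beta(a, a, size=len(dp))
    else:
        p = np.full(len(dp), 0.5)
    return rng.binomial(dp, p)


def _clean_annotations(rng, n: int) -> dict[str, np.ndarray]:
    """Null annotation draws at well-behaved variant sites."""
    return {
        "QD": rng.uniform(10.0, 30.0, n),
        "FS": -10.0 * np.log10(rng.uniform(0.0, 1.0, n)),
        "MQ": rng.uniform(50.0, 60.0, n),
        "MQRankSum": rng.standard_normal(n),
        "ReadPosRankSum": rng.standard_normal(n),
        "SOR": rng.uniform(0.5, 2.0, n),
    }


def _random_alt(rng, ref: np.ndarray) -> np.ndarray:
    shift = rng.integers(1, 4, size=len(ref))
    ref_idx = np.searchsorted(_BASES, ref)
    return _BASES[(ref_idx + shift) % 4]


def _contexts(rng, ref: np.ndarray) -> np.ndarray:
    left = _BASES[rng.integers(0, 4, size=len(ref))]
    right = _BASES[rng.integers(0, 4, size=len(ref))]
    return np.char.add(np.char.add(left, ref), right)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _dnm_alts_contexts(rng, ref: np.ndarray, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Alt alleles and contexts with a realistic planted spectrum.

    Transitions are drawn with probability ``ts_fraction_true``;
    strand-collapsed C>T mutations get a CpG context with probability
    ``cpg_fraction_true`` (flanks are otherwise uniform)."""
    n = len(ref)
    is_ts = rng.random(n) < cfg.ts_fraction_true
    alt = np.array([_TRANSITION[r] for r in ref])
    tv_shift = rng.integers(0, 2, size=n)
    for i in np.flatnonzero(~is_ts):
        choices = [b for b in "ACGT" if b != ref[i] and b != _TRANSITION[ref[i]]]
        alt[i] = choices[tv_shift[i]]
    left = _BASES[rng.integers(0, 4, size=n)]
    right = _BASES[rng.integers(0, 4, size=n)]
    want_cpg = rng.random(n) < cfg.cpg_fraction_true
    non_g = np.array(["A", "C", "T"])
    non_c = np.array(["A", "G", "T"])
    for i in range(n):
        if ref[i] == "C" and alt[i] == "T":
            right[i] = "G" if want_cpg[i] else non_g[rng.integers(0, 3)]
        elif ref[i] == "G" and alt[i] == "A":
            left[i] = "C" if want_cpg[i] else non_c[rng.integers(0, 3)]
    return alt, np.char.add(np.char.add(left, ref), right)


ERROR_MODES = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR", "AB", "nonmendelian")


def simulate_trio(
    config: SimConfig, trio_id: str = "trio0"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one trio's all-sites table and its planted-DNM truth slice.

    Returns
    -------
    (sites, truth)
        ``sites`` follows the :data:`gmrate.calling.SITE_COLUMNS` schema
        plus a ``context`` column; ``truth`` has one row per planted DNM
        (pos, ref, alt, parent_of_origin, context, trio).
    """
    cfg = config
    rng = _trio_rng(cfg.seed, trio_id)
    n = cfg.n_sites
    if cfg.mu_true > 0 and cfg.mu_true * 2 * n < 1:
        warnings.warn(
            f"expected planted DNM count {cfg.mu_true * 2 * n:.3g} < 1 for trio "
            f"{trio_id}; most replicates will contain zero DNMs",
            stacklevel=2,
        )

    n_dnm = int(rng.binomial(2 * n, cfg.mu_true)) if cfg.mu_true > 0 else 0
    n_dnm = min(n_dnm, n)
    n_het = int(rng.binomial(n, cfg.het_site_rate))
    n_err = int(rng.binomial(n, cfg.error_site_rate))
    special = rng.choice(n, size=min(n_dnm + n_het + n_err, n), replace=False)
    dnm_idx = special[:n_dnm]
    het_idx = special[n_dnm : n_dnm + n_het]
    err_idx = special[n_dnm + n_het :]

    ref = _BASES[rng.integers(0, 4, size=n)]
    sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(n), "ref": ref, "alt": "."})
    for ind in ("father", "mother", "offspring"):
        dp = rng.poisson(cfg.mean_depth, n)
        sites[f"{ind}_gt"] = HOM_REF
        sites[f"{ind}_ad_ref"] = dp
        sites[f"{ind}_ad_alt"] = 0
        sites[f"{ind}_dp"] = dp
        sites[f"{ind}_gq"] = _draw_gq(rng, n, cfg)
    for ann in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR"):
        sites[ann] = np.nan
    sites["context"] = "unknown"

    def make_het_offspring(idx):
        dp = sites.loc[idx, "offspring_dp"].to_numpy()
        alt_n = _het_alt_counts(rng, dp, cfg)
        sites.loc[idx, "offspring_gt"] = HET
        sites.loc[idx, "offspring_ad_alt"] = alt_n
        sites.loc[idx, "offspring_ad_ref"] = dp - alt_n

    def set_annotations(idx, values):
        for ann, v in values.items():
            sites.loc[idx, ann] = v

    # --- planted DNMs: parents HomRef, offspring Het, clean annotations.
    if n_dnm:
        alt, ctx = _dnm_alts_contexts(rng, ref[dnm_idx], cfg)
        sites.loc[dnm_idx, "alt"] = alt
        sites.loc[dnm_idx, "context"] = ctx
        make_het_offspring(dnm_idx)
        set_annotations(dnm_idx, _clean_annotations(rng, n_dnm))
        origin = np.where(
            rng.random(n_dnm) < cfg.paternal_fraction_true, "paternal", "maternal"
        )
    else:
        alt, ctx, origin = np.array([]), np.array([]), np.array([])

    # --- transmitted hets: one parent HomAlt, offspring Het.
    if n_het:
        h_alt = _random_alt(rng, ref[het_idx])
        sites.loc[het_idx, "alt"] = h_alt
        sites.loc[het_idx, "context"] = _contexts(rng, ref[het_idx])
        father_is_carrier = rng.random(n_het) < 0.5
        for carrier, mask in (("father", father_is_carrier), ("mother", ~father_is_carrier)):
            sel = np.asarray(het_idx)[mask]
            dp = sites.loc[sel, f"{carrier}_dp"].to_numpy()
            sites.loc[sel, f"{carrier}_gt"] = HOM_ALT
            sites.loc[sel, f"{carrier}_ad_alt"] = dp
            sites.loc[sel, f"{carrier}_ad_ref"] = 0
        make_het_offspring(het_idx)
        set_annotations(het_idx, _clean_annotations(rng, n_het))

    # --- error sites: candidate-DNM lookalikes violating one filter.
    if n_err:
        e_alt = _random_alt(rng, ref[err_idx])
        sites.loc[err_idx, "alt"] = e_alt
        sites.loc[err_idx, "context"] = _contexts(rng, ref[err_idx])
        make_het_offspring(err_idx)
        set_annotations(err_idx, _clean_annotations(rng, n_err))
        modes = rng.integers(0, len(ERROR_MODES), size=n_err)
        bad = {
            "QD": 0.5, "FS": 60.0, "MQ": 20.0, "MQRankSum": 8.0,
            "ReadPosRankSum": -8.0, "SOR": 6.0,
        }
        for k, mode in enumerate(ERROR_MODES):
            sel = np.asarray(err_idx)[modes == k]
            if len(sel) == 0:
                continue
            if mode == "AB":
                dp = sites.loc[sel, "offspring_dp"].to_numpy()
                alt_n = rng.binomial(dp, 0.08)
                sites.loc[sel, "offspring_ad_alt"] = alt_n
                sites.loc[sel, "offspring_ad_ref"] = dp - alt_n
            elif mode == "nonmendelian":
                dp = sites.loc[sel, "offspring_dp"].to_numpy()
                sites.loc[sel, "offspring_gt"] = HOM_ALT
                sites.loc[sel, "offspring_ad_alt"] = dp
                sites.loc[sel, "offspring_ad_ref"] = 0
            else:
                sites.loc[sel, mode] = bad[mode]

    truth = pd.DataFrame(
        {
            "trio": trio_id,
            "chrom": "chr1",
            "pos": np.asarray(dnm_idx, dtype=int),
            "ref": ref[dnm_idx] if n_dnm else np.array([], dtype=str),
            "alt": alt,
            "parent_of_origin": origin,
            "context": ctx,
            "shared_with_sibling": False,
        }
    ).sort_values("pos").reset_index(drop=True)
    return sites[list(SITE_COLUMNS) + ["context"]], truth


def default_species_params(
    n_species: int = 8, trios_per_species: int = 2, seed: int = 0
) -> pd.DataFrame:
    """A small default species table spanning the four vertebrate groups."""
    rng = np.random.default_rng(seed)
    groups = ["mammals", "birds", "fishes", "reptiles"]
    rows = []
    for i in range(n_species):
        g = groups[i % 4]
        gen_time = float(rng.uniform(2.0, 20.0))
        rows.append(
            {
                "species": f"sp{i:02d}",
                "group": g,
                "generation_time": gen_time,
                "n_trios": trios_per_species,
                "mean_father_age": gen_time * float(rng.uniform(0.7, 1.3)),
                "domesticated": bool(i % 5 == 0),
                "body_mass_kg": float(10 ** rng.uniform(-1, 3)),
                "maturation_time": gen_time * 0.5,
                "fecundity": float(rng.uniform(1, 50)),
            }
        )
    return pd.DataFrame(rows)


def random_ultrametric_tree(labels: list[str], crown_age: float, rng) -> dendropy.Tree:
    """Random ultrametric tree by sequential pair joins at increasing ages."""
    ages = np.sort(rng.uniform(0.0, crown_age, size=len(labels) - 1))
    if len(labels) > 1:
        ages[-1] = crown_age
    items = [(lab, 0.0) for lab in labels]
    for age in ages:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (na, aa), (nb, ab) = items[i], items[j]
        merged = (f"({na}:{age - aa:.8f},{nb}:{age - ab:.8f})", float(age))
        items = [it for k, it in enumerate(items) if k not in (i, j)] + [merged]
    newick = items[0][0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


def _simulate_ne(rng, cfg: SimConfig) -> NeTrajectory:
    bounds = np.concatenate(
        [[0.0], np.sort(rng.uniform(0.0, cfg.ne_horizon_years, cfg.ne_n_steps - 1)),
         [cfg.ne_horizon_years]]
    )
    ne = cfg.ne_mean * np.exp(rng.normal(0.0, 0.5, cfg.ne_n_steps))
    return NeTrajectory(
        segments=[(float(bounds[i]), float(bounds[i + 1]), float(ne[i]))
                  for i in range(cfg.ne_n_steps)]
    )


def _simulate_evidence(rng, dnm_id: str, origin: str) -> PhasingEvidence:
    """Consistent linkage observations pointing at the true parent."""
    ref2, alt2 = "A", "G"
    # alt2 rides the DNM haplotype and is carried only by the true parent.
    father = ("A", "G") if origin == "paternal" else ("A", "A")
    mother = ("A", "G") if origin == "maternal" else ("A", "A")
    obs = []
    for k in range(3):
        present = bool(rng.random() < 0.7)
        allele = alt2 if present else ref2
        obs.append(LinkageObservation(dnm_allele_present=present, het_allele=allele,
                                      read_id=f"{dnm_id}_r{k}"))
    return PhasingEvidence(
        dnm_id=dnm_id,
        linked_pos=-1,
        offspring_alleles=(ref2, alt2),
        father_alleles=father,
        mother_alleles=mother,
        observations=obs,
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a multi-species cohort of trios.

    In the default sites mode each trio gets a full site table from
    :func:`simulate_trio`; sibling sharing duplicates DNMs between trios
    of the same species (modelled as full siblings).  In
    ``age_model_mode`` the per-trio DNM counts are drawn directly from
    the identity-link Poisson model and no site tables are built.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0F0]))
    species = cfg.species_params
    if species is None:
        species = default_species_params(cfg.n_tree_tips, seed=cfg.seed)
    if len(species) == 0:
        raise ValueError("species_params must be non-empty")
    if species["generation_time"].isna().any() or (species["generation_time"] <= 0).any():
        raise ValueError("every species needs a positive generation time")

    # trio metadata with correlated parental ages
    trio_rows = []
    for _, sp in species.iterrows():
        n_trios = int(sp.get("n_trios", 1))
        mean_age = float(sp.get("mean_father_age", sp["generation_time"]))
        for t in range(n_trios):
            father_age = max(float(rng.normal(mean_age, 0.15 * mean_age)), 0.2)
            resid_sd = 0.15 * mean_age * np.sqrt(max(1.0 - cfg.age_correlation**2, 1e-9))
            mother_age = max(
                cfg.age_correlation * father_age
                + (1.0 - cfg.age_correlation) * mean_age
                + float(rng.normal(0.0, resid_sd)),
                0.2,
            )
            trio_rows.append(
                {
                    "trio": f"{sp['species']}_t{t}",
                    "species": sp["species"],
                    "group": sp.get("group", "mammals"),
                    "family": f"{sp['species']}_fam",
                    "father_age": father_age,
                    "mother_age": mother_age,
                    "generation_time": float(sp["generation_time"]),
                    "paternal_fraction": cfg.paternal_fraction_true,
                }
            )
    trio_meta = pd.DataFrame(trio_rows)

    tree = random_ultrametric_tree(list(species["species"]), cfg.crown_age, rng)
    ne_trajectories = {
        str(sp): _simulate_ne(rng, cfg) for sp in species["species"]
    }

    site_tables: dict[str, pd.DataFrame] = {}
    truth_frames: list[pd.DataFrame] = []
    counts = None

    if cfg.age_model_mode:
        tau = (
            trio_meta["paternal_fraction"] * trio_meta["father_age"]
            + (1 - trio_meta["paternal_fraction"]) * trio_meta["mother_age"]
        )
        lam = 2.0 * cfg.n_sites * (cfg.a_true + cfg.b_true * tau)
        m = rng.poisson(lam.to_numpy())
        counts = trio_meta.assign(m=m, C=float(cfg.n_sites), fnr=0.0)
    else:
        with warnings.catch_warnings():
            # one cohort-level message instead of one warning per trio
            warnings.simplefilter("ignore", UserWarning)
            for _, tr in trio_meta.iterrows():
                sites, truth = simulate_trio(cfg, tr["trio"])
                site_tables[tr["trio"]] = sites
                truth_frames.append(truth)
        if cfg.mu_true > 0 and cfg.mu_true * 2 * cfg.n_sites < 1:
            warnings.warn(
                f"expected planted DNM count per trio is "
                f"{cfg.mu_true * 2 * cfg.n_sites:.3g} < 1; most trios will "
                "contain zero DNMs",
                stacklevel=2,
            )
        # sibling sharing within families
        if cfg.sibling_share_prob > 0 and truth_frames:
            truth_all = pd.concat(truth_frames, ignore_index=True)
            by_trio = dict(trio_meta.groupby("family")["trio"].apply(list))
            extra = []
            for fam, trios in by_trio.items():
                if len(trios) < 2:
                    continue
                fam_truth = truth_all[truth_all["trio"].isin(trios)]
                for i, row in fam_truth.iterrows():
                    if rng.random() >= cfg.sibling_share_prob:
                        continue
                    others = [t for t in trios if t != row["trio"]]
                    sib = others[int(rng.integers(0, len(others)))]
                    truth_all.loc[i, "shared_with_sibling"] = True
                    dup = row.copy()
                    dup["trio"] = sib
                    dup["shared_with_sibling"] = True
                    extra.append(dup)
                    _copy_dnm_site(site_tables[row["trio"]], site_tables[sib],
                                   int(row["pos"]), rng, cfg)
            truth_frames = [truth_all] + ([pd.DataFrame(extra)] if extra else [])

    planted = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(
            columns=["trio", "chrom", "pos", "ref", "alt", "parent_of_origin",
                     "context", "shared_with_sibling"]
        )
    )

    evidence: dict[str, PhasingEvidence] = {}
    if len(planted) and not cfg.age_model_mode:
        for k, row in planted.iterrows():
            if rng.random() < cfg.phaseable_prob:
                dnm_id = f"{row['trio']}:{row['pos']}"
                evidence[dnm_id] = _simulate_evidence(rng, dnm_id, row["parent_of_origin"])

    truth = TruthSet(
        planted_dnms=planted,
        true_rates=pd.DataFrame(
            {
                "species": species["species"],
                "mu_true": cfg.mu_true,
                "paternal_fraction_true": cfg.paternal_fraction_true,
            }
        ),
        true_age_model=(cfg.a_true, cfg.b_true) if cfg.age_model_mode else None,
    )
    return Cohort(
        site_tables=site_tables,
        trio_meta=trio_meta,
        species_meta=species,
        tree=tree,
        ne_trajectories=ne_trajectories,
        truth=truth,
        evidence=evidence,
        counts=counts,
    )


def _copy_dnm_site(src: pd.DataFrame, dst: pd.DataFrame, pos: int, rng, cfg: SimConfig):
    """Plant the same DNM in a sibling's table (re-drawing its read support)."""
    row = src.loc[src["pos"] == pos].iloc[0]
    j = dst.index[dst["pos"] == pos][0]
    dst.loc[j, ["ref", "alt", "context"]] = row[["ref", "alt", "context"]].to_numpy()
    dp = int(dst.loc[j, "offspring_dp"])
    alt_n = int(_het_alt_counts(rng, np.array([dp]), cfg)[0])
    dst.loc[j, "offspring_gt"] = HET
    dst.loc[j, "offspring_ad_alt"] = alt_n
    dst.loc[j, "offspring_ad_ref"] = dp - alt_n
    for ann, v in _clean_annotations(rng, 1).items():
        dst.loc[j, ann] = v[0]


# ----------------------------------------------------------------------
# fixture emission
# ----------------------------------------------------------------------

def write_fixtures(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to disk: per-trio VCF, metadata/truth TSV, Newick, Ne TSV.

    Files round-trip losslessly through :mod:`gmrate.io` readers.
    """
    from gmrate import io as gio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for trio_id, sites in cohort.site_tables.items():
        p = out / f"{trio_id}.vcf"
        gio.write_trio_vcf(sites, p, trio_id=trio_id)
        paths[f"vcf:{trio_id}"] = p
    paths["trio_meta"] = out / "trio_meta.tsv"
    cohort.trio_meta.to_csv(paths["trio_meta"], sep="\t", index=False)
    paths["species_meta"] = out / "species_meta.tsv"
    cohort.species_meta.to_csv(paths["species_meta"], sep="\t", index=False)
    paths["truth"] = out / "truth_dnms.tsv"
    cohort.truth.planted_dnms.to_csv(paths["truth"], sep="\t", index=False)
    paths["tree"] = out / "species_tree.nwk"
    cohort.tree.write(path=str(paths["tree"]), schema="newick", suppress_rooting=True)
    paths["ne"] = out / "ne_trajectories.tsv"
    gio.write_ne_tsv(cohort.ne_trajectories, paths["ne"])
    if cohort.counts is not None:
        paths["counts"] = out / "trio_counts.tsv"
        cohort.counts.to_csv(paths["counts"], sep="\t", index=False)
    return paths
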