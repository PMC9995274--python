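"""Read-backed parent-of-origin phasing and the male mutation bias alpha.

A DNM sits on one of the offspring's two haplotypes.  Reads (or read
pairs) that span both the DNM and a nearby heterozygous site reveal which
allele of that het site shares the DNM haplotype; if exactly one parent
carries that allele, the DNM haplotype — and hence the mutation — came
from that parent.  The conflict rule is strict: any observation that
contradicts the others, or an allele traceable to neither parent, leaves
the DNM unphased, because a false phase biases alpha more than a lost
observation.

alpha = n_paternal / n_maternal, with a confidence interval obtained by
the monotone transform p -> p/(1-p) of the Wilson interval on the
paternal fraction p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, sqrt
from typing import Iterable, Sequence

import pandas as pd

from gmrate.rates import wilson_interval

PATERNAL = "paternal"
MATERNAL = "maternal"
UNPHASED = "unphased"


@dataclass(frozen=True)
class LinkageObservation:
    """One read(-pair) spanning the DNM and a linked offspring het site.

    ``dnm_allele_present`` says whether this read carries the DNM allele;
    ``het_allele`` is the base the read carries at the linked het site.
    """

    dnm_allele_present: bool
    het_allele: str
    read_id: str = ""


@dataclass
class PhasingEvidence:
    """All linkage observations tying one DNM to one linked het site.

    Parental and offspring genotypes at the linked site are allele pairs,
    e.g. ``("A", "G")``.  The linked site must be heterozygous in the
    offspring.
    """

    dnm_id: str
    linked_pos: int
    offspring_alleles: tuple[str, str]
    father_alleles: tuple[str, str]
    mother_alleles: tuple[str, str]
    observations: list[LinkageObservation] = field(default_factory=list)

    def __post_init__(self):
        if self.offspring_alleles[0] == self.offspring_alleles[1]:
            raise ValueError("linked site must be heterozygous in the offspring")


@dataclass
class PhasedCounts:
    n_paternal: int
    n_maternal: int
    n_unphased: int = 0
    group: str = ""

    def __post_init__(self):
        if min(self.n_paternal, self.n_maternal, self.n_unphased) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class AlphaEstimate:
    alpha: float
    paternal_fraction: float
    ci_low: float
    ci_high: float
    n_phased: int
    low_confidence: bool = False
    group: str = ""


def _dnm_haplotype_allele(obs: LinkageObservation, offspring_alleles: tuple[str, str]) -> str:
    """The het-site allele on the same haplotype as the DNM.

    A read carrying the DNM allele shows it directly; a read without the
    DNM allele shows the other haplotype, so the DNM haplotype carries
    the offspring's other allele at the linked site.
    """
    a, b = offspring_alleles
    if obs.dnm_allele_present:
        return obs.het_allele
    return b if obs.het_allele == a else a


def phase_dnm(evidence: PhasingEvidence) -> str:
    """Assign the parental origin of one DNM from its linkage evidence.

    Returns ``"paternal"``, ``"maternal"`` or ``"unphased"``.  No
    observations, alleles carried by both or neither parent, or
    observations pointing at different parents all yield ``"unphased"``.
    """
    if not evidence.observations:
        return UNPHASED
    votes: set[str] = set()
    for obs in evidence.observations:
        allele = _dnm_haplotype_allele(obs, evidence.offspring_alleles)
        if allele not in evidence.offspring_alleles:
            return UNPHASED  # read allele inconsistent with offspring genotype
        in_father = allele in evidence.father_alleles
        in_mother = allele in evidence.mother_alleles
        if in_father and in_mother:
            return UNPHASED  # uninformative allele: cannot rule either parent out
        if not in_father and not in_mother:
            return UNPHASED  # untraceable allele: inconsistent inheritance
        votes.add(PATERNAL if in_father else MATERNAL)
    if len(votes) != 1:
        return UNPHASED
    return votes.pop()


def phase_table(evidences: Iterable[PhasingEvidence]) -> pd.DataFrame:
    """Phase a collection of DNMs; one row per DNM with its origin."""
    rows = [{"dnm_id": ev.dnm_id, "parent_of_origin": phase_dnm(ev)} for ev in evidences]
    return pd.DataFrame(rows, columns=["dnm_id", "parent_of_origin"])


def counts_from_origins(origins: Sequence[str], group: str = "") -> PhasedCounts:
    return PhasedCounts(
        n_paternal=sum(o == PATERNAL for o in origins),
        n_maternal=sum(o == MATERNAL for o in origins),
        n_unphased=sum(o == UNPHASED for o in origins),
        group=group,
    )


def alpha_from_counts(
    counts: PhasedCounts, conf: float = 0.95, min_phased: int = 30
) -> AlphaEstimate:
    """Male-to-female mutation contribution ratio with a Wilson-based CI.

    alpha = n_pat / n_mat.  The CI is the Wilson interval (L, U) on the
    paternal fraction p, mapped through the monotone transform
    p -> p/(1-p).  Groups with fewer than ``min_phased`` phased mutations
    are flagged low-confidence but still computed.
    """
    n = counts.n_paternal + counts.n_maternal
    if n == 0:
        raise ValueError("no phased mutations")
    p = counts.n_paternal / n
    low, high = wilson_interval(counts.n_paternal, n, conf=conf)
    alpha = counts.n_paternal / counts.n_maternal if counts.n_maternal > 0 else inf
    ci_low = low / (1.0 - low) if low < 1.0 else inf
    ci_high = high / (1.0 - high) if high < 1.0 else inf
    return AlphaEstimate(
        alpha=float(alpha),
        paternal_fraction=float(p),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_phased=n,
        low_confidence=n < min_phased,
        group=counts.group,
    )


def sibling_sharing(
    dnm_tables: dict[str, pd.DataFrame],
    families: dict[str, Sequence[str]],
) -> tuple[float, float]:
    """Fraction of DNM instances shared between full siblings.

    Parameters
    ----------
    dnm_tables
        trio id -> DNM table with columns (chrom, pos, alt).
    families
        family id -> trio ids of offspring sharing both parents.

    Returns
    -------
    (shared_fraction, standard_error)
        A DNM instance counts as shared when the identical
        (chrom, pos, alt) appears in at least two siblings of the family.
        The denominator is every DNM instance in families with >= 2
        siblings; the s.e. is the binomial sqrt(f(1-f)/n).
    """
    n_total = 0
    n_shared = 0
    any_multi = False
    for trios in families.values():
        trios = [t for t in trios if t in dnm_tables]
        if len(trios) < 2:
            continue
        any_multi = True
        keys_per_trio = {
            t: set(zip(dnm_tables[t]["chrom"], dnm_tables[t]["pos"], dnm_tables[t]["alt"]))
            for t in trios
        }
        for t in trios:
            others = set().union(*(keys_per_trio[o] for o in trios if o != t))
            for key in keys_per_trio[t]:
                n_total += 1
                if key in others:
                    n_shared += 1
    if not any_multi:
        raise ValueError("no families with >= 2 sequenced siblings")
    if n_total == 0:
        return 0.0, 0.0
    f = n_shared / n_total
    se = sqrt(f * (1.0 - f) / n_total)
    return float(f), float(se)
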