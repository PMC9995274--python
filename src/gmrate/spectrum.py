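"""Strand-collapsed mutation-spectrum classification and tests.

Point mutations are collapsed to the six classes A>C, A>G, A>T, C>A,
C>G, C>T by complementing G>* and T>* mutations so the reference base is
always A or C.  CpG status is assessed in the original strand
orientation: a C followed by a G, or a G preceded by a C.
Strong-to-weak here flags the C:G > T:A transition (three hydrogen bonds
to two), the dominant deamination-driven class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gmrate.rates import wilson_interval

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

MUTATION_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")

VERTEBRATE_GROUPS = ("mammals", "birds", "fishes", "reptiles")


@dataclass(frozen=True)
class MutationClass:
    mutation_class: str  # one of MUTATION_CLASSES
    is_transition: bool
    is_cpg: bool
    is_strong_to_weak: bool
    cpg_known: bool = True


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_mutation(ref: str, alt: str, context: str = "unknown") -> MutationClass:
    """Classify a point mutation into its strand-collapsed class.

    Parameters
    ----------
    ref, alt
        Single bases, ref != alt.
    context
        Trinucleotide centred on the mutated base (middle base == ref),
        or ``"unknown"``.  CpG status needs the context; without it the
        class is still assigned but ``cpg_known`` is False.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"ambiguous or non-ACGT base in {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")

    has_context = isinstance(context, str) and len(context) == 3 and all(
        b in _COMPLEMENT for b in context.upper()
    )
    cpg = False
    if has_context:
        ctx = context.upper()
        if ctx[1] != ref:
            raise ValueError(f"context {ctx} does not match ref {ref}")
        # CpG in strand orientation: C followed by G, or G preceded by C.
        if ref == "C":
            cpg = ctx[2] == "G"
        elif ref == "G":
            cpg = ctx[0] == "C"

    # Collapse to the A/C reference frame.
    if ref in ("G", "T"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    mclass = f"{ref}>{alt}"
    transition = mclass in ("A>G", "C>T")
    return MutationClass(
        mutation_class=mclass,
        is_transition=transition,
        is_cpg=cpg,
        is_strong_to_weak=mclass == "C>T",
        cpg_known=has_context,
    )


@dataclass
class SpectrumTable:
    """6 x group contingency counts plus summary proportions."""

    counts: pd.DataFrame  # rows = MUTATION_CLASSES, columns = groups
    ts_tv: float
    ts_tv_ci: tuple[float, float]
    strong_to_weak: float
    strong_to_weak_ci: tuple[float, float]
    cpg_share: float  # CpG fraction among C:G > T:A, context-known only
    cpg_share_ci: tuple[float, float]
    n_context_unknown: int


def build_spectrum_table(dnms: pd.DataFrame, group_col: str = "group") -> SpectrumTable:
    """Tabulate a DNM table (columns ref, alt, context, group) into a spectrum.

    Ts/Tv, the strong-to-weak (C:G > T:A) proportion and the CpG share
    among strong-to-weak mutations are reported with 95% Wilson CIs.
    DNMs with unknown context keep their class but are excluded (and
    counted) from CpG proportions.
    """
    if dnms is None or len(dnms) == 0:
        raise ValueError("empty DNM table")
    classes = [
        classify_mutation(r, a, c)
        for r, a, c in zip(dnms["ref"], dnms["alt"], dnms.get("context", ["unknown"] * len(dnms)))
    ]
    groups = dnms[group_col].astype(str) if group_col in dnms.columns else pd.Series(
        ["all"] * len(dnms)
    )
    tab = pd.crosstab(
        pd.Series([c.mutation_class for c in classes], name="class"),
        pd.Series(groups.to_numpy(), name="group"),
    ).reindex(index=list(MUTATION_CLASSES), fill_value=0)

    n = len(classes)
    n_ts = sum(c.is_transition for c in classes)
    n_tv = n - n_ts
    ts_tv = n_ts / n_tv if n_tv > 0 else np.inf
    lo, hi = wilson_interval(n_ts, n)
    ts_tv_ci = (lo / (1 - lo) if lo < 1 else np.inf, hi / (1 - hi) if hi < 1 else np.inf)

    n_sw = sum(c.is_strong_to_weak for c in classes)
    sw = n_sw / n
    sw_ci = wilson_interval(n_sw, n)

    known_sw = [c for c in classes if c.is_strong_to_weak and c.cpg_known]
    n_unknown = sum(not c.cpg_known for c in classes)
    if known_sw:
        n_cpg = sum(c.is_cpg for c in known_sw)
        cpg = n_cpg / len(known_sw)
        cpg_ci = wilson_interval(n_cpg, len(known_sw))
    else:
        cpg, cpg_ci = np.nan, (np.nan, np.nan)

    return SpectrumTable(
        counts=tab,
        ts_tv=float(ts_tv),
        ts_tv_ci=ts_tv_ci,
        strong_to_weak=float(sw),
        strong_to_weak_ci=sw_ci,
        cpg_share=float(cpg),
        cpg_share_ci=cpg_ci,
        n_context_unknown=int(n_unknown),
    )


def drop_zero_margins(table: pd.DataFrame) -> pd.DataFrame:
    """Drop all-zero rows/columns (unobserved classes or groups)."""
    return table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]


def chi_square_test(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of homogeneity, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.sum(axis=0).min() <= 0 or arr.sum(axis=1).min() <= 0:
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(dof), float(p)


def class_vs_rest_test(table: pd.DataFrame, mutation_class: str) -> tuple[float, int, float]:
    """2 x k test of one mutation class against all others across groups."""
    if mutation_class not in table.index:
        raise ValueError(f"unknown class {mutation_class}")
    target = table.loc[mutation_class]
    rest = table.sum(axis=0) - target
    return chi_square_test(pd.DataFrame([target, rest]))


def class_anova(rates: pd.Series | np.ndarray, groups) -> tuple[float, int, int, float]:
    """One-way ANOVA of species-level mean rates across vertebrate groups.

    Returns (F, df_between, df_within, p).
    """
    rates = np.asarray(rates, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [rates[groups == g] for g in labels]
    df_between = len(labels) - 1
    df_within = len(rates) - len(labels)
    if df_within <= 0:
        raise ValueError("no within-group degrees of freedom")
    f, p = stats.f_oneway(*samples)
    return float(f), int(df_between), int(df_within), float(p)
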