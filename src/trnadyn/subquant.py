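"""Substitution quantification: site labeling, ranked weighting, z-categories.

Every alignment column is treated as an independent locus.  The most
frequent base is the dominant (conserved) state "C"; every other base is a
transition "S" (same purine/pyrimidine class) or a transversion "V"
(cross-class) relative to it.  Columns containing gaps are indel loci:
a deletion locus "D" when gaps are rarer than the dominant base, an
insertion locus "I" when gaps are the majority state (the dominant state
is then the gap and the minority base carriers are the insertions).

When two or more bases tie for the maximum the dominant is the minimal
IUPAC degeneracy code covering the tie set; exactly one member of the tie
set — the base earliest in A<C<G<T order — is the conserved designate, the
other members are classified as substitutions relative to it.

Category totals are converted to weights drawn from the fixed ladder
0.00/0.25/0.50/0.75/1.00: the most frequent category gets the smallest
weight and the rarest the largest.  When only substitutions are present
the fixed weights 0.25 (transition) and 0.50 (transversion) apply instead.
Per-tRNA weighted totals are z-scored within each cohort and every tRNA is
put in one of four variability categories by the signs of its two z-scores
(hyper/hyper, hypo/hypo, hyper/hypo, hypo/hyper), with |z| >= 1 flagged
extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cloverleaf import DOMAIN_GROUPS, TALLY_DOMAINS
from .msa import GeneAlignment
from .seqio import SET_TO_IUPAC

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

CATEGORIES = ("C", "S", "V", "D", "I")
SNP_CATEGORIES = frozenset("SV")
INDEL_CATEGORIES = frozenset("DI")

WEIGHT_LADDER = (0.00, 0.25, 0.50, 0.75, 1.00)
FIXED_SUBSTITUTION_WEIGHTS = {"C": 0.00, "S": 0.25, "V": 0.50}


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or \
        (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass
class ColumnClassification:
    """Dominant state and per-species category labels for one column."""

    column_index: int                  # 1-based
    dominant: str                      # IUPAC base, possibly degenerate, or '-'
    labels: dict[str, str]             # species_id -> category
    counts: dict[str, int]             # category -> count

    def __post_init__(self) -> None:
        tally = Counter(self.labels.values())
        if dict(tally) != {k: v for k, v in self.counts.items() if v}:
            raise ValueError("counts inconsistent with labels")


def classify_column(column: Sequence[tuple[str, str]],
                    column_index: int = 0) -> ColumnClassification:
    """Classify one alignment column of (species_id, base-or-gap) entries."""
    if len(column) < 2:
        raise ValueError("column needs at least two entries")
    bases = {}
    for sp, b in column:
        b = b.upper()
        if b not in "ACGT-":
            raise ValueError(f"unsupported state {b!r} in column")
        bases[sp] = b
    base_counts = Counter(b for b in bases.values() if b != "-")
    gap_count = sum(b == "-" for b in bases.values())
    if not base_counts:
        raise ValueError("vacuous column: all gaps")
    top = max(base_counts.values())
    labels: dict[str, str] = {}
    if gap_count > top:
        # insertion locus: the gap is the dominant (ancestral-absence) state
        dominant = "-"
        for sp, b in bases.items():
            labels[sp] = "C" if b == "-" else "I"
    else:
        tie = frozenset(b for b, c in base_counts.items() if c == top)
        dominant = SET_TO_IUPAC[tie]
        designate = min(tie)  # A < C < G < T
        for sp, b in bases.items():
            if b == "-":
                labels[sp] = "D"
            elif b == designate:
                labels[sp] = "C"
            else:
                labels[sp] = "S" if is_transition(b, designate) else "V"
    counts = dict(Counter(labels.values()))
    return ColumnClassification(column_index, dominant, labels, counts)


def classify_alignment(alig: GeneAlignment) -> list[ColumnClassification]:
    """Classify every column of a gene alignment (1-based column indices)."""
    return [classify_column(alig.column(j), j)
            for j in range(1, alig.length + 1)]


@dataclass
class CategoryWeights:
    """Category -> weight map drawn from the fixed 0.00..1.00 ladder."""

    weight_of: dict[str, float]

    def __post_init__(self) -> None:
        for cat, w in self.weight_of.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if w not in WEIGHT_LADDER:
                raise ValueError(f"weight {w} not on the fixed ladder")

    def __getitem__(self, cat: str) -> float:
        return self.weight_of.get(cat, 0.0)


def assign_weights(totals: Mapping[str, int],
                   substitution_only: bool = False) -> CategoryWeights:
    """Rank categories by total count and assign the fixed weight ladder.

    The most frequent category receives 0.00 and the rarest the largest
    weight in use; ties are broken by the fixed category order C,V,S,D,I.
    With ``substitution_only`` the fixed weights C=0.00, S=0.25, V=0.50 are
    used regardless of the counts.
    """
    if not totals:
        raise ValueError("empty category totals")
    if substitution_only:
        return CategoryWeights(dict(FIXED_SUBSTITUTION_WEIGHTS))
    if len(totals) > len(WEIGHT_LADDER):
        raise ValueError("more than five categories")
    fixed_rank = {c: i for i, c in enumerate(("C", "V", "S", "D", "I"))}
    ranked = sorted(totals, key=lambda c: (-totals[c], fixed_rank.get(c, 99)))
    return CategoryWeights(
        {cat: WEIGHT_LADDER[i] for i, cat in enumerate(ranked)})


def weights_for(totals: Mapping[str, int]) -> CategoryWeights:
    """Weighting rule dispatch: fixed substitution weights when the observed
    mutation categories are transitions/transversions only, the count-ranked
    ladder otherwise."""
    mutated = {c for c, n in totals.items() if c != "C" and n > 0}
    return assign_weights(totals, substitution_only=mutated <= {"S", "V"})


def category_totals(classifications: Iterable[ColumnClassification]
                    ) -> Counter:
    """Summed per-category counts over a set of classified columns."""
    totals: Counter = Counter()
    for cls in classifications:
        totals.update(cls.labels.values())
    return totals


@dataclass
class VariabilityProfile:
    """Weighted mutation totals for one tRNA (and its domains)."""

    isotype: str
    snp_total: float                       # summed S+V weights
    indel_total: float                     # summed D+I weights
    domain_snp: dict[str, float]           # tally domain -> weighted SNPs
    domain_indel: dict[str, float]         # tally domain -> weighted indels
    per_species_ratio: dict[str, float]    # weighted sum / alignment length
    n_columns: int
    n_species: int

    @property
    def total(self) -> float:
        return self.snp_total + self.indel_total

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(list(self.per_species_ratio.values())))


def weighted_profile(classifications: Sequence[ColumnClassification],
                     weights: CategoryWeights,
                     column_domain: Sequence[str],
                     isotype: str = "") -> VariabilityProfile:
    """Aggregate weighted category labels per tRNA, domain and species."""
    if len(column_domain) != len(classifications):
        raise ValueError("domain labels missing for some columns")
    snp_total = 0.0
    indel_total = 0.0
    domain_snp = {d: 0.0 for d in TALLY_DOMAINS}
    domain_indel = {d: 0.0 for d in TALLY_DOMAINS}
    species = sorted({sp for cls in classifications for sp in cls.labels})
    per_species = {sp: 0.0 for sp in species}
    for cls, pos_label in zip(classifications, column_domain):
        group = DOMAIN_GROUPS.get(pos_label, pos_label)
        for sp, lab in cls.labels.items():
            w = weights[lab]
            per_species[sp] += w
            if lab in SNP_CATEGORIES:
                snp_total += w
                domain_snp[group] += w
            elif lab in INDEL_CATEGORIES:
                indel_total += w
                domain_indel[group] += w
    n_cols = len(classifications)
    ratios = {sp: (v / n_cols if n_cols else 0.0)
              for sp, v in per_species.items()}
    return VariabilityProfile(isotype, snp_total, indel_total, domain_snp,
                              domain_indel, ratios, n_cols, len(species))


@dataclass(frozen=True)
class ZCategory:
    z_ci: float
    z_ht: float
    category: int          # 1..4
    extreme: bool          # |z| >= 1 in either cohort


def zscore_categorize(totals_ci: Mapping[str, float],
                      totals_ht: Mapping[str, float]
                      ) -> dict[str, ZCategory]:
    """Z-score per-tRNA totals within each cohort and assign categories.

    Category 1: hyper-variable in both cohorts; 2: hypo in both; 3: hyper
    in the full cohort but hypo in the sublineage; 4: the reverse.  Hyper
    and hypo are the sign of the z-score (z >= 0 counts as hyper); tRNAs
    beyond the +/-1 standard limits are flagged extreme.
    """
    if set(totals_ci) != set(totals_ht):
        raise ValueError("cohort vectors indexed by different tRNA sets")
    names = sorted(totals_ci)
    out: dict[str, ZCategory] = {}
    zs = {}
    for label, totals in (("ci", totals_ci), ("ht", totals_ht)):
        x = np.array([totals[n] for n in names], dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"degenerate cohort vector ({label}): zero SD")
        zs[label] = (x - x.mean()) / sd
    for i, name in enumerate(names):
        z_ci, z_ht = float(zs["ci"][i]), float(zs["ht"][i])
        hyper_ci, hyper_ht = z_ci >= 0, z_ht >= 0
        if hyper_ci and hyper_ht:
            cat = 1
        elif not hyper_ci and not hyper_ht:
            cat = 2
        elif hyper_ci:
            cat = 3
        else:
            cat = 4
        out[name] = ZCategory(z_ci, z_ht, cat,
                              abs(z_ci) >= 1 or abs(z_ht) >= 1)
    return out


# ---------------------------------------------------------------- tables --

def classification_table(classifications: Iterable[ColumnClassification]
                         ) -> pd.DataFrame:
    """Long-format per-column classification (one row per species/column)."""
    rows = []
    for cls in classifications:
        for sp, lab in sorted(cls.labels.items()):
            rows.append((cls.column_index, cls.dominant, sp, lab))
    return pd.DataFrame(rows, columns=["column", "dominant", "species_id",
                                       "category"])


def profile_table(profiles: Mapping[str, VariabilityProfile]) -> pd.DataFrame:
    """Per-tRNA/per-domain weighted totals in long format (plot-ready)."""
    rows = []
    for iso, prof in sorted(profiles.items()):
        for domain in TALLY_DOMAINS:
            rows.append((iso, domain, "snp", prof.domain_snp[domain]))
            rows.append((iso, domain, "indel", prof.domain_indel[domain]))
    return pd.DataFrame(rows, columns=["isotype", "domain", "kind",
                                       "weighted_total"])


def zscore_table(categories: Mapping[str, ZCategory]) -> pd.DataFrame:
    rows = [(iso, zc.z_ci, zc.z_ht, zc.category, zc.extreme)
            for iso, zc in sorted(categories.items())]
    return pd.DataFrame(rows, columns=["isotype", "z_ci", "z_ht",
                                       "category", "extreme"])
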