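"""End-to-end orchestration: annotate, align, quantify, contrast cohorts.

Thin glue over the library modules; every step is available individually.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

import pandas as pd

from . import cloverleaf, msa, subquant
from .seqio import CohortTable, TRNAGene
from .subquant import VariabilityProfile, CategoryWeights


def annotate_all(genes: Mapping[str, Mapping[str, TRNAGene]],
                 structures: Mapping[str, str] | None = None
                 ) -> dict[str, dict[str, cloverleaf.CloverleafAnnotation]]:
    """Cloverleaf annotation for every gene (dot-bracket when provided,
    template mode otherwise); keyed isotype -> species."""
    out: dict[str, dict[str, cloverleaf.CloverleafAnnotation]] = {}
    for isotype, by_sp in genes.items():
        out[isotype] = {}
        for sp, gene in by_sp.items():
            struct = structures.get(gene.gene_id) if structures else None
            out[isotype][sp] = cloverleaf.annotate_domains(gene, struct)
    return out


def align_all(genes: Mapping[str, Mapping[str, TRNAGene]],
              annotations: Mapping[str, Mapping[
                  str, cloverleaf.CloverleafAnnotation]],
              params: msa.AlignParams = msa.DEFAULT_PARAMS
              ) -> dict[str, msa.GeneAlignment]:
    """Domain-blocked alignment of every isotype across species."""
    out = {}
    for isotype, by_sp in genes.items():
        sps = sorted(by_sp)
        out[isotype] = msa.align_gene([by_sp[sp] for sp in sps],
                                      [annotations[isotype][sp]
                                       for sp in sps], params)
    return out


def cohort_profiles(alignments: Mapping[str, msa.GeneAlignment],
                    species: list[str] | None = None,
                    weight_scope: str = "global"
                    ) -> tuple[dict[str, VariabilityProfile],
                               dict[str, CategoryWeights]]:
    """Weighted variability profiles for one cohort.

    ``weight_scope='global'`` derives one weight table from the pooled
    category totals of all tRNAs; ``'per-gene'`` ranks each tRNA's own
    totals.  The substitution-only fixed weights apply automatically when
    a scope's categories are transitions/transversions only.
    """
    if weight_scope not in ("global", "per-gene"):
        raise ValueError("weight_scope must be 'global' or 'per-gene'")
    classifications = {}
    for isotype, alig in alignments.items():
        sub = alig.subset(species) if species is not None else alig
        classifications[isotype] = (subquant.classify_alignment(sub), sub)
    weights_by_iso: dict[str, CategoryWeights] = {}
    if weight_scope == "global":
        pooled = sum((subquant.category_totals(cls)
                      for cls, _ in classifications.values()),
                     start=Counter())
        shared = subquant.weights_for(pooled)
        weights_by_iso = {iso: shared for iso in classifications}
    else:
        for isotype, (cls, _) in classifications.items():
            weights_by_iso[isotype] = subquant.weights_for(
                subquant.category_totals(cls))
    profiles = {}
    for isotype, (cls, sub) in classifications.items():
        profiles[isotype] = subquant.weighted_profile(
            cls, weights_by_iso[isotype], sub.column_domain, isotype)
    return profiles, weights_by_iso


def compare_cohorts(alignments: Mapping[str, msa.GeneAlignment],
                    cohorts: CohortTable,
                    weight_scope: str = "global") -> pd.DataFrame:
    """Cohort-contrasted z-score categorization of every tRNA.

    The full family set and the sublineage subset are each classified,
    weighted and totalled (per-species means so cohort sizes cancel), the
    per-tRNA totals are z-scored within each cohort, and every tRNA is
    assigned its variability category (1-4).
    """
    if not cohorts.sublineage:
        raise ValueError("cohort contrast requested with empty sublineage")
    prof_ci, _ = cohort_profiles(alignments, cohorts.family, weight_scope)
    prof_ht, _ = cohort_profiles(alignments, cohorts.sublineage, weight_scope)
    tot_ci = {iso: p.total / p.n_species for iso, p in prof_ci.items()}
    tot_ht = {iso: p.total / p.n_species for iso, p in prof_ht.items()}
    cats = subquant.zscore_categorize(tot_ci, tot_ht)
    df = subquant.zscore_table(cats)
    df["total_ci"] = df["isotype"].map(tot_ci)
    df["total_ht"] = df["isotype"].map(tot_ht)
    return df
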