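"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a family-level mitogenome survey: per species, 22
tRNA genes of 67-74 nt folding into the four-domain cloverleaf (one
D-armless isotype), eight genes on the reverse strand, per-gene
heterogeneous substitution rates with a transition bias, indels confined to
loops (D- and V-loop elevated), two nested cohorts (a full family set and a
sublineage clade) with contrasting per-gene variability, and 13
protein-coding genes evolved under the vertebrate mitochondrial code with a
controllable nonsynonymous fraction.  Sequences are evolved in alignment
coordinates down a random species tree, so the true alignment, the true
domain boundaries of every emitted sequence and the true variability
category of every gene are all known exactly (the truth table).

Stem substitutions are compensated on the paired strand with high
probability, mirroring the covariation that maintains secondary structure;
the anticodon triplet is invariant.  Two hand-built three-species fixtures
(``worked_example``) reproduce a published cysteine- and aspartate-tRNA
comparison position by position; only the polymorphic positions, their
substitution types and the non-Watson-Crick stem pairs are constrained —
the monomorphic background is generated from a fixed seed and is arbitrary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import exp
from pathlib import Path
import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .cloverleaf import CloverleafAnnotation, layout_margin
from .msa import GeneAlignment
from .seqio import (AA3_TO_1, D_ARMLESS_ISOTYPE, ISOTYPES, MT_ANTICODONS,
                    REVERSE_STRAND_ISOTYPES, CohortTable, TRNAGene, revcomp,
                    write_cohort_table, write_fasta)

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# 13 vertebrate mitochondrial protein-coding genes with roughly realistic
# lengths (nt, multiples of three, stop included)
CDS_LENGTHS = {
    "ATP6": 681, "ATP8": 165, "COX1": 1548, "COX2": 690, "COX3": 783,
    "CYTB": 1140, "ND1": 972, "ND2": 1044, "ND3": 348, "ND4": 1377,
    "ND4L": 294, "ND5": 1836, "ND6": 519,
}

# template length ranges (nt) for loop regions
LOOP_RANGES = {"D-loop": (3, 10), "V-loop": (4, 6), "T-loop": (7, 9)}
ARMLESS_CC_RANGE = (2, 12)
GENE_LENGTH_RANGE = (67, 74)

# generator-side connector range for the D-armless gene: kept at 10-11 nt so
# that no cloverleaf layout (which needs 2*d_stem + d_loop = cc - 3) can
# masquerade as a rival fold of the same sequence
_ARMLESS_CC_GEN_RANGE = (10, 11)


def _default_rate_multipliers() -> dict[str, float]:
    # contrasting per-gene variability mirroring the family-level pattern:
    # a hyper-variable group, a hypo-variable group, and two genes whose
    # sublineage behavior diverges from the family-level one
    return {
        "trnC": 3.0, "trnY": 2.5, "trnP": 2.5, "trnG": 2.0, "trnI": 2.0,
        "trnH": 2.0,
        "trnA": 0.5, "trnE": 0.4, "trnF": 0.4, "trnK": 0.5, "trnN": 0.5,
        "trnQ": 0.5, "trnW": 0.4, "trnD": 0.5,
    }


def _default_sublineage_multipliers() -> dict[str, float]:
    return {"trnH": 0.1, "trnD": 8.0}


def _default_indel_odds() -> dict[str, float]:
    return {"D-loop": 1.0, "V-loop": 0.8, "T-loop": 0.05, "An-loop": 0.0,
            "CC-loop": 0.0}


@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort."""

    n_species: int = 30
    sublineage_fraction: float = 0.3
    species_tree: str | None = None          # newick; None -> random
    rate_multipliers: dict[str, float] = field(
        default_factory=_default_rate_multipliers)
    sublineage_rate_multipliers: dict[str, float] = field(
        default_factory=_default_sublineage_multipliers)
    domain_indel_odds: dict[str, float] = field(
        default_factory=_default_indel_odds)
    kappa: float = 2.3                       # ts/tv rate ratio
    trna_sub_rate: float = 0.10              # substitutions/site over depth 1
    trna_indel_rate: float = 0.15            # indel events/loop site, depth 1
    stem_wobble_prob: float = 0.05           # stem change leaves a G*T pair
    cds_rate: float = 0.06                   # codon substitution rate
    nonsynonymous_fraction: float = 0.11
    cds_deletion_prob: float = 0.005         # per gene per branch
    cds_frameshift_prob: float = 0.003
    cds_truncation_prob: float = 0.003
    d_loop_range: tuple[int, int] = LOOP_RANGES["D-loop"]
    v_loop_range: tuple[int, int] = LOOP_RANGES["V-loop"]
    t_loop_range: tuple[int, int] = LOOP_RANGES["T-loop"]
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if not 0 < self.sublineage_fraction < 1:
            raise ValueError("sublineage_fraction must be in (0, 1)")
        for name, rng_, allowed in (
                ("d_loop_range", self.d_loop_range, LOOP_RANGES["D-loop"]),
                ("v_loop_range", self.v_loop_range, LOOP_RANGES["V-loop"]),
                ("t_loop_range", self.t_loop_range, LOOP_RANGES["T-loop"])):
            if rng_[0] < allowed[0] or rng_[1] > allowed[1]:
                raise ValueError(
                    f"{name} {rng_} outside the structural range {allowed}")
        for m in (self.rate_multipliers, self.sublineage_rate_multipliers):
            if any(v < 0 for v in m.values()):
                raise ValueError("rate multipliers must be >= 0")


@dataclass
class TruthTable:
    """Generator ground truth for one cohort."""

    gene_rates: dict[str, dict[str, float]]        # iso -> {ci, ht}
    categories: dict[str, int | None]              # iso -> true category
    tree_newick: str
    alignment_domains: dict[str, list[str]]        # iso -> per-column label
    kappa: float


# ------------------------------------------------------------- tree model --

class _Node:
    __slots__ = ("name", "children", "in_sub")

    def __init__(self, name=None, children=None, in_sub=False):
        self.name = name
        self.children = children or []   # list of (child, branch_length)
        self.in_sub = in_sub

    def newick(self) -> str:
        if self.name is not None:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def _coalescent(names: list[str], rng) -> tuple[_Node, float]:
    nodes = [(_Node(name=n), 0.0) for n in names]
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        parent = _Node(children=[(a, height - ha), (b, height - hb)])
        nodes = [nodes[m] for m in range(k) if m not in (i, j)]
        nodes.append((parent, height))
    return nodes[0][0]


def _mark_sub(node: _Node) -> None:
    node.in_sub = True
    for child, _ in node.children:
        _mark_sub(child)


def _scale(node: _Node, factor: float) -> None:
    node.children = [(c, bl * factor) for c, bl in node.children]
    for c, _ in node.children:
        _scale(c, factor)


def _depth(node: _Node) -> float:
    if not node.children:
        return 0.0
    return max(bl + _depth(c) for c, bl in node.children)


def _species_tree(spec: CohortSpec, rng
                  ) -> tuple[_Node, list[str], list[str]]:
    n_ht = max(2, round(spec.n_species * spec.sublineage_fraction))
    ht = [f"sp_ht_{i:02d}" for i in range(1, n_ht + 1)]
    ci = [f"sp_ci_{i:02d}" for i in range(1, spec.n_species - n_ht + 1)]
    root_ht = _coalescent(ht, rng)
    root_ci = _coalescent(ci, rng)
    h_ht, h_ci = _depth(root_ht), _depth(root_ci)
    top = max(h_ht, h_ci) * 1.25 + 0.05
    _mark_sub(root_ht)
    root = _Node(children=[(root_ht, top - h_ht), (root_ci, top - h_ci)])
    _scale(root, 1.0 / top)   # normalize root-to-tip depth to 1
    return root, ht + ci, ht


# -------------------------------------------------------- tRNA gene model --

class _GeneContext:
    """Mutable bookkeeping for one gene's evolution in column coordinates."""

    def __init__(self, isotype: str, layout: list[tuple[str, int]],
                 spec: CohortSpec):
        self.isotype = isotype
        self.layout = layout
        self.domain_of: dict[tuple, str] = {}
        key = 0
        seg_positions: list[tuple[str, list[tuple]]] = []
        for label, n in layout:
            keys = [(key + i,) for i in range(n)]
            key += n
            for k in keys:
                self.domain_of[k] = label
            seg_positions.append((label, keys))
        # stem partner map (outermost pair first)
        self.partner: dict[tuple, tuple] = {}
        seg_keys = dict()
        for idx, (label, keys) in enumerate(seg_positions):
            seg_keys.setdefault(label, []).append(keys)
        for arm in ("A", "D", "An", "T"):
            k5 = seg_keys.get(f"{arm}-stem5'", [[]])[0]
            k3 = seg_keys.get(f"{arm}-stem3'", [[]])[0]
            for a, b in zip(k5, reversed(k3)):
                self.partner[a] = b
                self.partner[b] = a
        an_loop = seg_keys.get("An-loop", [[]])[0]
        mid = len(an_loop) // 2
        self.anticodon_keys = set(an_loop[mid - 1: mid + 2])
        self.counter = 0
        armless = not seg_keys.get("D-stem5'")
        d_stem = len(seg_keys.get("D-stem5'", [[]])[0])
        # a 3-bp D-stem is only distinguishable from a 4-bp one when the
        # D-loop stays short enough that no 4-bp layout fits the template
        d_loop_range = (3, 4) if d_stem == 3 else spec.d_loop_range
        self.indel_ranges: dict[str, tuple[int, int]] = {
            "V-loop": spec.v_loop_range,
            "T-loop": spec.t_loop_range,
        }
        if armless:
            self.indel_ranges["CC"] = _ARMLESS_CC_GEN_RANGE
        else:
            self.indel_ranges["D-loop"] = d_loop_range


def _sample_layout(isotype: str, rng) -> list[tuple[str, int]]:
    """Random domain layout honoring the structural length constraints."""
    if isotype == D_ARMLESS_ISOTYPE:
        while True:
            v = int(rng.integers(4, 7))
            tl = int(rng.integers(7, 10))
            cc = int(rng.integers(_ARMLESS_CC_GEN_RANGE[0],
                                  _ARMLESS_CC_GEN_RANGE[1] + 1))
            L = 42 + cc + v + tl
            if GENE_LENGTH_RANGE[0] <= L <= GENE_LENGTH_RANGE[1]:
                break
        return [("A-stem5'", 7), ("CC", cc), ("An-stem5'", 5),
                ("An-loop", 7), ("An-stem3'", 5), ("V-loop", v),
                ("T-stem5'", 5), ("T-loop", tl), ("T-stem3'", 5),
                ("A-stem3'", 7), ("discriminator", 1)]
    while True:
        d = int(rng.integers(3, 5))
        # d = 3 pairs with a short D-loop only (see _GeneContext)
        dl = int(rng.integers(3, 5)) if d == 3 else int(rng.integers(3, 11))
        v = int(rng.integers(4, 7))
        tl = int(rng.integers(7, 10))
        L = 45 + 2 * d + dl + v + tl
        if GENE_LENGTH_RANGE[0] <= L <= GENE_LENGTH_RANGE[1]:
            break
    return [("A-stem5'", 7), ("CC", 2), ("D-stem5'", d), ("D-loop", dl),
            ("D-stem3'", d), ("CC", 1), ("An-stem5'", 5), ("An-loop", 7),
            ("An-stem3'", 5), ("V-loop", v), ("T-stem5'", 5), ("T-loop", tl),
            ("T-stem3'", 5), ("A-stem3'", 7), ("discriminator", 1)]


def _root_state(ctx: _GeneContext, rng,
                min_margin: float = 3.0) -> dict[tuple, str]:
    """Sample a root sequence whose true layout is the unambiguous template
    winner (fold-score margin >= ``min_margin`` over every rival layout),
    so that annotation still recovers the truth after some divergence."""
    anticodon = MT_ANTICODONS[ctx.isotype]
    ac_keys = sorted(ctx.anticodon_keys)
    labels = [ctx.domain_of[k] for k in sorted(ctx.domain_of)]
    truth = _annotation_from_labels(ctx.isotype, labels,
                                    ctx.isotype == D_ARMLESS_ISOTYPE)
    for _ in range(500):
        state: dict[tuple, str] = {}
        for key in sorted(ctx.domain_of):
            if key in state:
                continue
            if key in ctx.anticodon_keys:
                state[key] = anticodon[ac_keys.index(key)]
            elif key in ctx.partner:
                b = "ACGT"[rng.integers(4)]
                state[key] = b
                state[ctx.partner[key]] = _WC[b]
            else:
                state[key] = "ACGT"[rng.integers(4)]
        seq = "".join(state[k] for k in sorted(state))
        gene = TRNAGene(ctx.isotype, "root", ctx.isotype, anticodon,
                        "forward", 1, len(seq), seq)
        if layout_margin(gene, truth) >= min_margin:
            return state
    raise RuntimeError(f"{ctx.isotype}: no unambiguous root layout found")


def _substitute(base: str, kappa: float, rng) -> str:
    r = rng.random() * (kappa + 2)
    if r < kappa:
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][0 if r < kappa + 1 else 1]


def _mutate_trna(state: dict[tuple, str], branch_len: float, mult: float,
                 ctx: _GeneContext, spec: CohortSpec, rng
                 ) -> dict[tuple, str]:
    state = dict(state)
    p_sub = 1 - exp(-spec.trna_sub_rate * mult * branch_len)
    if p_sub > 0:
        for key in list(state):
            if key in ctx.anticodon_keys or rng.random() >= p_sub:
                continue
            nb = _substitute(state[key], spec.kappa, rng)
            state[key] = nb
            partner = ctx.partner.get(key)
            if partner is not None and partner in state:
                # covariation keeps stems closed; occasionally the repair
                # leaves a tolerated G*T wobble instead of a WC pair
                if nb in "GT" and rng.random() < spec.stem_wobble_prob:
                    state[partner] = "T" if nb == "G" else "G"
                else:
                    state[partner] = _WC[nb]
    odds_of = dict(spec.domain_indel_odds)
    odds_of.setdefault("CC-loop", 0.0)
    for domain, bounds in ctx.indel_ranges.items():
        odds = odds_of.get("CC-loop" if domain == "CC" else domain, 0.0)
        if odds <= 0:
            continue
        p_ind = 1 - exp(-spec.trna_indel_rate * odds * branch_len)
        if p_ind <= 0:
            continue
        for key in [k for k in list(state) if ctx.domain_of[k] == domain]:
            if rng.random() >= p_ind:
                continue
            cur = sum(1 for k in state if ctx.domain_of[k] == domain)
            total = len(state)
            can_del = cur > bounds[0] and total > GENE_LENGTH_RANGE[0]
            can_ins = cur < bounds[1] and total < GENE_LENGTH_RANGE[1]
            if can_del and (not can_ins or rng.random() < 0.5):
                del state[key]
            elif can_ins:
                ctx.counter += 1
                new_key = key + (ctx.counter,)
                ctx.domain_of[new_key] = domain
                state[new_key] = "ACGT"[rng.integers(4)]
    return state


def _evolve_trna(ctx: _GeneContext, root_state: dict[tuple, str],
                 tree: _Node, mult_ci: float, mult_ht: float,
                 spec: CohortSpec, rng) -> dict[str, dict[tuple, str]]:
    tips: dict[str, dict[tuple, str]] = {}

    def rec(node: _Node, state: dict[tuple, str]) -> None:
        if node.name is not None:
            tips[node.name] = state
            return
        for child, bl in node.children:
            mult = mult_ci * (mult_ht if child.in_sub else 1.0)
            rec(child, _mutate_trna(state, bl, mult, ctx, spec, rng))

    rec(tree, root_state)
    return tips


def _tips_to_alignment(isotype: str, ctx: _GeneContext,
                       tips: dict[str, dict[tuple, str]]) -> GeneAlignment:
    all_keys = sorted({k for state in tips.values() for k in state})
    rows = {sp: "".join(state.get(k, "-") for k in all_keys)
            for sp, state in tips.items()}
    domains = [ctx.domain_of[k] for k in all_keys]
    return GeneAlignment(isotype, rows, domains)


def _annotation_from_labels(gene_id: str, labels: list[str],
                            armless: bool) -> CloverleafAnnotation:
    stems = {f"{arm}-stem": labels.count(f"{arm}-stem5'")
             for arm in ("A", "D", "An", "T")}
    loops = {name: labels.count(name)
             for name in ("D-loop", "An-loop", "V-loop", "T-loop")}
    loops["CC"] = labels.count("CC")
    return CloverleafAnnotation(gene_id, labels, stems, loops, armless)


# -------------------------------------------------------------- CDS model --

def _codon_moves() -> dict[str, dict[str, list[tuple[str, bool]]]]:
    """Per codon: single-base neighbor codons split into synonymous,
    nonsynonymous (non-stop) and stop, each with a transition flag."""
    from .cdsmut import CODON_TO_AA
    moves: dict[str, dict[str, list[tuple[str, bool]]]] = {}
    bases = "ACGT"
    for codon, aa in CODON_TO_AA.items():
        entry = {"syn": [], "nonsyn": [], "stop": []}
        for pos in range(3):
            for nb in bases:
                if nb == codon[pos]:
                    continue
                alt = codon[:pos] + nb + codon[pos + 1:]
                is_ts = _TRANSITION[codon[pos]] == nb
                alt_aa = CODON_TO_AA[alt]
                if alt_aa == "*":
                    entry["stop"].append((alt, is_ts))
                elif alt_aa == aa:
                    entry["syn"].append((alt, is_ts))
                else:
                    entry["nonsyn"].append((alt, is_ts))
        moves[codon] = entry
    return moves


_CODON_MOVES = _codon_moves()


def _pick_move(options: list[tuple[str, bool]], kappa: float, rng) -> str:
    weights = np.array([kappa if ts else 1.0 for _, ts in options])
    idx = rng.choice(len(options), p=weights / weights.sum())
    return options[idx][0]


def _root_cds(length: int, rng) -> list[str]:
    from .cdsmut import CODON_TO_AA
    sense = [c for c, aa in CODON_TO_AA.items() if aa != "*"]
    n = length // 3
    codons = ["ATG"]
    codons += [sense[rng.integers(len(sense))] for _ in range(n - 2)]
    codons.append("TAA")
    return codons


def _mutate_cds(codons: list[str], branch_len: float, spec: CohortSpec,
                rng) -> list[str]:
    codons = list(codons)
    p = 1 - exp(-spec.cds_rate * branch_len)
    if p > 0:
        mask = rng.random(len(codons)) < p
        for i in np.nonzero(mask)[0]:
            if i == 0 or i == len(codons) - 1 or "-" in codons[i]:
                continue
            entry = _CODON_MOVES[codons[i]]
            want_nonsyn = rng.random() < spec.nonsynonymous_fraction
            pool = entry["nonsyn"] if want_nonsyn else entry["syn"]
            if not pool:
                pool = entry["syn"] or entry["nonsyn"]
            if pool:
                codons[i] = _pick_move(pool, spec.kappa, rng)
    intact = [i for i in range(1, len(codons) - 1) if "-" not in codons[i]]
    if intact and rng.random() < spec.cds_deletion_prob:
        codons[intact[rng.integers(len(intact))]] = "---"
    intact = [i for i in intact if "-" not in codons[i]]
    if intact and rng.random() < spec.cds_frameshift_prob:
        i = intact[rng.integers(len(intact))]
        codons[i] = codons[i][:2] + "-"
    intact = [i for i in intact if "-" not in codons[i]]
    if rng.random() < spec.cds_truncation_prob:
        candidates = [i for i in intact if _CODON_MOVES[codons[i]]["stop"]]
        if candidates:
            i = candidates[rng.integers(len(candidates))]
            codons[i] = _pick_move(_CODON_MOVES[codons[i]]["stop"],
                                   spec.kappa, rng)
    return codons


def _evolve_cds(root: list[str], tree: _Node, spec: CohortSpec, rng
                ) -> dict[str, str]:
    tips: dict[str, str] = {}

    def rec(node: _Node, codons: list[str]) -> None:
        if node.name is not None:
            tips[node.name] = "".join(codons)
            return
        for child, bl in node.children:
            rec(child, _mutate_cds(codons, bl, spec, rng))

    rec(tree, root)
    return tips


# ------------------------------------------------------------- the cohort --

@dataclass
class SyntheticCohort:
    spec: CohortSpec
    cohort_table: CohortTable
    genes: dict[str, dict[str, TRNAGene]]                 # iso -> sp -> gene
    annotations: dict[str, dict[str, CloverleafAnnotation]]
    alignments: dict[str, GeneAlignment]                  # true alignments
    cds: dict[str, dict[str, str]]                        # gene -> sp -> seq
    cds_root: dict[str, str]
    truth: TruthTable

    @property
    def species(self) -> list[str]:
        return self.cohort_table.family


def _true_category(mult_ci: float, mult_ht_total: float) -> int | None:
    if mult_ci == 1.0 and mult_ht_total == 1.0:
        return None
    hyper_ci, hyper_ht = mult_ci > 1.0, mult_ht_total > 1.0
    if hyper_ci and hyper_ht:
        return 1
    if not hyper_ci and not hyper_ht:
        return 2
    return 3 if hyper_ci else 4


def generate_cohort(spec: CohortSpec,
                    out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate one synthetic two-cohort data set (deterministic in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tree, species, ht_species = _species_tree(spec, rng)
    cohort = CohortTable(
        in_family={sp: True for sp in species},
        in_sublineage={sp: sp in ht_species for sp in species})

    genes: dict[str, dict[str, TRNAGene]] = {}
    annotations: dict[str, dict[str, CloverleafAnnotation]] = {}
    alignments: dict[str, GeneAlignment] = {}
    gene_rates: dict[str, dict[str, float]] = {}
    categories: dict[str, int | None] = {}
    alignment_domains: dict[str, list[str]] = {}
    for isotype in ISOTYPES:
        layout = _sample_layout(isotype, rng)
        ctx = _GeneContext(isotype, layout, spec)
        root = _root_state(ctx, rng)
        mult_ci = spec.rate_multipliers.get(isotype, 1.0)
        mult_ht = spec.sublineage_rate_multipliers.get(isotype, 1.0)
        tips = _evolve_trna(ctx, root, tree, mult_ci, mult_ht, spec, rng)
        alig = _tips_to_alignment(isotype, ctx, tips)
        alignments[isotype] = alig
        alignment_domains[isotype] = list(alig.column_domain)
        gene_rates[isotype] = {"ci": mult_ci, "ht": mult_ci * mult_ht}
        categories[isotype] = _true_category(mult_ci, mult_ci * mult_ht)
        strand = ("reverse" if isotype in REVERSE_STRAND_ISOTYPES
                  else "forward")
        genes[isotype] = {}
        annotations[isotype] = {}
        armless = isotype == D_ARMLESS_ISOTYPE
        for sp in species:
            keys = [k for k in sorted(tips[sp])]
            seq = "".join(tips[sp][k] for k in keys)
            labels = [ctx.domain_of[k] for k in keys]
            gene = TRNAGene(f"{sp}|{isotype}", sp, isotype,
                            MT_ANTICODONS[isotype], strand, 1, len(seq), seq)
            genes[isotype][sp] = gene
            annotations[isotype][sp] = _annotation_from_labels(
                gene.gene_id, labels, armless)

    cds: dict[str, dict[str, str]] = {}
    cds_root: dict[str, str] = {}
    for gene_name, length in CDS_LENGTHS.items():
        root = _root_cds(length, rng)
        cds_root[gene_name] = "".join(root)
        cds[gene_name] = _evolve_cds(root, tree, spec, rng)

    truth = TruthTable(gene_rates, categories, tree.newick() + ";",
                       alignment_domains, spec.kappa)
    result = SyntheticCohort(spec, cohort, genes, annotations, alignments,
                             cds, cds_root, truth)
    if out_dir is not None:
        _write_cohort(result, Path(out_dir))
    return result


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort_table(cohort.cohort_table, out_dir / "cohort.csv")
    for isotype, by_sp in cohort.genes.items():
        write_fasta({sp: g.sequence for sp, g in sorted(by_sp.items())},
                    out_dir / f"{isotype}.fasta")
        alig = cohort.alignments[isotype]
        write_fasta(dict(sorted(alig.rows.items())),
                    out_dir / f"{isotype}.aligned.fasta")
    for gene_name, by_sp in cohort.cds.items():
        write_fasta(dict(sorted(by_sp.items())),
                    out_dir / f"cds_{gene_name}.fasta")
    truth = asdict(cohort.truth)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def mitogenome_record(cohort: SyntheticCohort, species_id: str,
                      spacer_rng_seed: int = 0) -> SeqRecord:
    """Assemble one species' tRNAs into an annotated mitogenome-like record.

    Genes are laid out in the canonical isotype order, separated by short
    random spacers; reverse-strand isotypes are stored reverse-complemented
    with a minus-strand feature, so extraction round-trips the gene product.
    """
    rng = np.random.default_rng(spacer_rng_seed)
    parts: list[str] = []
    features: list[SeqFeature] = []
    pos = 0
    for isotype in ISOTYPES:
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10))
        parts.append(spacer)
        pos += len(spacer)
        gene = cohort.genes[isotype][species_id]
        reverse = gene.strand == "reverse"
        genomic = revcomp(gene.sequence) if reverse else gene.sequence
        parts.append(genomic)
        aa3 = _AA1_TO_3[isotype[3]]
        features.append(SeqFeature(
            FeatureLocation(pos, pos + len(genomic),
                            strand=-1 if reverse else 1),
            type="tRNA",
            qualifiers={"product": [f"tRNA-{aa3}"],
                        "gene": [isotype],
                        "anticodon": [gene.anticodon]}))
        pos += len(genomic)
    record = SeqRecord(Seq("".join(parts)), id=species_id,
                       description="synthetic mitogenome (tRNA genes only)")
    record.annotations["molecule_type"] = "DNA"
    record.features = features
    return record


# -------------------------------------------------------- worked examples --

@dataclass
class WorkedExample:
    """A three-species gene alignment with its structural annotation."""

    name: str
    alignment: GeneAlignment
    annotation: CloverleafAnnotation
    genes: dict[str, TRNAGene]


_EGYPT_SPECIES = ("O_niloticus", "S_galilaeus", "C_zillii")

# trnC, 66 nt: layout with a 3-nt D-loop and a shortened (3-nt) variable
# loop; seven polymorphic positions, all transitions, four minority alleles
# carried by C. zillii; wobble stem pairs T5*G61 and G10*T20.
_TRNC_LAYOUT = [("A-stem5'", 7), ("CC", 2), ("D-stem5'", 4), ("D-loop", 3),
                ("D-stem3'", 4), ("CC", 1), ("An-stem5'", 5), ("An-loop", 7),
                ("An-stem3'", 5), ("V-loop", 3), ("T-stem5'", 5),
                ("T-loop", 7), ("T-stem3'", 5), ("A-stem3'", 7),
                ("discriminator", 1)]
# position -> (majority base, forced partner/constrained base)
_TRNC_FIXED = {5: "T", 61: "G", 4: "G", 62: "C", 10: "G", 20: "T",
               11: "G", 19: "C", 25: "C", 35: "G", 16: "A", 27: "T",
               47: "A"}
# position -> (minority base, carrier species)
_TRNC_VARIANTS = {16: ("G", "C_zillii"), 19: ("T", "C_zillii"),
                  20: ("C", "O_niloticus"), 25: ("T", "C_zillii"),
                  27: ("C", "S_galilaeus"), 47: ("G", "O_niloticus"),
                  62: ("T", "C_zillii")}

# trnD, 73 nt: nine variable positions concentrated in the D- and T-loops,
# one three-variant site (17), C50*A64 mispair in C. zillii.
_TRND_LAYOUT = [("A-stem5'", 7), ("CC", 2), ("D-stem5'", 4), ("D-loop", 8),
                ("D-stem3'", 4), ("CC", 1), ("An-stem5'", 5), ("An-loop", 7),
                ("An-stem3'", 5), ("V-loop", 5), ("T-stem5'", 5),
                ("T-loop", 7), ("T-stem3'", 5), ("A-stem3'", 7),
                ("discriminator", 1)]
_TRND_FIXED = {15: "G", 17: "G", 20: "T", 21: "C", 56: "A", 57: "G",
               59: "A", 50: "C", 64: "G", 73: "A"}
_TRND_VARIANTS = {15: ("A", "O_niloticus"), 20: ("C", "S_galilaeus"),
                  21: ("T", "O_niloticus"), 56: ("T", "S_galilaeus"),
                  57: ("A", "O_niloticus"), 59: ("G", "S_galilaeus"),
                  64: ("A", "C_zillii"), 73: ("G", "O_niloticus")}
_TRND_SITE17 = {"O_niloticus": "G", "S_galilaeus": "A", "C_zillii": "T"}


def _build_example(isotype: str, layout, fixed, variants, extra,
                   seed: int) -> WorkedExample:
    rng = np.random.default_rng(seed)
    labels = []
    for lab, n in layout:
        labels.extend([lab] * n)
    L = len(labels)
    ann = _annotation_from_labels(f"egypt|{isotype}", labels, False)
    base = [""] * (L + 1)   # 1-based
    lo, hi = ann.anticodon_span
    anticodon = MT_ANTICODONS[isotype]
    for i, pos in enumerate(range(lo, hi + 1)):
        base[pos] = anticodon[i]
    pairs = ann.stem_pairs()
    for p5, p3 in pairs:
        if base[p5] or base[p3]:
            continue
        if p5 in fixed or p3 in fixed:
            continue
        b = "ACGT"[rng.integers(4)]
        base[p5], base[p3] = b, _WC[b]
    for pos in range(1, L + 1):
        if pos in fixed:
            base[pos] = fixed[pos]
        elif not base[pos]:
            base[pos] = "ACGT"[rng.integers(4)]
    majority = "".join(base[1:])
    rows: dict[str, str] = {}
    for sp in _EGYPT_SPECIES:
        seq = list(majority)
        for pos, (minor, carrier) in variants.items():
            if carrier == sp:
                seq[pos - 1] = minor
        for pos, by_sp in extra.items():
            seq[pos - 1] = by_sp[sp]
        rows[sp] = "".join(seq)
    genes = {sp: TRNAGene(f"{sp}|{isotype}", sp, isotype, anticodon,
                          "reverse", 1, L, rows[sp])
             for sp in _EGYPT_SPECIES}
    alig = GeneAlignment(isotype, rows, labels)
    return WorkedExample(f"{isotype}_egypt", alig, ann, genes)


def worked_example(name: str) -> WorkedExample:
    """Hand-built three-species fixtures for the cysteine and aspartate
    tRNA comparisons (``trnC_egypt`` and ``trnD_egypt``).

    Only the polymorphic positions, substitution types, carrier species and
    non-Watson-Crick stem pairs are meaningful; the monomorphic background
    is synthetic, generated from a fixed seed.
    """
    if name == "trnC_egypt":
        return _build_example("trnC", _TRNC_LAYOUT, _TRNC_FIXED,
                              _TRNC_VARIANTS, {}, seed=20221018)
    if name == "trnD_egypt":
        return _build_example("trnD", _TRND_LAYOUT, _TRND_FIXED,
                              _TRND_VARIANTS, {17: _TRND_SITE17},
                              seed=20221019)
    raise ValueError(f"unknown worked example {name!r}")
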