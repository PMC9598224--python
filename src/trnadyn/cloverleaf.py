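"""Cloverleaf secondary-structure domain annotation for mitochondrial tRNAs.

Partitions each tRNA gene into the structural domains used throughout the
analysis: acceptor stem (A), dihydrouridine arm (D: stem + loop), anticodon
arm (An: stem + loop), variable loop (V), thymidine arm (T: stem + loop),
the central connector positions (CC) and the unpaired discriminator base.
Annotation comes either from a supplied dot-bracket string or from a
constrained template search (stems of fixed length: A-stem 7 bp, An-stem
5 bp, T-stem 5 bp; D-stem 3-4 bp; An-loop 7 nt; T-loop 7-9 nt; V-loop
4-6 nt; D-loop 3-10 nt), with D-armless genes handled by a three-arm
template.  Template mode returns the assignment maximizing the number of
complementary (Watson-Crick or G*U wobble) stem pairs; ties are broken
deterministically (cloverleaf over armless, longer D-stem, shorter loops).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import IUPAC_SETS, TRNAGene, check_balanced

logger = logging.getLogger("trnadyn")

WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}

# Position-level labels in 5'->3' order for the canonical cloverleaf.  CC is
# the one label that occurs in two physical segments (between the acceptor
# stem and the D-arm, and between the D-arm and the anticodon arm).
CLOVERLEAF_ORDER = (
    "A-stem5'", "CC", "D-stem5'", "D-loop", "D-stem3'", "CC",
    "An-stem5'", "An-loop", "An-stem3'", "V-loop",
    "T-stem5'", "T-loop", "T-stem3'", "A-stem3'", "discriminator",
)
ARMLESS_ORDER = (
    "A-stem5'", "CC", "An-stem5'", "An-loop", "An-stem3'", "V-loop",
    "T-stem5'", "T-loop", "T-stem3'", "A-stem3'", "discriminator",
)

# Grouping of position labels into the tally domains used in reports; the
# discriminator is grouped with the acceptor stem.
DOMAIN_GROUPS = {
    "A-stem5'": "A-stem", "A-stem3'": "A-stem", "discriminator": "A-stem",
    "D-stem5'": "D-stem", "D-stem3'": "D-stem", "D-loop": "D-loop",
    "An-stem5'": "An-stem", "An-stem3'": "An-stem", "An-loop": "An-loop",
    "V-loop": "V-loop",
    "T-stem5'": "T-stem", "T-stem3'": "T-stem", "T-loop": "T-loop",
    "CC": "CC-loop",
}
TALLY_DOMAINS = ("A-stem", "D-stem", "D-loop", "An-stem", "An-loop",
                 "V-loop", "T-stem", "T-loop", "CC-loop")


def can_pair(b5: str, b3: str, allow_wobble: bool = True) -> bool:
    """True when two (possibly degenerate) bases can form a WC or wobble pair."""
    s5 = IUPAC_SETS.get(b5.upper())
    s3 = IUPAC_SETS.get(b3.upper())
    if s5 is None or s3 is None:
        return False
    ok = set(WATSON_CRICK) | (set(WOBBLE) if allow_wobble else set())
    return any((x, y) in ok for x in s5 for y in s3)


@dataclass
class CloverleafAnnotation:
    """Per-position structural-domain labels for one tRNA gene."""

    gene_id: str
    domain_of: list[str]                 # label per position, 5'->3'
    stem_lengths: dict[str, int]         # domain -> paired length (bp)
    loop_lengths: dict[str, int]         # domain -> length (nt)
    d_armless: bool

    def __len__(self) -> int:
        return len(self.domain_of)

    def segments(self) -> list[tuple[str, int, int]]:
        """Contiguous (label, start, end) runs, 1-based inclusive."""
        segs: list[tuple[str, int, int]] = []
        for i, lab in enumerate(self.domain_of, 1):
            if segs and segs[-1][0] == lab and segs[-1][2] == i - 1:
                segs[-1] = (lab, segs[-1][1], i)
            else:
                segs.append((lab, i, i))
        return segs

    def positions_of(self, label: str) -> list[int]:
        return [i for i, lab in enumerate(self.domain_of, 1) if lab == label]

    def stem_pairs(self) -> list[tuple[int, int]]:
        """All (pos5', pos3') stem base pairs, outermost first per stem."""
        pairs: list[tuple[int, int]] = []
        for arm in ("A", "D", "An", "T"):
            p5 = self.positions_of(f"{arm}-stem5'")
            p3 = self.positions_of(f"{arm}-stem3'")
            pairs.extend(zip(p5, reversed(p3)))
        return pairs

    @property
    def anticodon_span(self) -> tuple[int, int]:
        """1-based (start, end) of the anticodon at the An-loop center."""
        loop = self.positions_of("An-loop")
        mid = len(loop) // 2
        return loop[mid - 1], loop[mid + 1]


@dataclass(frozen=True)
class TemplateConstraints:
    """Search ranges for template-mode annotation (lengths in nt/bp)."""

    a_stem: int = 7
    an_stem: int = 5
    t_stem: int = 5
    d_stem: tuple[int, ...] = (3, 4)
    an_loop: int = 7
    d_loop: tuple[int, int] = (3, 10)
    v_loop: tuple[int, int] = (4, 6)
    t_loop: tuple[int, int] = (7, 9)
    cc_armless: tuple[int, int] = (2, 12)


DEFAULT_CONSTRAINTS = TemplateConstraints()


def _layout_to_labels(layout: Sequence[tuple[str, int]]) -> list[str]:
    labels: list[str] = []
    for lab, n in layout:
        labels.extend([lab] * n)
    return labels


def _cloverleaf_layout(d: int, dl: int, v: int, tl: int,
                       c: TemplateConstraints) -> list[tuple[str, int]]:
    return [("A-stem5'", c.a_stem), ("CC", 2), ("D-stem5'", d),
            ("D-loop", dl), ("D-stem3'", d), ("CC", 1),
            ("An-stem5'", c.an_stem), ("An-loop", c.an_loop),
            ("An-stem3'", c.an_stem), ("V-loop", v),
            ("T-stem5'", c.t_stem), ("T-loop", tl), ("T-stem3'", c.t_stem),
            ("A-stem3'", c.a_stem), ("discriminator", 1)]


def _armless_layout(cc: int, v: int, tl: int,
                    c: TemplateConstraints) -> list[tuple[str, int]]:
    return [("A-stem5'", c.a_stem), ("CC", cc),
            ("An-stem5'", c.an_stem), ("An-loop", c.an_loop),
            ("An-stem3'", c.an_stem), ("V-loop", v),
            ("T-stem5'", c.t_stem), ("T-loop", tl), ("T-stem3'", c.t_stem),
            ("A-stem3'", c.a_stem), ("discriminator", 1)]


def _score_pairs(seq: str, ann: CloverleafAnnotation) -> int:
    """Fold-quality score of a candidate layout.

    Watson-Crick pairs score 3, wobble pairs 2 and non-complementary stem
    pairs -2, so a layout that forces extra mispairs into a stem never ties
    with one whose stems close cleanly."""
    score = 0
    for p5, p3 in ann.stem_pairs():
        b5, b3 = seq[p5 - 1], seq[p3 - 1]
        if can_pair(b5, b3, allow_wobble=False):
            score += 3
        elif can_pair(b5, b3):
            score += 2
        else:
            score -= 2
    return score


def _annotation_from_layout(gene_id: str, layout: Sequence[tuple[str, int]],
                            d: int, dl: int, v: int, tl: int,
                            cc_total: int, armless: bool,
                            c: TemplateConstraints) -> CloverleafAnnotation:
    return CloverleafAnnotation(
        gene_id=gene_id,
        domain_of=_layout_to_labels(layout),
        stem_lengths={"A-stem": c.a_stem, "D-stem": d,
                      "An-stem": c.an_stem, "T-stem": c.t_stem},
        loop_lengths={"D-loop": dl, "An-loop": c.an_loop, "V-loop": v,
                      "T-loop": tl, "CC": cc_total},
        d_armless=armless,
    )


def _template_candidates(gene: TRNAGene, c: TemplateConstraints
                         ) -> list[tuple[tuple, CloverleafAnnotation]]:
    """Enumerate all layouts consistent with length + anticodon centering.

    Each candidate carries a deterministic tie-break key
    (armless?, -d, dl, v, tl, cc)."""
    seq = gene.sequence
    L = len(seq)
    # every occurrence of the anticodon is a candidate An-loop center
    ac_positions = []
    start = 0
    while True:
        idx = seq.find(gene.anticodon, start)
        if idx < 0:
            break
        ac_positions.append(idx + 1)
        start = idx + 1
    out = []
    for acpos in ac_positions:
        # cloverleaf: anticodon first base sits at 18 + 2d + dl
        for d in c.d_stem:
            dl = acpos - 18 - 2 * d
            if not c.d_loop[0] <= dl <= c.d_loop[1]:
                continue
            for v in range(c.v_loop[0], c.v_loop[1] + 1):
                tl = L - 45 - 2 * d - dl - v
                if not c.t_loop[0] <= tl <= c.t_loop[1]:
                    continue
                layout = _cloverleaf_layout(d, dl, v, tl, c)
                ann = _annotation_from_layout(gene.gene_id, layout, d, dl,
                                              v, tl, 3, False, c)
                out.append(((0, -d, dl, v, tl, 3), ann))
        # armless: anticodon first base sits at 15 + cc
        cc = acpos - 15
        if c.cc_armless[0] <= cc <= c.cc_armless[1]:
            for v in range(c.v_loop[0], c.v_loop[1] + 1):
                tl = L - 42 - cc - v
                if not c.t_loop[0] <= tl <= c.t_loop[1]:
                    continue
                layout = _armless_layout(cc, v, tl, c)
                ann = _annotation_from_layout(gene.gene_id, layout, 0, 0,
                                              v, tl, cc, True, c)
                out.append(((1, 0, 0, v, tl, cc), ann))
    return out


def _annotate_from_structure(gene: TRNAGene, structure: str
                             ) -> CloverleafAnnotation:
    seq = gene.sequence
    if len(structure) != len(seq):
        raise ValueError(f"{gene.gene_id}: structure length mismatch")
    if not check_balanced(structure):
        raise ValueError(f"{gene.gene_id}: unbalanced dot-bracket")
    stack: list[int] = []
    partner = [0] * (len(seq) + 1)  # 1-based
    for i, ch in enumerate(structure, 1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            partner[i], partner[j] = j, i
    # group 5'-side paired positions into helices of stacked pairs
    helices: list[list[tuple[int, int]]] = []
    for i in range(1, len(seq) + 1):
        j = partner[i]
        if j <= i:
            continue
        if helices and helices[-1][-1][0] == i - 1 and helices[-1][-1][1] == j + 1:
            helices[-1].append((i, j))
        else:
            helices.append([(i, j)])
    if len(helices) not in (3, 4):
        raise ValueError(
            f"{gene.gene_id}: expected 3 or 4 helices, found {len(helices)}")
    armless = len(helices) == 3
    arms = ["A", "An", "T"] if armless else ["A", "D", "An", "T"]
    labels = ["?"] * len(seq)
    for arm, helix in zip(arms, helices):
        for i, j in helix:
            labels[i - 1] = f"{arm}-stem5'"
            labels[j - 1] = f"{arm}-stem3'"
    # each unpaired run gets one label from its flanking stems
    loop_of = {"D": "D-loop", "An": "An-loop", "T": "T-loop"}
    pos = 1
    while pos <= len(seq):
        if labels[pos - 1] != "?":
            pos += 1
            continue
        end = pos
        while end < len(seq) and labels[end] == "?":
            end += 1
        prev = labels[pos - 2] if pos > 1 else None
        nxt = labels[end] if end < len(seq) else None
        if prev is None:
            raise ValueError(f"{gene.gene_id}: leading unpaired bases "
                             "before the acceptor stem")
        if nxt is None:
            label = "discriminator"
        elif prev.endswith("5'") and nxt.endswith("3'") \
                and prev[:-7] == nxt[:-7]:
            label = loop_of[prev[:-7]]
        elif prev == "An-stem3'" and nxt == "T-stem5'":
            label = "V-loop"
        else:
            label = "CC"
        for k in range(pos, end + 1):
            labels[k - 1] = label
        pos = end + 1
    stem_lengths = {f"{arm}-stem": len(h) for arm, h in zip(arms, helices)}
    stem_lengths.setdefault("D-stem", 0)
    loop_lengths = {
        "D-loop": labels.count("D-loop"),
        "An-loop": labels.count("An-loop"),
        "V-loop": labels.count("V-loop"),
        "T-loop": labels.count("T-loop"),
        "CC": labels.count("CC"),
    }
    ann = CloverleafAnnotation(gene.gene_id, labels, stem_lengths,
                               loop_lengths, armless)
    lo, hi = ann.anticodon_span
    acpos = gene.anticodon_position
    if not (lo <= acpos and acpos + 2 <= hi + 1):
        raise ValueError(f"{gene.gene_id}: anticodon not centered in the "
                         "anticodon loop of the supplied structure")
    return ann


def annotate_domains(gene: TRNAGene, structure: str | None = None,
                     constraints: TemplateConstraints = DEFAULT_CONSTRAINTS
                     ) -> CloverleafAnnotation:
    """Annotate a tRNA with cloverleaf domains.

    With ``structure`` (dot-bracket), domains follow the supplied pairing.
    Without it, a constrained template search is run and the layout with
    the most complementary stem pairs wins; ties prefer the canonical
    cloverleaf over the D-armless form, then the longer D-stem, then the
    shorter D-loop/V-loop/T-loop.  Raises ``ValueError("unfoldable: ...")``
    when no layout satisfies the constraints.
    """
    seq = gene.sequence
    if structure is not None:
        return _annotate_from_structure(gene, structure)
    candidates = _template_candidates(gene, constraints)
    if not candidates and seq.endswith("CCA"):
        # mitochondrial tRNA genes do not encode CCA; a trailing unpaired CCA
        # is treated as post-transcriptional and folded around
        logger.warning("%s: trailing CCA not part of the fold, treated as "
                       "3' extension", gene.gene_id)
        trimmed = TRNAGene(gene.gene_id, gene.species_id, gene.isotype,
                           gene.anticodon, gene.strand, gene.start,
                           gene.end, seq[:-3])
        candidates = [(key, CloverleafAnnotation(
            ann.gene_id, ann.domain_of + ["discriminator"] * 3,
            ann.stem_lengths, ann.loop_lengths, ann.d_armless))
            for key, ann in _template_candidates(trimmed, constraints)]
    if not candidates:
        raise ValueError(f"unfoldable: {gene.gene_id} (length {len(seq)}) "
                         "admits no layout under the template constraints")
    best = min(candidates, key=lambda ka: (-_score_pairs(seq, ka[1]), ka[0]))
    return best[1]


def layout_margin(gene: TRNAGene, ann: CloverleafAnnotation,
                  constraints: TemplateConstraints = DEFAULT_CONSTRAINTS
                  ) -> float:
    """Fold-score margin of a reference layout over its best template rival.

    Positive margins mean template-mode annotation would pick the reference
    layout; large margins mean the choice is robust to a few mutations.
    Returns +inf when no alternative layout fits the constraints.
    """
    seq = gene.sequence
    ref = _score_pairs(seq, ann)
    rivals = [_score_pairs(seq, cand)
              for _, cand in _template_candidates(gene, constraints)
              if cand.domain_of != ann.domain_of]
    if not rivals:
        return float("inf")
    return ref - max(rivals)


@dataclass(frozen=True)
class StemPairObservation:
    """One non-Watson-Crick stem pair; wobble (G*T/T*G) flagged separately."""

    pos5: int
    pos3: int
    base5: str
    base3: str
    wobble: bool


def pairing_mismatches(gene: TRNAGene, ann: CloverleafAnnotation
                       ) -> list[StemPairObservation]:
    """All stem pairs that are not Watson-Crick.

    G*T/T*G pairs are reported with ``wobble=True`` so that either
    convention (wobble as valid pair, or wobble as mismatch) is
    recoverable downstream; other non-complementary pairs carry
    ``wobble=False``.
    """
    if not any(v > 0 for v in ann.stem_lengths.values()):
        raise ValueError(f"{gene.gene_id}: annotation has no stems")
    out: list[StemPairObservation] = []
    for p5, p3 in ann.stem_pairs():
        b5, b3 = gene.sequence[p5 - 1], gene.sequence[p3 - 1]
        if (b5, b3) in WATSON_CRICK:
            continue
        if (b5, b3) in WOBBLE:
            out.append(StemPairObservation(p5, p3, b5, b3, True))
        elif not can_pair(b5, b3, allow_wobble=False):
            out.append(StemPairObservation(p5, p3, b5, b3, False))
    return out


def write_annotation_csv(genes: Iterable[TRNAGene],
                         anns: Iterable[CloverleafAnnotation],
                         path: str | Path) -> None:
    """Per-gene domain annotation CSV: gene_id,position,base,domain."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene_id", "position", "base", "domain"])
        for gene, ann in zip(genes, anns):
            for pos, (base, lab) in enumerate(
                    zip(gene.sequence, ann.domain_of), 1):
                writer.writerow([gene.gene_id, pos, base, lab])
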