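"""Domain-preserving multiple alignment of tRNA genes and consensus calling.

Each tRNA gene is aligned across species one structural domain at a time:
homologous domain blocks (as delimited by the cloverleaf annotations) are
aligned independently with a center-star Needleman-Wunsch strategy and then
concatenated, so gap columns never span a domain boundary.  This mirrors
manual structure-aware alignment practice for tRNAs: indels are confined to
the loop regions where they actually occur, and stem homology is never
broken by an alignment artifact.  The center sequence is the one minimizing
the summed edit distance to all others (edit distances via edlib).

The consensus caller emits, per column, the majority base when it reaches
the requested threshold and otherwise the minimal IUPAC degeneracy code
covering all bases tied for the maximal count; gap-majority columns are
excluded from the consensus (but kept in the alignment for indel scoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import edlib

from .cloverleaf import CloverleafAnnotation
from .seqio import SET_TO_IUPAC, TRNAGene


@dataclass(frozen=True)
class AlignParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0


DEFAULT_PARAMS = AlignParams()


@dataclass
class GeneAlignment:
    """A gapped alignment of one tRNA gene across species."""

    isotype: str
    rows: dict[str, str]            # species_id -> gapped sequence
    column_domain: list[str]        # per-column structural-domain label

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if lengths and lengths.pop() != len(self.column_domain):
            raise ValueError("column_domain length mismatch")

    @property
    def length(self) -> int:
        return len(self.column_domain)

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def column(self, index: int) -> list[tuple[str, str]]:
        """(species, base) pairs for a 1-based column index."""
        return [(sp, row[index - 1]) for sp, row in self.rows.items()]

    def subset(self, species: list[str], drop_gap_columns: bool = True
               ) -> "GeneAlignment":
        """Row subset; all-gap columns are dropped by default."""
        rows = {sp: self.rows[sp] for sp in species}
        if not drop_gap_columns:
            return GeneAlignment(self.isotype, rows, list(self.column_domain))
        keep = [j for j in range(self.length)
                if any(r[j] != "-" for r in rows.values())]
        return GeneAlignment(
            self.isotype,
            {sp: "".join(r[j] for j in keep) for sp, r in rows.items()},
            [self.column_domain[j] for j in keep],
        )


def needleman_wunsch(a: str, b: str, params: AlignParams = DEFAULT_PARAMS
                     ) -> tuple[str, str, float]:
    """Global pairwise alignment with linear gap cost; deterministic traceback
    (diagonal preferred over up over left on ties)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * params.gap
    for j in range(1, m + 1):
        score[0][j] = j * params.gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = score[i], score[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (params.match if ai == b[j - 1]
                                  else params.mismatch)
            up = prev[j] + params.gap
            left = row[j - 1] + params.gap
            row[j] = diag if diag >= up and diag >= left else max(up, left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
                params.match if a[i - 1] == b[j - 1] else params.mismatch):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i][j] == score[i - 1][j] + params.gap:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score[n][m]


def _center_star_block(block: dict[str, str], center_sp: str,
                       params: AlignParams) -> dict[str, str]:
    """Center-star MSA of one domain block.

    Every sequence is aligned pairwise to the center; center gap patterns
    are merged slot-wise (max insertions per slot), so each row still
    ungaps to its input.
    """
    core = block[center_sp]
    others = [sp for sp in block if sp != center_sp]
    n = len(core)
    # per-row decomposition: ins[k] = bases aligned to center gaps before
    # core position k (k = 0..n), chars[k] = base aligned to core char k
    decomp: dict[str, tuple[list[str], list[str]]] = {}
    slot_max = [0] * (n + 1)
    for sp in others:
        c_aln, s_aln, _ = needleman_wunsch(core, block[sp], params)
        ins: list[str] = [""] * (n + 1)
        chars: list[str] = []
        k = 0
        for cc, sc in zip(c_aln, s_aln):
            if cc == "-":
                ins[k] += sc
            else:
                chars.append(sc)
                k += 1
        decomp[sp] = (ins, chars)
        for k in range(n + 1):
            slot_max[k] = max(slot_max[k], len(ins[k]))
    out: dict[str, str] = {}
    for sp in block:
        if sp == center_sp:
            ins, chars = [""] * (n + 1), list(core)
        else:
            ins, chars = decomp[sp]
        parts = []
        for k in range(n + 1):
            parts.append(ins[k] + "-" * (slot_max[k] - len(ins[k])))
            if k < n:
                parts.append(chars[k])
        out[sp] = "".join(parts)
    return out


def align_gene(genes: list[TRNAGene], anns: list[CloverleafAnnotation],
               params: AlignParams = DEFAULT_PARAMS) -> GeneAlignment:
    """Align one tRNA gene across species, one domain block at a time.

    All genes must share an isotype and each must carry an annotation with
    the same ordered domain-segment layout (a mixed armless/cloverleaf set
    has no column-wise domain homology and is rejected).
    """
    if len(genes) < 2:
        raise ValueError("need at least two sequences to align")
    isotypes = {g.isotype for g in genes}
    if len(isotypes) != 1:
        raise ValueError(f"mixed isotypes in alignment input: {isotypes}")
    if len(anns) != len(genes):
        raise ValueError("every sequence needs a cloverleaf annotation")
    by_sp = {g.species_id: (g, ann) for g, ann in zip(genes, anns)}
    seg_labels = [tuple(lab for lab, _, _ in ann.segments())
                  for _, ann in by_sp.values()]
    if len(set(seg_labels)) != 1:
        raise ValueError("sequences have incompatible domain layouts")
    layout = seg_labels[0]
    # center: sequence minimizing summed edit distance to all others
    sps = list(by_sp)
    seqs = {sp: by_sp[sp][0].sequence for sp in sps}
    dist_sum = {sp: 0 for sp in sps}
    for i, a in enumerate(sps):
        for b in sps[i + 1:]:
            d = edlib.align(seqs[a], seqs[b])["editDistance"]
            dist_sum[a] += d
            dist_sum[b] += d
    center_sp = min(sps, key=lambda sp: (dist_sum[sp], sp))
    # per-domain blocks in layout order
    rows = {sp: "" for sp in sps}
    column_domain: list[str] = []
    seg_bounds = {sp: by_sp[sp][1].segments() for sp in sps}
    for si, label in enumerate(layout):
        block = {}
        for sp in sps:
            _, start, end = seg_bounds[sp][si]
            block[sp] = seqs[sp][start - 1: end]
        aligned = _center_star_block(block, center_sp, params)
        width = len(next(iter(aligned.values())))
        for sp in sps:
            rows[sp] += aligned[sp]
        column_domain.extend([label] * width)
    return GeneAlignment(next(iter(isotypes)), rows, column_domain)


def consensus(alig: GeneAlignment, threshold: float = 0.95) -> str:
    """Degenerate consensus of a gene alignment.

    Per column: the majority base when its frequency among non-gap rows
    reaches ``threshold``; otherwise the minimal IUPAC code covering all
    bases tied for the maximal count.  Columns in which more than half the
    rows carry a gap are omitted.  ``threshold=0.5`` reproduces a simple
    majority rule.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1.0]")
    if not alig.rows or alig.length == 0:
        raise ValueError("empty alignment")
    nrow = len(alig.rows)
    out: list[str] = []
    for j in range(alig.length):
        col = [r[j] for r in alig.rows.values()]
        gaps = col.count("-")
        if gaps / nrow > 0.5:
            continue
        counts = Counter(b for b in col if b != "-")
        top = max(counts.values())
        tie = frozenset(b for b, c in counts.items() if c == top)
        if len(tie) == 1 and top / (nrow - gaps) >= threshold:
            out.append(next(iter(tie)))
        else:
            out.append(SET_TO_IUPAC[tie] if len(tie) > 1
                       else next(iter(tie)))
    return "".join(out)
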