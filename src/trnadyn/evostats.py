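"""Population-genetic and distance statistics for the tRNA/CDS alignments.

Tajima's D is computed from the standard coefficient chain (a1, a2, b1, b2,
c1, c2, e1, e2) with complete deletion of gap-containing columns, and its
two-tailed significance from the beta approximation over the statistic's
attainable range.  The transition/transversion bias R and the rate ratios
k_purines/k_pyrimidines come from the Tamura-Nei (TN93) closed-form
estimators applied to mismatch proportions pooled over all sequence pairs
(site-weighted), after a partial-deletion column filter (default 95% site
coverage).  Pairwise TN93 distances feed a neighbor-joining tree
(scikit-bio) whose leaf order also serves as the clustering order for
heatmap-style matrix export.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj

from .msa import GeneAlignment

logger = logging.getLogger("trnadyn")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


# ------------------------------------------------------------- Tajima's D --

@dataclass
class TajimaResult:
    n: int                 # sequences
    S: int                 # segregating sites
    pi: float              # mean pairwise differences
    theta_w: float         # Watterson estimator (per locus)
    D: float | None        # None when S == 0
    p_value: float | None  # beta-approximation two-tailed p
    significant: bool      # at the 0.05 level


def tajima_coefficients(n: int) -> dict[str, float]:
    """The a1..e2 coefficient chain for a sample of n sequences."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _tajima_beta_p(D: float, n: int, a1: float, e2: float) -> float:
    """Two-tailed p from the beta approximation of D's null distribution.

    D is bounded; the null density is approximated by a generalized beta
    with mean 0 and variance 1 over [D_min, D_max]."""
    d_min = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    d_max = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(e2)
    rng = d_max - d_min
    m = -d_min / rng
    v = 1.0 / rng ** 2
    k = m * (1 - m) / v - 1
    if k <= 0:
        return 1.0
    a, b = m * k, (1 - m) * k
    x = min(max((D - d_min) / rng, 0.0), 1.0)
    cdf = stats.beta.cdf(x, a, b)
    return float(2 * min(cdf, 1 - cdf))


def tajima_d(alig: GeneAlignment) -> TajimaResult:
    """Tajima's neutrality test on one alignment (complete gap deletion)."""
    rows = list(alig.rows.values())
    n = len(rows)
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    cols = [tuple(r[j] for r in rows) for j in range(alig.length)
            if all(r[j] != "-" for r in rows)]
    S = sum(len(set(c)) > 1 for c in cols)
    npairs = n * (n - 1) // 2
    diffs = 0
    for c in cols:
        counts = {}
        for b in c:
            counts[b] = counts.get(b, 0) + 1
        same = sum(v * (v - 1) // 2 for v in counts.values())
        diffs += npairs - same
    pi = diffs / npairs
    coef = tajima_coefficients(n)
    theta_w = S / coef["a1"]
    if S == 0:
        return TajimaResult(n, 0, 0.0, 0.0, None, None, False)
    var = coef["e1"] * S + coef["e2"] * S * (S - 1)
    D = (pi - theta_w) / math.sqrt(var)
    p = _tajima_beta_p(D, n, coef["a1"], coef["e2"])
    return TajimaResult(n, S, pi, theta_w, D, p, p < 0.05)


# --------------------------------------------------- Tamura-Nei estimators --

@dataclass
class TsTvBias:
    base_freqs: dict[str, float]
    k_purines: float | None        # A<->G rate / transversion rate
    k_pyrimidines: float | None    # C<->T rate / transversion rate
    R: float | None                # overall transition/transversion bias
    sites_used: int


def _coverage_columns(alig: GeneAlignment, cutoff: float) -> list[int]:
    nrow = len(alig.rows)
    keep = []
    for j in range(alig.length):
        nongap = sum(r[j] != "-" for r in alig.rows.values())
        if nongap / nrow >= cutoff:
            keep.append(j)
    return keep


def _pair_mismatch_counts(a: str, b: str, cols: Sequence[int]
                          ) -> tuple[int, int, int, int]:
    """(sites, purine transitions, pyrimidine transitions, transversions)."""
    sites = p1 = p2 = q = 0
    for j in cols:
        x, y = a[j], b[j]
        if x == "-" or y == "-" or x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if {x, y} <= PURINES:
            p1 += 1
        elif {x, y} <= PYRIMIDINES:
            p2 += 1
        else:
            q += 1
    return sites, p1, p2, q


def _tn93_logs(p1: float, p2: float, q: float, g: dict[str, float]
               ) -> tuple[float, float, float] | None:
    """TN93 log terms (L1, L2, L3); None when any log argument is <= 0."""
    gR = g["A"] + g["G"]
    gY = g["C"] + g["T"]
    w1 = 1 - gR * p1 / (2 * g["A"] * g["G"]) - q / (2 * gR)
    w2 = 1 - gY * p2 / (2 * g["C"] * g["T"]) - q / (2 * gY)
    w3 = 1 - q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return None
    return -math.log(w1), -math.log(w2), -math.log(w3)


def tstv_bias(alig: GeneAlignment, coverage_cutoff: float = 0.95) -> TsTvBias:
    """Transition/transversion bias under the Tamura-Nei model.

    Mismatch proportions are pooled (site-weighted) over all sequence
    pairs after the coverage filter; saturated pairs (log argument <= 0)
    are skipped with a warning.  With TN93 rates alpha1 (A<->G), alpha2
    (C<->T) and beta (transversions): k1 = alpha1/beta, k2 = alpha2/beta,
    and R = (gA gG k1 + gC gT k2) / (gR gY).
    """
    if len(alig.rows) < 2:
        raise ValueError("need at least two sequences")
    cols = _coverage_columns(alig, coverage_cutoff)
    rows = alig.rows
    pooled = "".join(r[j] for r in rows.values() for j in cols
                     if r[j] in "ACGT")
    if not pooled:
        raise ValueError("no usable sites after the coverage filter")
    g = {b: pooled.count(b) / len(pooled) for b in "ACGT"}
    if min(g.values()) == 0:
        g = {b: (pooled.count(b) + 1) / (len(pooled) + 4) for b in "ACGT"}
    tot_sites = tot_p1 = tot_p2 = tot_q = 0
    for a, b in combinations(rows.values(), 2):
        sites, p1, p2, q = _pair_mismatch_counts(a, b, cols)
        if sites == 0:
            continue
        if _tn93_logs(p1 / sites, p2 / sites, q / sites, g) is None:
            logger.warning("saturated pair skipped in ts/tv estimation")
            continue
        tot_sites += sites
        tot_p1 += p1
        tot_p2 += p2
        tot_q += q
    if tot_sites == 0 or (tot_p1 + tot_p2 + tot_q) == 0:
        return TsTvBias(g, None, None, None, len(cols))
    P1, P2, Q = (tot_p1 / tot_sites, tot_p2 / tot_sites, tot_q / tot_sites)
    gR, gY = g["A"] + g["G"], g["C"] + g["T"]
    logs = _tn93_logs(P1, P2, Q, g)
    if logs is None:
        logger.warning("pooled mismatch proportions saturated; R undefined")
        return TsTvBias(g, None, None, None, len(cols))
    L1, L2, L3 = logs
    if L3 == 0:
        # transitions but no transversions observed: bias is unbounded
        return TsTvBias(g, math.inf, math.inf, math.inf, len(cols))
    k1 = (L1 - gY * L3) / (gR * L3)
    k2 = (L2 - gR * L3) / (gY * L3)
    R = (g["A"] * g["G"] * k1 + g["C"] * g["T"] * k2) / (gR * gY)
    return TsTvBias(g, k1, k2, R, len(cols))


def tn93_distance(p1: float, p2: float, q: float, g: dict[str, float]
                  ) -> float | None:
    """TN93 distance from mismatch proportions; None when saturated."""
    logs = _tn93_logs(p1, p2, q, g)
    if logs is None:
        return None
    L1, L2, L3 = logs
    gR, gY = g["A"] + g["G"], g["C"] + g["T"]
    k1 = 2 * g["A"] * g["G"] / gR
    k2 = 2 * g["C"] * g["T"] / gY
    k3 = 2 * (gR * gY - g["A"] * g["G"] * gY / gR - g["C"] * g["T"] * gR / gY)
    return k1 * L1 + k2 * L2 + k3 * L3


def distance_matrix(aligs: GeneAlignment | Sequence[GeneAlignment]
                    ) -> pd.DataFrame:
    """Pairwise TN93 distance matrix across species.

    Multiple gene alignments are concatenated by species; sites are
    compared pairwise-complete.  Saturated pairs are set to 1.5x the
    largest finite distance with a warning.
    """
    if isinstance(aligs, GeneAlignment):
        aligs = [aligs]
    species = sorted(set.intersection(*(set(a.rows) for a in aligs)))
    if len(species) < 2:
        raise ValueError("need at least two shared species")
    cat = {sp: "".join(a.rows[sp] for a in aligs) for sp in species}
    pooled = "".join(b for s in cat.values() for b in s if b in "ACGT")
    g = {b: (pooled.count(b) + 1) / (len(pooled) + 4) for b in "ACGT"}
    n = len(species)
    mat = np.zeros((n, n))
    saturated = []
    for i, j in combinations(range(n), 2):
        a, b = cat[species[i]], cat[species[j]]
        sites, p1, p2, q = _pair_mismatch_counts(a, b, range(len(a)))
        if sites == 0:
            saturated.append((i, j))
            continue
        d = tn93_distance(p1 / sites, p2 / sites, q / sites, g)
        if d is None:
            saturated.append((i, j))
            continue
        mat[i, j] = mat[j, i] = d
    if saturated:
        finite_max = mat.max()
        fallback = finite_max * 1.5 if finite_max > 0 else 1.0
        logger.warning("%d saturated pairs set to %.4f",
                       len(saturated), fallback)
        for i, j in saturated:
            mat[i, j] = mat[j, i] = fallback
    return pd.DataFrame(mat, index=species, columns=species)


def nj_tree(matrix: pd.DataFrame) -> str:
    """Neighbor-joining tree (newick, with branch lengths) from a square
    symmetric distance matrix."""
    if not np.allclose(matrix.values, matrix.values.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(matrix.values), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    dm = DistanceMatrix(matrix.values, ids=list(matrix.index))
    tree = nj(dm)
    return str(tree).strip()


def leaf_order(newick: str) -> list[str]:
    """Tip names in tree traversal order (clustering order for heatmaps)."""
    import io
    from skbio import TreeNode
    tree = TreeNode.read(io.StringIO(newick))
    return [t.name for t in tree.tips()]


def ordered_matrix(matrix: pd.DataFrame, newick: str) -> pd.DataFrame:
    """Distance matrix reordered by the NJ clustering order."""
    order = [name for name in leaf_order(newick) if name in matrix.index]
    return matrix.loc[order, order]
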