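"""Codon-level mutation accounting under the vertebrate mitochondrial code.

SNPs in protein-coding genes are classified against a designated reference
at the codon level: synonymous, nonsynonymous, truncation (substitution to
a stop), deletion (gap length a multiple of three) or frameshift (any other
gap length).  Nonsynonymous changes are tallied into a 20x20 amino-acid
change matrix whose row sums are the "backward" counts (changes away from
an amino acid) and column sums the "forward" counts (changes toward it).
The module also provides the correlation machinery used to relate CDS and
tRNA mutation loads: Pearson correlation, the partial Mantel test
(residual-permutation method) and a BH-FDR battery helper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from Bio.Data import CodonTable

logger = logging.getLogger("trnadyn")

_VMITO = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

CODON_TO_AA: dict[str, str] = dict(_VMITO.forward_table)
for _stop in _VMITO.stop_codons:       # TAA, TAG, AGA, AGG
    CODON_TO_AA[_stop] = "*"

EFFECTS = ("synonymous", "nonsynonymous", "truncation", "deletion",
           "frameshift")


def translate_codon(codon: str) -> str:
    """One codon -> 1-letter amino acid ('*' for stop) under the vertebrate
    mitochondrial code (TGA=Trp, AGA/AGG=stop, ATA=Met)."""
    codon = codon.upper()
    if codon not in CODON_TO_AA:
        raise ValueError(f"cannot translate codon {codon!r}")
    return CODON_TO_AA[codon]


@dataclass(frozen=True)
class CDSMutation:
    gene: str
    codon_index: int       # 1-based
    ref_codon: str
    alt_codon: str
    effect: str
    ref_aa: str | None
    alt_aa: str | None


def classify_codon_change(ref_codon: str, alt_codon: str,
                          gene: str = "", codon_index: int = 0
                          ) -> CDSMutation:
    """Classify one aligned ref/alt codon pair.

    Codons are over {A,C,G,T,-}; any gap makes the change structural
    (deletion when the total gap length is a multiple of three, frameshift
    otherwise).  Substitution to a stop codon is a truncation.
    """
    ref_codon = ref_codon.upper()
    alt_codon = alt_codon.upper()
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or any(ch not in "ACGT-" for ch in codon):
            raise ValueError(f"bad codon {codon!r}")
    n_gaps = ref_codon.count("-") + alt_codon.count("-")
    if n_gaps:
        effect = "deletion" if n_gaps % 3 == 0 else "frameshift"
        return CDSMutation(gene, codon_index, ref_codon, alt_codon,
                           effect, None, None)
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "truncation"
    else:
        effect = "nonsynonymous"
    return CDSMutation(gene, codon_index, ref_codon, alt_codon, effect,
                       ref_aa, alt_aa)


def scan_cds(ref: str, alt: str, gene: str = "") -> list[CDSMutation]:
    """Codon-by-codon comparison of two aligned, equal-length CDS strings.

    Identical codons yield no record.  A trailing partial codon (an
    incomplete stop completed by polyadenylation in mitochondrial mRNAs) is
    treated as a complete stop and skipped when identical, logged otherwise.
    """
    if len(ref) != len(alt):
        raise ValueError("ref and alt CDS must be aligned to equal length")
    out: list[CDSMutation] = []
    full = len(ref) - len(ref) % 3
    for i in range(0, full, 3):
        r, a = ref[i:i + 3], alt[i:i + 3]
        if r == a:
            continue
        out.append(classify_codon_change(r, a, gene, i // 3 + 1))
    if full < len(ref) and ref[full:] != alt[full:]:
        logger.warning("%s: mutation in incomplete terminal stop codon "
                       "(%r -> %r), not classified", gene, ref[full:],
                       alt[full:])
    return out


@dataclass
class AAChangeMatrix:
    """Forward/backward nonsynonymous change tallies per amino acid."""

    matrix: pd.DataFrame     # 20x20, rows = from (backward), cols = to

    @property
    def forward(self) -> dict[str, int]:
        return {aa: int(self.matrix[aa].sum()) for aa in AMINO_ACIDS}

    @property
    def backward(self) -> dict[str, int]:
        return {aa: int(self.matrix.loc[aa].sum()) for aa in AMINO_ACIDS}

    @property
    def total(self) -> int:
        return int(self.matrix.values.sum())


def aa_change_matrix(mutations: Iterable[CDSMutation]) -> AAChangeMatrix:
    """Tally nonsynonymous changes X->Y into the 20x20 change matrix."""
    mat = pd.DataFrame(0, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    for mut in mutations:
        if mut.effect != "nonsynonymous":
            continue
        if mut.ref_aa not in AMINO_ACIDS or mut.alt_aa not in AMINO_ACIDS:
            # stop-loss (reference stop replaced by a sense codon) carries
            # no amino-acid-to-amino-acid change to tally
            continue
        mat.loc[mut.ref_aa, mut.alt_aa] += 1
    return AAChangeMatrix(mat)


# ------------------------------------------------------------ correlation --

def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-tailed p; zero-variance input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices_from(m, k=-1)]


def _residuals(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_mantel(A: np.ndarray, B: np.ndarray, C: np.ndarray,
                   n_perm: int = 999, seed: int | None = None
                   ) -> tuple[float, float]:
    """Partial Mantel test of A vs B controlling for C.

    Residual-permutation method: the lower triangles of A and B are
    residualized on C, the observed statistic is the Pearson correlation
    of the residuals, and the null is built by jointly permuting rows and
    columns of A's residual matrix ``n_perm`` times (two-tailed p with the
    +1 correction).
    """
    A, B, C = (np.asarray(m, dtype=float) for m in (A, B, C))
    if not (A.shape == B.shape == C.shape) or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    if A.shape[0] < 4:
        raise ValueError("matrices too small for a permutation test")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    for m in (A, B, C):
        if not np.allclose(m, m.T):
            raise ValueError("matrices must be symmetric")
    c = _lower_triangle(C)
    res_a = _residuals(_lower_triangle(A), c)
    res_b = _residuals(_lower_triangle(B), c)
    if res_a.std() == 0 or res_b.std() == 0:
        raise ValueError("zero variance after residualization")
    r_obs = float(np.corrcoef(res_a, res_b)[0, 1])
    # residuals of A back in matrix form for row/column permutation
    n = A.shape[0]
    RA = np.zeros_like(A)
    RA[np.tril_indices(n, k=-1)] = res_a
    RA = RA + RA.T
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = _lower_triangle(RA[np.ix_(perm, perm)])
        r_perm = np.corrcoef(rp, res_b)[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return r_obs, float(p)


def correlation_battery(vectors_a: Mapping[str, Sequence[float]],
                        vectors_b: Mapping[str, Sequence[float]]
                        ) -> pd.DataFrame:
    """All-pairs Pearson correlations with BH-FDR q-values."""
    rows = []
    for name_a, va in sorted(vectors_a.items()):
        for name_b, vb in sorted(vectors_b.items()):
            r, p = correlate(va, vb)
            rows.append((name_a, name_b, r, p))
    df = pd.DataFrame(rows, columns=["a", "b", "r", "p"])
    if len(df):
        df["q_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
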