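"""Input/output and record normalization for mitogenome tRNA analysis.

Reads annotated mitogenome records (GenBank flat files via Biopython),
per-gene FASTA, tab-separated dot-bracket structure files and the cohort
membership CSV, and writes the pipeline's FASTA/CSV products.  All
coordinates are 1-based inclusive (GenBank convention) and every tRNA
sequence is reported 5'->3' in the orientation of the gene product, i.e.
reverse-strand features are reverse-complemented on extraction.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("trnadyn")

# The 22 vertebrate mitochondrial tRNA isotypes.  Leucine and serine occur
# twice each and are disambiguated by anticodon (gene-strand DNA triplet).
AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

# Canonical anticodons (DNA, as written in the gene, 5'->3') for vertebrate
# mitochondrial tRNAs; used to resolve duplicated isotypes and as generator
# truth.  RNA anticodon UAA is written TAA here.
MT_ANTICODONS = {
    "trnF": "GAA", "trnV": "TAC", "trnL-UAA": "TAA", "trnI": "GAT",
    "trnQ": "TTG", "trnM": "CAT", "trnW": "TCA", "trnA": "TGC",
    "trnN": "GTT", "trnC": "GCA", "trnY": "GTA", "trnS-UGA": "TGA",
    "trnD": "GTC", "trnK": "TTT", "trnG": "TCC", "trnR": "TCG",
    "trnH": "GTG", "trnS-GCU": "GCT", "trnL-UAG": "TAG", "trnE": "TTC",
    "trnT": "TGT", "trnP": "TGG",
}

ISOTYPES = tuple(MT_ANTICODONS)

# Strand layout of the vertebrate/cichlid mitogenome: eight tRNA genes sit
# on the reverse strand.
REVERSE_STRAND_ISOTYPES = frozenset(
    {"trnQ", "trnA", "trnN", "trnC", "trnY", "trnS-UGA", "trnE", "trnP"}
)

# The single D-armless isotype in cichlid (and generally metazoan) mitogenomes.
D_ARMLESS_ISOTYPE = "trnS-GCU"

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) DNA string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class TRNAGene:
    """One mitochondrial tRNA gene instance.

    ``sequence`` is the 5'->3' gene product orientation; ``start``/``end``
    are 1-based inclusive coordinates on the source mitogenome.
    """

    gene_id: str
    species_id: str
    isotype: str
    anticodon: str
    strand: str  # "forward" | "reverse"
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.anticodon = self.anticodon.upper()
        if not 50 <= len(self.sequence) <= 100:
            raise ValueError(
                f"{self.gene_id}: tRNA length {len(self.sequence)} outside [50, 100]"
            )
        if any(b not in IUPAC_SETS for b in self.sequence):
            raise ValueError(f"{self.gene_id}: non-IUPAC character in sequence")
        if self.anticodon not in self.sequence:
            raise ValueError(f"{self.gene_id}: anticodon not found in sequence")
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.strand == "forward" and self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start on forward strand")

    @property
    def anticodon_position(self) -> int:
        """1-based position of the anticodon's first base in ``sequence``."""
        return self.sequence.index(self.anticodon) + 1


@dataclass
class CohortTable:
    """Species membership in the nested study cohorts.

    ``Ci`` is the full family-level set, ``Ht`` the sublineage subset
    (haplotilapiine in the motivating study); Ht is always a subset of Ci.
    """

    in_family: dict[str, bool] = field(default_factory=dict)
    in_sublineage: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, ht in self.in_sublineage.items():
            if ht and not self.in_family.get(sp, False):
                raise ValueError(f"{sp}: in sublineage but not in family")

    @property
    def family(self) -> list[str]:
        return sorted(s for s, v in self.in_family.items() if v)

    @property
    def sublineage(self) -> list[str]:
        return sorted(s for s, v in self.in_sublineage.items() if v)


def _isotype_from_feature(feature, gene_seq: str) -> tuple[str, str] | None:
    """Resolve (isotype, anticodon) from a Biopython tRNA feature.

    Uses the product/gene qualifier for the amino acid and the anticodon
    qualifier when present; L/S duplicates without an anticodon qualifier
    are disambiguated by searching the gene sequence for the two candidate
    anticodon triplets near the expected anticodon-loop region.
    """
    label = (feature.qualifiers.get("product", [""])[0]
             or feature.qualifiers.get("gene", [""])[0])
    aa1 = None
    for aa3, one in AA3_TO_1.items():
        if aa3.lower() in label.lower():
            aa1 = one
            break
    if aa1 is None:
        # labels like "trnF" / "trnL-UAA"
        stripped = label.replace("tRNA-", "trn").split("^")[0]
        for iso in ISOTYPES:
            if stripped.startswith(iso.split("-")[0]) and (
                iso == stripped or "-" not in iso
            ):
                aa1 = iso[3]
                break
    if aa1 is None:
        return None
    candidates = [i for i in ISOTYPES if i[3] == aa1]
    qual_ac = feature.qualifiers.get("anticodon", [""])[0]
    # anticodon qualifier may be "(pos:..,aa:..,seq:gca)" or a bare triplet
    ac = ""
    if "seq:" in qual_ac:
        ac = qual_ac.split("seq:")[1].strip(") ").upper().replace("U", "T")
    elif len(qual_ac.strip()) == 3:
        ac = qual_ac.strip().upper().replace("U", "T")
    if len(candidates) == 1:
        return candidates[0], ac or MT_ANTICODONS[candidates[0]]
    for iso in candidates:
        if ac and MT_ANTICODONS[iso] == ac:
            return iso, ac
    # fall back: search the middle third of the gene for a candidate anticodon
    mid = gene_seq[len(gene_seq) // 3: 2 * len(gene_seq) // 3 + 3]
    for iso in candidates:
        if MT_ANTICODONS[iso] in mid:
            return iso, MT_ANTICODONS[iso]
    return None


def extract_trna_genes(record: SeqRecord, species_id: str | None = None
                       ) -> list[TRNAGene]:
    """Extract all tRNA genes from an annotated mitogenome record.

    Reverse-strand features are reverse-complemented so that ``sequence``
    is the 5'->3' gene product.  Features whose isotype cannot be resolved
    are skipped with a warning; a record yielding fewer than 20 distinct
    isotypes is flagged incomplete (warning) for downstream QC.
    """
    species = species_id or record.id
    genes: list[TRNAGene] = []
    for feature in record.features:
        if feature.type != "tRNA":
            continue
        start = int(feature.location.start) + 1  # to 1-based inclusive
        end = int(feature.location.end)
        raw = str(record.seq[start - 1: end]).upper()
        reverse = feature.location.strand == -1
        seq = revcomp(raw) if reverse else raw
        resolved = _isotype_from_feature(feature, seq)
        if resolved is None:
            logger.warning("%s: unresolvable tRNA feature at %d..%d, skipped",
                           species, start, end)
            continue
        isotype, anticodon = resolved
        genes.append(TRNAGene(
            gene_id=f"{species}|{isotype}",
            species_id=species,
            isotype=isotype,
            anticodon=anticodon or MT_ANTICODONS[isotype],
            strand="reverse" if reverse else "forward",
            start=start,
            end=end,
            sequence=seq,
        ))
    if len({g.isotype for g in genes}) < 20:
        logger.warning("%s: flagged incomplete (<20 distinct tRNA isotypes)",
                       species)
    return genes


def qc_filter(genes_by_species: Mapping[str, list[TRNAGene]],
              max_ambiguous_frac: float = 0.05,
              length_sd: float = 3.0) -> dict[str, list[TRNAGene]]:
    """Cohort-level QC: drop species records that are structurally suspect.

    A species is dropped when it (a) is missing any of the 22 isotypes,
    (b) has a summed tRNA length outside mean +/- ``length_sd`` SD of the
    cohort, or (c) carries more than ``max_ambiguous_frac`` ambiguous bases.
    These deterministic filters stand in for manual curation of anomalous
    database records.
    """
    totals = {}
    for sp, genes in genes_by_species.items():
        totals[sp] = sum(len(g.sequence) for g in genes)
    mean = float(np.mean(list(totals.values())))
    sd = float(np.std(list(totals.values())))
    kept: dict[str, list[TRNAGene]] = {}
    for sp, genes in genes_by_species.items():
        isotypes = {g.isotype for g in genes}
        if len(isotypes) < 22:
            logger.warning("QC drop %s: only %d isotypes", sp, len(isotypes))
            continue
        if sd > 0 and abs(totals[sp] - mean) > length_sd * sd:
            logger.warning("QC drop %s: total tRNA length %d outlier", sp,
                           totals[sp])
            continue
        nt = "".join(g.sequence for g in genes)
        amb = sum(b not in "ACGT" for b in nt)
        if amb / len(nt) > max_ambiguous_frac:
            logger.warning("QC drop %s: %.1f%% ambiguous bases", sp,
                           100 * amb / len(nt))
            continue
        kept[sp] = list(genes)
    return kept


def check_balanced(structure: str) -> bool:
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return False
        elif ch != ".":
            return False
    return depth == 0


def read_structure_file(path: str | Path,
                        lengths: Mapping[str, int] | None = None
                        ) -> dict[str, str]:
    """Read a tab-separated ``gene_id<TAB>dot-bracket`` structure file.

    Raises ``ValueError`` naming the offending line for unbalanced brackets
    or (when ``lengths`` is supplied) a structure whose length differs from
    the named gene's sequence length.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                gene_id, struct = line.split("\t")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected id<TAB>structure")
            if not check_balanced(struct):
                raise ValueError(
                    f"{path}:{lineno}: unbalanced dot-bracket for {gene_id}")
            if lengths is not None and gene_id in lengths \
                    and len(struct) != lengths[gene_id]:
                raise ValueError(
                    f"{path}:{lineno}: structure length {len(struct)} != "
                    f"sequence length {lengths[gene_id]} for {gene_id}")
            out[gene_id] = struct
    return out


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read the cohort CSV with header ``species_id,in_family,in_sublineage``."""
    in_family: dict[str, bool] = {}
    in_sub: dict[str, bool] = {}
    truthy = {"1", "true", "yes", "y"}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            sp = row["species_id"]
            if sp in in_family:
                raise ValueError(f"duplicate species {sp} in cohort table")
            in_family[sp] = row["in_family"].strip().lower() in truthy
            in_sub[sp] = row["in_sublineage"].strip().lower() in truthy
    return CohortTable(in_family=in_family, in_sublineage=in_sub)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species_id", "in_family", "in_sublineage"])
        for sp in sorted(table.in_family):
            writer.writerow([sp, int(table.in_family[sp]),
                             int(table.in_sublineage.get(sp, False))])


def write_fasta(seqs: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_genbank(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "genbank"))
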