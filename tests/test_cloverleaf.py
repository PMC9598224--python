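"""Cloverleaf domain annotation: template search, structure mode, pairing."""

import numpy as np
import pytest

from trnadyn import TRNAGene, annotate_domains, pairing_mismatches
from trnadyn.cloverleaf import can_pair
from trnadyn.seqio import MT_ANTICODONS

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def build_trna(isotype: str, d: int, dl: int, v: int, tl: int,
               seed: int = 0) -> TRNAGene:
    """A perfectly base-paired cloverleaf tRNA with the given geometry."""
    rng = np.random.default_rng(seed)
    layout = [("A-stem5'", 7), ("CC", 2), ("D-stem5'", d), ("D-loop", dl),
              ("D-stem3'", d), ("CC", 1), ("An-stem5'", 5), ("An-loop", 7),
              ("An-stem3'", 5), ("V-loop", v), ("T-stem5'", 5),
              ("T-loop", tl), ("T-stem3'", 5), ("A-stem3'", 7),
              ("discriminator", 1)]
    labels = [lab for lab, n in layout for _ in range(n)]
    L = len(labels)
    seq = [""] * L
    # anticodon at the center of the 7-nt anticodon loop
    loop = [i for i, lab in enumerate(labels) if lab == "An-loop"]
    anticodon = MT_ANTICODONS[isotype]
    for k, i in enumerate(loop[2:5]):
        seq[i] = anticodon[k]
    for arm in ("A", "D", "An", "T"):
        p5 = [i for i, lab in enumerate(labels) if lab == f"{arm}-stem5'"]
        p3 = [i for i, lab in enumerate(labels) if lab == f"{arm}-stem3'"]
        for i, j in zip(p5, reversed(p3)):
            b = "ACGT"[rng.integers(4)]
            seq[i], seq[j] = b, _WC[b]
    for i in range(L):
        if not seq[i]:
            seq[i] = "ACGT"[rng.integers(4)]
    return TRNAGene(f"test|{isotype}", "test", isotype, anticodon,
                    "forward", 1, L, "".join(seq))


class TestTemplateMode:
    def test_canonical_71nt_geometry(self):
        """A 71-nt tRNA with the anticodon at 33-35 resolves to the fixed
        stem lengths: acceptor 7 bp, anticodon 5 bp, T 5 bp, D 4 bp."""
        gene = build_trna("trnF", d=4, dl=7, v=4, tl=7)
        assert len(gene.sequence) == 71
        assert gene.sequence[32:35] == "GAA"
        ann = annotate_domains(gene)
        assert ann.stem_lengths == {"A-stem": 7, "D-stem": 4,
                                    "An-stem": 5, "T-stem": 5}
        assert not ann.d_armless

    def test_armless_gene_detected(self, cohort):
        sp = cohort.species[0]
        gene = cohort.genes["trnS-GCU"][sp]
        ann = annotate_domains(gene)
        assert ann.d_armless
        assert ann.stem_lengths["D-stem"] == 0
        assert ann.loop_lengths["D-loop"] == 0

    def test_short_sequence_unfoldable(self):
        gene = TRNAGene("g", "sp", "trnF", "GAA", "forward", 1, 50,
                        "GAA" + "ACTG" * 12 + "TT")
        with pytest.raises(ValueError, match="unfoldable"):
            annotate_domains(gene)

    def test_below_minimum_viable_length_rejected(self):
        # a 40-nt input cannot even be a valid tRNA gene record
        with pytest.raises(ValueError):
            TRNAGene("g", "sp", "trnF", "GAA", "forward", 1, 40, "GAA" * 13
                     + "A")

    def test_case_invariant(self):
        gene = build_trna("trnK", d=3, dl=4, v=5, tl=8)
        lower = TRNAGene(gene.gene_id, "test", gene.isotype, gene.anticodon,
                         "forward", 1, len(gene.sequence),
                         gene.sequence.lower())
        assert annotate_domains(gene).domain_of == \
            annotate_domains(lower).domain_of


class TestInvariants:
    def test_domains_tile_sequence(self, aligned_cohort):
        cohort, anns, _ = aligned_cohort
        for iso, by_sp in anns.items():
            for sp, ann in by_sp.items():
                assert len(ann.domain_of) == \
                    len(cohort.genes[iso][sp].sequence)
                p5 = ann.positions_of("A-stem5'")
                p3 = ann.positions_of("A-stem3'")
                assert len(p5) == len(p3)

    def test_template_mode_recovers_generator_truth(self, aligned_cohort):
        """Every emitted sequence re-annotates to its true boundaries."""
        cohort, anns, _ = aligned_cohort
        for iso, by_sp in anns.items():
            for sp, ann in by_sp.items():
                assert ann.domain_of == \
                    cohort.annotations[iso][sp].domain_of, (iso, sp)


class TestStructureMode:
    @staticmethod
    def dot_bracket(ann):
        out = []
        for lab in ann.domain_of:
            if lab.endswith("5'") and "stem" in lab:
                out.append("(")
            elif lab.endswith("3'") and "stem" in lab:
                out.append(")")
            else:
                out.append(".")
        return "".join(out)

    def test_structure_mode_matches_template_mode(self):
        gene = build_trna("trnG", d=4, dl=8, v=5, tl=7)
        template_ann = annotate_domains(gene)
        struct_ann = annotate_domains(gene,
                                      self.dot_bracket(template_ann))
        assert struct_ann.domain_of == template_ann.domain_of

    def test_structure_length_mismatch_rejected(self):
        gene = build_trna("trnG", d=4, dl=8, v=5, tl=7)
        with pytest.raises(ValueError, match="length"):
            annotate_domains(gene, "(((...)))")


class TestPairingMismatches:
    def test_wc_silent_wobble_flagged_mismatch_reported(self):
        gene = build_trna("trnT", d=4, dl=6, v=4, tl=8, seed=3)
        ann = annotate_domains(gene)
        assert pairing_mismatches(gene, ann) == []
        seq = list(gene.sequence)
        pairs = ann.stem_pairs()
        # force a wobble on the first A-stem pair and a hard mismatch on
        # the second
        (w5, w3), (m5, m3) = pairs[0], pairs[1]
        seq[w5 - 1], seq[w3 - 1] = "G", "T"
        seq[m5 - 1], seq[m3 - 1] = "C", "A"
        mutant = TRNAGene(gene.gene_id, "test", gene.isotype, gene.anticodon,
                          "forward", 1, len(seq), "".join(seq))
        found = {(m.pos5, m.pos3): m for m in pairing_mismatches(mutant, ann)}
        assert found[(w5, w3)].wobble
        assert not found[(m5, m3)].wobble
        assert len(found) == 2

    def test_can_pair_semantics(self):
        assert can_pair("A", "T") and can_pair("G", "C")
        assert can_pair("G", "T") and not can_pair("G", "T",
                                                   allow_wobble=False)
        assert not can_pair("C", "A")
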