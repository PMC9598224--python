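"""Domain-blocked alignment and degenerate consensus."""

import numpy as np
import pytest

from trnadyn import GeneAlignment, align_gene, annotate_domains, consensus
from trnadyn.msa import AlignParams, needleman_wunsch

from test_cloverleaf import build_trna


def nw_oracle(a: str, b: str, params: AlignParams) -> float:
    """Independent exhaustive DP optimum (score only), memoized recursion."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == 0:
            return j * params.gap
        if j == 0:
            return i * params.gap
        sub = params.match if a[i - 1] == b[j - 1] else params.mismatch
        return max(best(i - 1, j - 1) + sub,
                   best(i - 1, j) + params.gap,
                   best(i, j - 1) + params.gap)

    return best(len(a), len(b))


class TestPairwise:
    @pytest.mark.parametrize("seed", range(5))
    def test_nw_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = AlignParams()
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 15)))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 15)))
        out_a, out_b, score = needleman_wunsch(a, b, params)
        assert score == nw_oracle(a, b, params)
        assert out_a.replace("-", "") == a
        assert out_b.replace("-", "") == b


class TestAlignGene:
    def test_identical_sequences_align_gap_free(self):
        gene = build_trna("trnM", d=4, dl=6, v=4, tl=7)
        ann = annotate_domains(gene)
        genes = []
        for sp in ("s1", "s2"):
            g = build_trna("trnM", d=4, dl=6, v=4, tl=7)
            g.species_id = sp
            genes.append(g)
        alig = align_gene(genes, [ann, ann])
        assert alig.length == len(gene.sequence)
        assert "-" not in "".join(alig.rows.values())
        assert len(set(alig.rows.values())) == 1

    def test_single_shorter_d_loop_gives_one_d_loop_gap_column(self):
        from trnadyn import TRNAGene
        base = build_trna("trnM", d=4, dl=6, v=4, tl=7, seed=1)
        ann = annotate_domains(base)
        # delete one D-loop base from the third species
        drop = ann.positions_of("D-loop")[2]
        short_seq = base.sequence[:drop - 1] + base.sequence[drop:]
        genes = []
        for sp in ("s1", "s2"):
            g = build_trna("trnM", d=4, dl=6, v=4, tl=7, seed=1)
            g.species_id = sp
            genes.append(g)
        genes.append(TRNAGene("s3|trnM", "s3", "trnM", base.anticodon,
                              "forward", 1, len(short_seq), short_seq))
        anns = [annotate_domains(g) for g in genes]
        alig = align_gene(genes, anns)
        gap_cols = [j for j in range(alig.length)
                    if any(r[j] == "-" for r in alig.rows.values())]
        assert len(gap_cols) == 1
        assert alig.column_domain[gap_cols[0]] == "D-loop"

    def test_rows_ungap_to_inputs_and_gaps_stay_in_domain(self,
                                                          aligned_cohort):
        cohort, _, aligs = aligned_cohort
        for iso, alig in aligs.items():
            for sp, row in alig.rows.items():
                assert row.replace("-", "") == cohort.genes[iso][sp].sequence
            # no gap column spans a domain boundary: each domain forms
            # contiguous column runs (CC legitimately occurs twice)
            from collections import Counter
            runs = [lab for i, lab in enumerate(alig.column_domain)
                    if i == 0 or alig.column_domain[i - 1] != lab]
            counts = Counter(runs)
            assert all(v == 1 for lab, v in counts.items() if lab != "CC")
            assert counts.get("CC", 0) <= 2

    def test_mixed_isotypes_rejected(self):
        a = build_trna("trnM", d=4, dl=6, v=4, tl=7)
        b = build_trna("trnT", d=4, dl=6, v=4, tl=7)
        with pytest.raises(ValueError, match="isotype"):
            align_gene([a, b], [annotate_domains(a), annotate_domains(b)])


class TestConsensus:
    @staticmethod
    def _alig(columns, n_extra_domains=None):
        """Build a toy alignment from per-column base lists."""
        nrow = len(columns[0])
        rows = {f"s{i}": "".join(col[i] for col in columns)
                for i in range(nrow)}
        return GeneAlignment("trnX", rows, ["D-loop"] * len(columns))

    def test_majority_base_at_threshold(self):
        # 24 of 25 rows carry A (96%) -> plain A at the 95% rule
        alig = self._alig([["A"] * 24 + ["G"]])
        assert consensus(alig, 0.95) == "A"

    def test_even_tie_gives_degenerate_code(self):
        alig = self._alig([["A", "A", "G", "G"]])
        assert consensus(alig, 0.95) == "R"

    def test_unique_maximum_below_threshold_stays_plain(self):
        # 40/35/25 split: A uniquely maximal, minimal covering code is A
        col = ["A"] * 8 + ["G"] * 7 + ["C"] * 5
        assert consensus(self._alig([col]), 0.95) == "A"

    def test_identity_at_majority_threshold(self):
        alig = self._alig([["A"] * 3, ["C"] * 3, ["G"] * 3])
        assert consensus(alig, 0.5) == "ACG"

    def test_gap_majority_column_omitted(self):
        alig = self._alig([["A", "A", "A"], ["-", "-", "C"]])
        assert consensus(alig, 0.95) == "A"

    def test_threshold_bounds(self):
        alig = self._alig([["A", "A"]])
        with pytest.raises(ValueError):
            consensus(alig, 0.3)
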