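"""Substitution-quantification: labels, weights, profiles, z-categories."""

from collections import Counter
from itertools import product

import numpy as np
import pytest

from trnadyn import (GeneAlignment, assign_weights, classify_alignment,
                     classify_column, weighted_profile, weights_for,
                     zscore_categorize)
from trnadyn.subquant import CategoryWeights, category_totals


def oracle_classify(bases):
    """Independent rule-table reimplementation of column labeling.

    Dominant = most frequent base (IUPAC-degenerate on ties, with the
    earliest tie member in A<C<G<T order as the conserved designate);
    an insertion locus when gaps outnumber every base, a deletion locus
    otherwise; substitutions split into transitions/transversions by
    purine/pyrimidine class relative to the designate.
    """
    counts = Counter(b for b in bases if b != "-")
    gaps = bases.count("-")
    if not counts:
        raise ValueError("all gaps")
    best = max(counts.values())
    if gaps > best:
        return ["C" if b == "-" else "I" for b in bases]
    tie = sorted([b for b in counts if counts[b] == best])
    designate = tie[0]
    purine = set("AG")
    out = []
    for b in bases:
        if b == "-":
            out.append("D")
        elif b == designate:
            out.append("C")
        elif (b in purine) == (designate in purine):
            out.append("S")
        else:
            out.append("V")
    return out


class TestClassifyColumn:
    @pytest.mark.parametrize("bases,dominant,labels", [
        (("A", "A", "G"), "A", ("C", "C", "S")),
        (("A", "A", "C"), "A", ("C", "C", "V")),
        (("A", "G"), "R", ("C", "S")),
        (("A", "A", "A", "-", "G"), "A", ("C", "C", "C", "D", "S")),
        (("A", "-", "-", "-"), "-", ("I", "C", "C", "C")),
        (("C", "T", "T", "C"), "Y", ("C", "S", "S", "C")),
    ])
    def test_printed_examples(self, bases, dominant, labels):
        col = [(f"s{i}", b) for i, b in enumerate(bases)]
        cls = classify_column(col, 1)
        assert cls.dominant == dominant
        assert tuple(cls.labels[f"s{i}"] for i in range(len(bases))) == labels
        assert sum(cls.counts.values()) == len(bases)

    def test_exhaustive_rule_table_equivalence(self):
        """Every column over <=5 rows agrees with the independent oracle."""
        for k in (2, 3, 4, 5):
            for bases in product("ACGT-", repeat=k):
                col = [(f"s{i}", b) for i, b in enumerate(bases)]
                if all(b == "-" for b in bases):
                    with pytest.raises(ValueError):
                        classify_column(col, 1)
                    continue
                cls = classify_column(col, 1)
                expect = oracle_classify(list(bases))
                got = [cls.labels[f"s{i}"] for i in range(k)]
                assert got == expect, bases

    def test_permutation_invariance_of_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            bases = [("ACGT-")[i] for i in rng.integers(0, 5, 6)]
            if all(b == "-" for b in bases):
                continue
            col = [(f"s{i}", b) for i, b in enumerate(bases)]
            cls = classify_column(col, 1)
            perm = rng.permutation(6)
            col2 = [(f"t{i}", bases[p]) for i, p in enumerate(perm)]
            assert classify_column(col2, 1).counts == cls.counts

    def test_vacuous_column_rejected(self):
        with pytest.raises(ValueError, match="vacuous"):
            classify_column([("a", "-"), ("b", "-")], 1)


class TestWeights:
    def test_count_ranked_ladder(self):
        w = assign_weights({"C": 40, "V": 16, "S": 14, "D": 5, "I": 3})
        assert w.weight_of == {"C": 0.00, "V": 0.25, "S": 0.50,
                               "D": 0.75, "I": 1.00}

    def test_substitution_only_fixed_weights(self):
        w = assign_weights({"C": 10, "S": 3, "V": 1}, substitution_only=True)
        assert w.weight_of == {"C": 0.00, "S": 0.25, "V": 0.50}

    def test_tie_broken_by_fixed_category_order(self):
        w = assign_weights({"C": 10, "S": 10})
        assert w.weight_of["C"] == 0.00
        assert w.weight_of["S"] == 0.25

    def test_weights_for_dispatch(self):
        assert weights_for({"C": 9, "S": 2, "V": 1}).weight_of == {
            "C": 0.00, "S": 0.25, "V": 0.50}
        assert weights_for({"C": 9, "S": 2, "D": 1}).weight_of == {
            "C": 0.00, "S": 0.25, "D": 0.50}

    def test_monotonicity_property(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            cats = ["C", "S", "V", "D", "I"][: rng.integers(2, 6)]
            totals = {c: int(rng.integers(0, 50)) for c in cats}
            w = assign_weights(totals)
            for a in cats:
                for b in cats:
                    if totals[a] > totals[b]:
                        assert w.weight_of[a] < w.weight_of[b]

    def test_too_many_categories_rejected(self):
        with pytest.raises(ValueError):
            CategoryWeights({"C": 0.1})


class TestWeightedProfile:
    def test_all_conserved_gives_zero_totals(self):
        alig = GeneAlignment("trnX", {"a": "AAAA", "b": "AAAA"},
                             ["D-loop"] * 4)
        cls = classify_alignment(alig)
        prof = weighted_profile(cls, weights_for(category_totals(cls)),
                                alig.column_domain, "trnX")
        assert prof.snp_total == 0 and prof.indel_total == 0

    def test_single_transition_scores_quarter(self):
        alig = GeneAlignment("trnX", {"a": "A", "b": "A", "c": "G"},
                             ["T-loop"])
        cls = classify_alignment(alig)
        prof = weighted_profile(cls, weights_for(category_totals(cls)),
                                alig.column_domain, "trnX")
        assert prof.snp_total == pytest.approx(0.25)
        assert prof.domain_snp["T-loop"] == pytest.approx(0.25)

    def test_toy_alignment_matches_hand_summation(self):
        """Ten-column toy alignment against a brute-force recount."""
        rng = np.random.default_rng(42)
        cols = []
        for _ in range(10):
            col = [("ACGT-")[i] for i in rng.integers(0, 5, 4)]
            if all(b == "-" for b in col):
                col[0] = "A"
            cols.append(col)
        rows = {f"s{i}": "".join(c[i] for c in cols) for i in range(4)}
        domains = ["D-loop"] * 5 + ["T-stem"] * 5
        alig = GeneAlignment("trnX", rows, domains)
        cls = classify_alignment(alig)
        weights = weights_for(category_totals(cls))
        prof = weighted_profile(cls, weights, domains, "trnX")
        # independent per-cell summation
        snp = indel = 0.0
        per_sp = {sp: 0.0 for sp in rows}
        for j, col in enumerate(cols):
            labels = oracle_classify(col)
            for i, lab in enumerate(labels):
                w = weights.weight_of.get(lab, 0.0)
                per_sp[f"s{i}"] += w
                if lab in "SV":
                    snp += w
                elif lab in "DI":
                    indel += w
        assert prof.snp_total == pytest.approx(snp)
        assert prof.indel_total == pytest.approx(indel)
        for sp in rows:
            assert prof.per_species_ratio[sp] == pytest.approx(
                per_sp[sp] / 10)


class TestZScores:
    def test_normalization_identities(self):
        rng = np.random.default_rng(3)
        ci = {f"t{i}": float(v) for i, v in enumerate(rng.random(22))}
        ht = {f"t{i}": float(v) for i, v in enumerate(rng.random(22))}
        cats = zscore_categorize(ci, ht)
        z_ci = np.array([c.z_ci for c in cats.values()])
        z_ht = np.array([c.z_ht for c in cats.values()])
        assert abs(z_ci.mean()) < 1e-9 and abs(z_ht.mean()) < 1e-9
        assert abs(z_ci.std() - 1) < 1e-9 and abs(z_ht.std() - 1) < 1e-9

    @pytest.mark.parametrize("z_ci,z_ht,category", [
        (1.5, 1.2, 1), (-1.3, 1.4, 4), (-0.5, -0.2, 2), (0.8, -1.1, 3)])
    def test_category_assignment(self, z_ci, z_ht, category):
        # build vectors whose z-scores land on the requested side
        base = {f"t{i}": 0.0 for i in range(10)}
        ci = dict(base, t0=z_ci, t1=-z_ci / 2)
        ht = dict(base, t0=z_ht, t1=-z_ht / 2)
        cats = zscore_categorize(ci, ht)
        assert cats["t0"].category == category

    def test_constant_vector_rejected(self):
        flat = {f"t{i}": 1.0 for i in range(5)}
        with pytest.raises(ValueError, match="degenerate"):
            zscore_categorize(flat, flat)

    def test_mismatched_indices_rejected(self):
        with pytest.raises(ValueError):
            zscore_categorize({"a": 1.0, "b": 2.0}, {"a": 1.0, "c": 2.0})
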