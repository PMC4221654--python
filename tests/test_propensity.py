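import math

import numpy as np
import pytest

from contactprop import (
    ContactMap,
    ContactParams,
    Domain,
    PropensityTable,
    Residue,
    build_contact_map,
    compute_fp,
    compute_fpn,
    compute_frequencies,
    compute_St,
    compute_Wc,
    compute_Wt,
    pair_key,
    summarize_domain,
    truth_map,
)
from contactprop.propensity import DomainContactSummary
from contactprop import synthetic

from conftest import random_cloud_domain


def make_domain(sequence, pairs):
    residues = [
        Residue(seq_index=i + 1, aa_type=a, cbeta=np.array([i * 100.0, 0, 0]))
        for i, a in enumerate(sequence)
    ]
    dom = Domain("manual", residues)
    cmap = ContactMap("manual", ContactParams(8.0, 1), frozenset(pairs))
    return dom, cmap


class TestSummarizeDomain:
    def test_hand_counted_aall(self):
        dom, cmap = make_domain("AALL", {(1, 4)})
        s = summarize_domain(dom, cmap)
        assert s.ic.get("A", 0) == 1 and s.iw["A"] == 2
        assert s.ic.get("L", 0) == 1 and s.iw["L"] == 2

    def test_contact_free_domain(self):
        dom, cmap = make_domain("AALL", set())
        s = summarize_domain(dom, cmap)
        assert s.ic == {}
        assert s.iw == {"A": 2, "L": 2}

    def test_matches_brute_force_recount(self, rng):
        dom = random_cloud_domain(40, rng, box=12.0)
        cmap = build_contact_map(dom, ContactParams(8.0, 3))
        s = summarize_domain(dom, cmap)
        in_contact = {i for p in cmap.pairs for i in p}
        for a in set(dom.sequence):
            iw = sum(1 for r in dom.residues if r.aa_type == a)
            ic = sum(
                1
                for r in dom.residues
                if r.aa_type == a and r.seq_index in in_contact
            )
            assert s.iw[a] == iw
            assert s.ic.get(a, 0) == ic


class TestWc:
    def test_every_ala_in_contact_gives_one(self):
        dom, cmap = make_domain("ALA", {(1, 3)})
        table = compute_Wc([summarize_domain(dom, cmap)], "alpha")
        assert table.values["A"] == 1.0

    def test_unweighted_mean_of_per_protein_ratios(self):
        d1, m1 = make_domain("AA", {(1, 2)})  # both Ala in contact: 1.0
        d2, m2 = make_domain("AAL", {(1, 3)})  # one of two Ala: 0.5
        table = compute_Wc(
            [summarize_domain(d1, m1), summarize_domain(d2, m2)], "alpha"
        )
        assert table.values["A"] == pytest.approx(0.75)
        assert table.n_proteins["A"] == 2

    def test_absent_type_is_nan_not_zero(self):
        dom, cmap = make_domain("AALL", {(1, 4)})
        table = compute_Wc([summarize_domain(dom, cmap)], "alpha")
        assert math.isnan(table.values["W"])
        assert table.n_proteins["W"] == 0

    def test_matches_direct_transcription(self, rng):
        summaries = []
        for _ in range(30):
            dom = random_cloud_domain(int(rng.integers(10, 50)), rng, box=12.0)
            cmap = build_contact_map(dom, ContactParams(8.0, 5))
            summaries.append(summarize_domain(dom, cmap))
        table = compute_Wc(summaries, "alpha")
        for a in set().union(*(s.iw for s in summaries)):
            ratios = [
                s.ic.get(a, 0) / s.iw[a] for s in summaries if s.iw.get(a, 0) > 0
            ]
            assert table.values[a] == pytest.approx(
                sum(ratios) / len(ratios), abs=1e-12
            )

    def test_bounds(self, rng):
        summaries = []
        for _ in range(10):
            dom = random_cloud_domain(20, rng, box=10.0)
            cmap = build_contact_map(dom, ContactParams(8.0, 3))
            summaries.append(summarize_domain(dom, cmap))
        table = compute_Wc(summaries, "k")
        for v in table.values.values():
            assert math.isnan(v) or 0.0 <= v <= 1.0


class TestWt:
    def test_equals_wc_for_identical_grouping(self, rng):
        summaries = []
        for _ in range(8):
            dom = random_cloud_domain(25, rng, box=10.0)
            cmap = build_contact_map(dom, ContactParams(8.0, 3))
            summaries.append(summarize_domain(dom, cmap))
        wc = compute_Wc(summaries, "alpha")
        wt = compute_Wt(summaries, "topo1")
        for a in wc.values:
            if math.isnan(wc.values[a]):
                assert math.isnan(wt.values[a])
            else:
                assert wt.values[a] == wc.values[a]

    def test_single_protein_topology_is_its_ratios(self):
        dom, cmap = make_domain("AALL", {(1, 4)})
        s = summarize_domain(dom, cmap)
        wt = compute_Wt([s], "t")
        assert wt.values["A"] == 0.5
        assert wt.values["L"] == 0.5


class TestFp:
    def test_single_contact(self):
        dom, cmap = make_domain("AL", {(1, 2)})
        table = compute_fp([(dom, cmap)], "alpha")
        assert table.fp_value("A", "L") == 1.0
        assert table.fp_value("L", "A") == 1.0  # unordered
        assert table.fp_value("A", "A") == 0.0

    def test_homotypic_counted_once(self):
        dom, cmap = make_domain("ALCC", {(1, 2), (3, 4)})
        table = compute_fp([(dom, cmap)], "alpha")
        assert table.fp_value("A", "L") == 0.5
        assert table.fp_value("C", "C") == 0.5
        assert table.jw == 2

    def test_sums_to_one_and_matches_brute_tally(self, rng):
        inputs = []
        for s in range(20):
            dom = synthetic.make_hairpin(10, 5.0, seed=100 + s)
            inputs.append((dom, truth_map(dom)))  # 8 A / separation 10
        table = compute_fp(inputs, "beta")
        assert sum(table.fp.values()) == pytest.approx(1.0, abs=1e-12)
        tally = {}
        total = 0
        for dom, cmap in inputs:
            seq = dom.sequence
            for i, j in cmap.pairs:
                k = pair_key(seq[i - 1], seq[j - 1])
                tally[k] = tally.get(k, 0) + 1
                total += 1
        assert table.jw == total
        for k, c in tally.items():
            assert table.fp[k] == pytest.approx(c / total, abs=1e-12)

    def test_x_pairs_reported_but_excludable(self):
        dom, cmap = make_domain("AXL", {(1, 2), (1, 3)})
        table = compute_fp([(dom, cmap)], "k")
        assert table.jw == 2
        assert table.fp_value("A", "X") == 0.5
        table2 = compute_fp([(dom, cmap)], "k", include_x_in_total=False)
        assert table2.jw == 1
        assert table2.fp_value("A", "L") == 1.0

    def test_empty_class_warns(self):
        dom, cmap = make_domain("AL", set())
        with pytest.warns(UserWarning, match="no contact sites"):
            table = compute_fp([(dom, cmap)], "k")
        assert table.jw == 0 and table.fp == {}


class TestFpn:
    def test_simple_arithmetic(self):
        dom, cmap = make_domain("ALAL", {(1, 2), (3, 4)})
        table = compute_fp([(dom, cmap)], "k")
        fpn = compute_fpn(table, {"A": 0.5, "L": 0.5})
        # f_p(A,L) = 1.0; 1.0 / (0.5 * 0.5) = 4.0
        assert fpn.fpn_value("A", "L") == pytest.approx(4.0)

    def test_uniform_contacts_equifrequent_types_all_equal(self):
        dom, cmap = make_domain("ALALALAL", {(1, 2), (3, 4), (5, 6), (7, 8)})
        # hand-built map with A-L contacts only; replace two with A-A and L-L
        dom2, cmap2 = make_domain("AALL", {(1, 2), (3, 4)})
        table = compute_fp([(dom2, cmap2)], "k")
        fpn = compute_fpn(table, compute_frequencies([dom2]))
        assert fpn.fpn_value("A", "A") == fpn.fpn_value("L", "L")

    def test_inconsistent_zero_frequency_raises(self):
        dom, cmap = make_domain("AL", {(1, 2)})
        table = compute_fp([(dom, cmap)], "k")
        with pytest.raises(ValueError, match="zero occurrence frequency"):
            compute_fpn(table, {"A": 0.0, "L": 1.0})

    def test_matches_brute_division(self, rng):
        inputs = []
        for s in range(10):
            dom = synthetic.make_hairpin(8, 5.0, seed=200 + s)
            inputs.append((dom, truth_map(dom)))
        table = compute_fp(inputs, "beta")
        freqs = compute_frequencies([d for d, _ in inputs])
        fpn = compute_fpn(table, freqs)
        for k, v in table.fp.items():
            expected = v / (freqs[k[0]] * freqs[k[1]])
            assert fpn.fpn[k] == pytest.approx(expected, abs=1e-12)


class TestFrequencies:
    def test_simple_counts(self):
        dom, _ = make_domain("AAAL", set())
        f = compute_frequencies([dom])
        assert f["A"] == 0.75 and f["L"] == 0.25

    def test_all_x_raises(self):
        dom, _ = make_domain("XXX", set())
        with pytest.raises(ValueError, match="no standard amino acids"):
            compute_frequencies([dom])

    def test_sums_to_one(self, rng):
        domains = [random_cloud_domain(30, rng) for _ in range(10)]
        assert sum(compute_frequencies(domains).values()) == pytest.approx(
            1.0, abs=1e-12
        )


class TestSt:
    def test_identical_profiles_give_zero(self, rng):
        summaries = []
        for _ in range(5):
            dom = random_cloud_domain(25, rng, box=10.0)
            cmap = build_contact_map(dom, ContactParams(10.0, 7))
            summaries.append(summarize_domain(dom, cmap))
        wc = compute_Wc(summaries, "alpha")
        wt = compute_Wt(summaries, "t12")
        assert compute_St(wt, wc) == 0.0

    def test_hand_arithmetic(self):
        wc = PropensityTable("k", {"A": 0.5, "L": 0.5}, {}, {"A": 1, "L": 1})
        wt = PropensityTable("t", {"A": 0.6, "L": 0.6}, {}, {"A": 1, "L": 1})
        assert compute_St(wt, wc) == pytest.approx(
            math.sqrt((0.01 + 0.01) / 1), abs=1e-12
        )

    def test_single_type_undefined(self):
        wc = PropensityTable("k", {"A": 0.5}, {}, {"A": 1})
        wt = PropensityTable("t", {"A": 0.6}, {}, {"A": 1})
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert math.isnan(compute_St(wt, wc))

    def test_matches_direct_formula(self, rng):
        types = list("ACDEFGHIK")
        wc_vals = {a: float(rng.random()) for a in types}
        wt_vals = {a: float(rng.random()) for a in types}
        n_prot = {a: 3 for a in types}
        wc = PropensityTable("k", wc_vals, {}, n_prot)
        wt = PropensityTable("t", wt_vals, {}, n_prot)
        expected = math.sqrt(
            sum((wt_vals[a] - wc_vals[a]) ** 2 for a in types) / (len(types) - 1)
        )
        assert compute_St(wt, wc) == pytest.approx(expected, abs=1e-12)

    def test_excludes_x(self):
        wc = PropensityTable(
            "k", {"A": 0.5, "L": 0.3, "X": 0.9}, {}, {"A": 1, "L": 1, "X": 1}
        )
        wt = PropensityTable(
            "t", {"A": 0.5, "L": 0.3, "X": 0.1}, {}, {"A": 1, "L": 1, "X": 1}
        )
        assert compute_St(wt, wc) == 0.0


def test_null_model_fpn_roughly_constant(rng):
    """With uniform sequences and uniformly random contacts, f_pn is flat."""
    inputs = []
    for s in range(200):
        dom = random_cloud_domain(40, rng)
        n_pairs = 30
        pairs = set()
        while len(pairs) < n_pairs:
            i, j = sorted(rng.integers(1, 41, size=2))
            if i != j:
                pairs.add((int(i), int(j)))
        cmap = ContactMap("null", ContactParams(8.0, 1), frozenset(pairs))
        inputs.append((dom, cmap))
    table = compute_fp(inputs, "null")
    fpn = compute_fpn(table, compute_frequencies([d for d, _ in inputs]))
    hetero = np.array(
        [v for k, v in fpn.fpn.items() if k[0] != k[1] and not math.isnan(v)]
    )
    homo = np.array(
        [v for k, v in fpn.fpn.items() if k[0] == k[1] and not math.isnan(v)]
    )
    # without double-counting of homotypic contacts, a heterotypic pair is
    # drawn twice as often as a homotypic one at equal frequencies, so f_pn
    # converges to a constant within each category, heterotypic ~2x homotypic
    assert hetero.std() / hetero.mean() < 0.3
    assert hetero.mean() == pytest.approx(2.0, rel=0.15)
    assert homo.mean() == pytest.approx(1.0, rel=0.25)


def test_summary_rejects_inconsistent_counts():
    with pytest.raises(ValueError, match="inconsistent"):
        DomainContactSummary("d", {"A": 3}, {"A": 2})
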