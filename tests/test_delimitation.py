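"""Species identification rules: gap tests, classification, splits."""

import math

import numpy as np
import pytest

from barcodegap.delimitation import (
    DelimitationConfig,
    barcoding_gap_test,
    classify_species,
    propose_splits,
    success_rate,
)
from barcodegap.distances import DistanceMatrix, build_matrix, summarize_groups
from barcodegap.haplotypes import collapse, shared_haplotypes
from barcodegap.simulate import SimConfig, simulate_dataset

from conftest import make_set


def dm(labels, entries):
    n = len(labels)
    d = np.zeros((n, n))
    for (i, j), v in entries.items():
        d[i, j] = d[j, i] = v
    return DistanceMatrix(list(labels), d)


def summary_for(matrix, grouping):
    return summarize_groups(matrix, grouping)


class TestBarcodingGapTest:
    def grouped(self, within_g, within_h, between):
        """Two 2-member groups with controlled within/between distances."""
        m = dm("wxyz", {
            (0, 1): within_g, (2, 3): within_h,
            (0, 2): between, (0, 3): between, (1, 2): between, (1, 3): between,
        })
        return summarize_groups(m, {"w": "g", "x": "g", "y": "h", "z": "h"})

    def test_clear_gap(self):
        s = self.grouped(0.0030, 0.0030, 0.0440)
        assert barcoding_gap_test(s, "g", "h") is True

    def test_equality_is_not_a_gap(self):
        s = self.grouped(0.0100, 0.0050, 0.0100)
        assert barcoding_gap_test(s, "g", "h") is False

    def test_tenfold_rule_ratio(self):
        s = self.grouped(0.004, 0.002, 0.05)  # 12.5x the larger within mean
        assert barcoding_gap_test(s, "g", "h", rule="tenfold") is True
        s2 = self.grouped(0.006, 0.002, 0.05)  # 8.3x
        assert barcoding_gap_test(s2, "g", "h", rule="tenfold") is False

    def test_singleton_within_treated_as_zero(self):
        m = dm("wxy", {(0, 1): 0.002, (0, 2): 0.03, (1, 2): 0.03})
        s = summarize_groups(m, {"w": "g", "x": "g", "y": "h"})
        assert barcoding_gap_test(s, "g", "h") is True


def classify_all(sset, config=DelimitationConfig()):
    matrix = build_matrix(sset)
    grouping = sset.species_grouping()
    summary = summarize_groups(matrix, grouping)
    overlap = {frozenset((a, b)) for a, b, _ in shared_haplotypes(collapse(sset))}
    return {
        sp: classify_species(sp, summary, overlap, config,
                             matrix=matrix, grouping=grouping)
        for sp in summary.groups
    }


class TestClassifySpecies:
    def test_sole_species_of_genus_identified(self):
        sset = make_set(["ACGTACGT", "ACGAACGT"], species=["solo", "solo"])
        reports = classify_all(sset)
        r = reports[("Testus", "solo")]
        assert r.identified and r.closest_congener is None

    def test_well_separated_congeners_identified(self, rng):
        sset, _ = simulate_dataset(SimConfig(n_groups=3, seqs_per_group=6, seed=9))
        reports = classify_all(sset)
        assert all(r.identified for r in reports.values())
        assert all(r.gap_with_closest for r in reports.values())

    def test_shared_haplotype_intermingling_fails(self):
        # two nominal species sharing a haplotype with intermingled
        # distances: neither separable (the trout-like failure mode)
        base = "A" * 40
        near = "A" * 39 + "G"
        sset = make_set(
            [base, near, base, near],
            species=["s1", "s1", "s2", "s2"],
        )
        reports = classify_all(sset)
        assert not reports[("Testus", "s1")].identified
        assert not reports[("Testus", "s2")].identified
        assert "b" in reports[("Testus", "s1")].flags

    def test_exclusive_cluster_identified_without_gap(self):
        # species e forms a tight exclusive cluster near species p, which is
        # spread so wide that min-between < max-within(p): mean below the
        # threshold and no gap, yet e is diagnosable and identified
        def mutate(base, positions, to):
            s = list(base)
            for p in positions:
                s[p] = to
            return "".join(s)

        base = "ACGT" * 250  # 1000 sites
        p1 = base
        p2 = mutate(base, range(100, 120), "A")   # ~0.020 from p1
        p3 = mutate(base, range(100, 110), "A")   # ~0.010 from p1
        e1 = mutate(base, range(500, 505), "A")   # ~0.005 from p1
        e2 = mutate(e1, [510], "A")               # ~0.001 from e1
        sset = make_set(
            [e1, e2, p1, p2, p3],
            species=["e", "e", "p", "p", "p"],
        )
        reports = classify_all(sset)
        re = reports[("Testus", "e")]
        assert re.mean_to_closest < 0.02
        assert re.gap_with_closest is False
        assert re.identified
        assert "b" not in re.flags

    def test_flag_a_for_deep_intraspecific_divergence(self):
        far = "T" * 10 + "A" * 30
        sset = make_set(
            ["A" * 40, far, "G" * 40, "G" * 39 + "A"],
            species=["s1", "s1", "s2", "s2"],
        )
        reports = classify_all(sset)
        assert "a" in reports[("Testus", "s1")].flags

    def test_flags_agree_with_brute_force_oracle(self, rng):
        """Enumerate all congener pairs independently on random small genera."""
        config = DelimitationConfig()
        for trial in range(8):
            local = np.random.default_rng(100 + trial)
            n_sp = int(local.integers(2, 5))
            seqs, species = [], []
            root = "".join(local.choice(list("ACGT"), size=60))
            from barcodegap.simulate import evolve_k2p
            for s in range(n_sp):
                anc = evolve_k2p(root, float(local.uniform(0.005, 0.05)), 2.0, local)
                for k in range(int(local.integers(2, 5))):
                    seqs.append(evolve_k2p(anc, 0.004, 2.0, local))
                    species.append(f"s{s}")
            sset = make_set(seqs, species=species)
            matrix = build_matrix(sset)
            grouping = sset.species_grouping()
            summary = summarize_groups(matrix, grouping)
            reports = classify_all(sset, config)
            for sp, r in reports.items():
                congeners = [g for g in summary.groups if g != sp]
                # oracle: identified unless some congener is close, gapless
                # and the species is not an exclusive cluster w.r.t. it
                expect = True
                for t in congeners:
                    close = summary.get_mean_between(sp, t) < config.threshold
                    gap = barcoding_gap_test(summary, sp, t)
                    if close and not gap and not _oracle_diag(matrix, grouping, sp):
                        expect = False
                assert r.identified == expect, (sp, trial)

    def test_identified_counts_partition_species(self, rng):
        sset, _ = simulate_dataset(SimConfig(n_groups=4, seqs_per_group=5, seed=3))
        reports = list(classify_all(sset).values())
        sr = success_rate(reports)
        assert sr.identified + sum(not r.identified for r in reports) == sr.total

    def test_threshold_monotonicity_of_failure(self):
        """Raising the threshold never converts a flag-b failure to success."""
        base = "A" * 40
        near = "A" * 39 + "G"
        # both species carry both haplotypes: close, gapless, not diagnosable
        sset = make_set([base, near, base, near], species=["x", "x", "y", "y"])
        failed_once = False
        for t1, t2 in [(0.05, 0.1), (0.1, 0.2)]:
            r1 = classify_all(sset, DelimitationConfig(threshold=t1))
            r2 = classify_all(sset, DelimitationConfig(threshold=t2))
            for sp in r1:
                if "b" in r1[sp].flags and not r1[sp].identified:
                    failed_once = True
                    assert not r2[sp].identified
        assert failed_once


def _oracle_diag(matrix, grouping, sp):
    members = [l for l in matrix.labels if grouping[l] == sp]
    if len(members) < 2:
        return False
    for lab in members:
        i = matrix.index(lab)
        d_in = min(matrix.d[i, matrix.index(m)] for m in members if m != lab)
        d_out = min(matrix.d[i, matrix.index(l)]
                    for l in matrix.labels if grouping[l] != sp)
        if not d_in < d_out:
            return False
    return True


class TestProposeSplits:
    def test_two_clusters_one_proposal(self):
        sset, _ = simulate_dataset(SimConfig(
            n_groups=1, seqs_per_group=10, populations_per_group=2,
            population_div=0.05, intra_div=0.002, inter_div=0.2, seed=4,
        ))
        matrix = build_matrix(sset)
        pops = sset.region_grouping()
        props = propose_splits("sp01", pops, matrix)
        assert len(props) == 1
        assert props[0].mean_between > 0.02

    def test_shared_haplotype_populations_no_proposal(self):
        sset = make_set(
            ["A" * 30] * 4, species=["s"] * 4,
            regions=["r1", "r1", "r2", "r2"],
        )
        props = propose_splits("s", sset.region_grouping(), build_matrix(sset))
        assert props == []

    def test_single_population_no_proposal(self):
        sset = make_set(["A" * 30, "A" * 29 + "G"], species=["s", "s"])
        props = propose_splits("s", sset.region_grouping(), build_matrix(sset))
        assert props == []


class TestSuccessRate:
    def test_paper_style_fractions(self):
        # 55 of 72 identified -> 76.4%; 53 of 55 with gap -> 96.4%
        reports = []
        from barcodegap.delimitation import SpeciesReport
        for i in range(72):
            identified = i < 55
            gap = i < 53 if identified else False
            reports.append(SpeciesReport(
                species=f"sp{i}", n_sequences=2, identified=identified,
                flags=frozenset(), closest_congener="x",
                mean_within=0.001, max_within=0.002,
                mean_to_closest=0.05, min_to_closest=0.04,
                gap_with_closest=gap,
            ))
        sr = success_rate(reports)
        assert sr.fraction * 100 == pytest.approx(76.4, abs=0.05)
        assert sr.gap_fraction * 100 == pytest.approx(96.4, abs=0.05)

    def test_all_identified_with_gap(self):
        sset, _ = simulate_dataset(SimConfig(n_groups=2, seqs_per_group=4, seed=6))
        sr = success_rate(list(classify_all(sset).values()))
        assert sr.fraction == 1.0 and sr.gap_fraction == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            success_rate([])


class TestConfig:
    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            DelimitationConfig(threshold=0.0)

    def test_invalid_rules(self):
        with pytest.raises(ValueError):
            DelimitationConfig(gap_rule="magic")
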