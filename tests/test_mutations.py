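"""Patient censoring, signature groups, GC-rich fractions, SNV profiles."""

import numpy as np
import pandas as pd
import pytest

from oxland.gc import GcTrack, fold_trinuc, gc_per_bin
from oxland.genome import Genome
from oxland.mutations import (SnvCatalog, assign_signature_groups,
                              censor_patients, fold_mutation_type,
                              gc_rich_fraction, group_fraction_stats,
                              select_pole_deficient, snv_metaprofile,
                              stratify_by_replication_timing)
from oxland.synth.snv import (PatientSpec, SignatureProfile,
                              simulate_snv_catalog)
from oxland.tracks import BinnedTrack


def patient_row(pid, n_ca=1000, sig18=0.0, sig17=0.0, sig10=0.0,
                ber=False, smoke=False):
    return {"patient": pid, "n_c_to_a": n_ca, "n_t_to_g": 0, "n_c_to_t": 0,
            "sig18": sig18, "sig17": sig17, "sig10": sig10,
            "ber_coding": ber, "smoking_or_therapy": smoke}


def catalog_from_patients(rows):
    snvs = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "patient",
                                 "mutation_type"])
    patients = pd.DataFrame(rows, columns=["patient", "n_c_to_a", "n_t_to_g",
                                           "n_c_to_t", "sig18", "sig17",
                                           "sig10", "ber_coding",
                                           "smoking_or_therapy"])
    return SnvCatalog(snvs, patients)


class TestCensoring:
    def test_hypermutator_threshold_is_strict(self):
        cat = catalog_from_patients([patient_row("a", n_ca=100_000),
                                     patient_row("b", n_ca=100_001)])
        kept, report = censor_patients(cat)
        assert list(kept.patients["patient"]) == ["a"]
        assert report.hypermutator == ["b"]

    def test_ber_coding_mutation_censored(self):
        cat = catalog_from_patients([patient_row("a", ber=True),
                                     patient_row("b")])
        kept, report = censor_patients(cat)
        assert list(kept.patients["patient"]) == ["b"]
        assert report.ber_coding == ["a"]

    def test_pole_patients_exempt_from_hypermutator_rule(self):
        cat = catalog_from_patients([patient_row("pole", n_ca=3_436_531 // 8,
                                                 sig10=0.8),
                                     patient_row("hyper", n_ca=150_000)])
        kept, report = censor_patients(cat)
        assert "pole" in list(kept.patients["patient"])
        assert report.hypermutator == ["hyper"]

    def test_empty_catalog(self):
        cat = catalog_from_patients([])
        kept, report = censor_patients(cat)
        assert len(kept.patients) == 0 and report.removed == []


class TestSignatureGroups:
    def test_basic_assignment(self):
        cat = catalog_from_patients([patient_row("a", sig18=0.05)])
        assert assign_signature_groups(cat, "sig18")["a"] == "<0.1"

    @pytest.mark.parametrize("exposure,expected", [
        (0.0, "<0.1"), (0.0999, "<0.1"), (0.1, "0.1-0.4"), (0.3999, "0.1-0.4"),
        (0.4, "0.4-0.6"), (0.5999, "0.4-0.6"), (0.6, ">0.6"), (1.0, ">0.6"),
    ])
    def test_sig18_boundaries_lower_closed(self, exposure, expected):
        cat = catalog_from_patients([patient_row("p", sig18=exposure)])
        assert assign_signature_groups(cat, "sig18")["p"] == expected

    @pytest.mark.parametrize("exposure,expected", [
        (0.09, "<0.1"), (0.1, "0.1-0.25"), (0.25, "0.25-0.5"), (0.5, ">0.5"),
    ])
    def test_sig17_boundaries(self, exposure, expected):
        cat = catalog_from_patients([patient_row("p", sig17=exposure)])
        assert assign_signature_groups(cat, "sig17")["p"] == expected

    def test_planted_cohort_group_sizes(self):
        rows = ([patient_row(f"lo{i}", sig18=0.02) for i in range(5)]
                + [patient_row(f"mid{i}", sig18=0.5) for i in range(3)]
                + [patient_row(f"hi{i}", sig18=0.9) for i in range(2)])
        groups = assign_signature_groups(catalog_from_patients(rows), "sig18")
        assert groups.value_counts().to_dict() == {"<0.1": 5, "0.4-0.6": 3,
                                                   ">0.6": 2}

    def test_out_of_range_exposure_rejected(self):
        cat = catalog_from_patients([patient_row("p", sig18=1.5)])
        with pytest.raises(ValueError):
            assign_signature_groups(cat, "sig18")


class TestPoleSelection:
    def test_selected_and_not_selected(self):
        cat = catalog_from_patients([
            patient_row("yes", n_ca=3_436_531 // 8, sig10=0.8),
            patient_row("no_sig", n_ca=150_000, sig10=0.01),
            patient_row("no_count", n_ca=50_000, sig10=0.9)])
        assert select_pole_deficient(cat) == ["yes"]

    def test_planted_pole_patients_all_selected(self):
        cat = catalog_from_patients(
            [patient_row(f"pole{i}", n_ca=200_000, sig10=0.7)
             for i in range(8)] + [patient_row("ctrl", n_ca=2000)])
        assert len(select_pole_deficient(cat)) == 8


def simple_gc_track(percents, bin_size=1000):
    arr = np.asarray(percents, dtype=float)
    return GcTrack(bin_size, {"c": arr},
                   {"c": np.ones(len(arr))},
                   {"c": np.zeros(len(arr), dtype=bool)})


class TestGcRichFraction:
    def _catalog(self, positions, pid="p", mtype="C>A"):
        snvs = pd.DataFrame({"chrom": "c", "pos": positions,
                             "ref": "C", "alt": "A", "patient": pid,
                             "mutation_type": mtype})
        return SnvCatalog(snvs, pd.DataFrame([patient_row(pid)]))

    def test_all_snvs_in_rich_bins(self):
        gc = simple_gc_track([60, 60, 40])
        cat = self._catalog([100, 1100])
        fracs, _ = gc_rich_fraction(cat, gc)
        assert fracs["p"] == pytest.approx(1.0)

    def test_membership_oracle_three_of_ten(self):
        gc = simple_gc_track([60, 40, 40, 40])
        # bins (0-based) of 1-based positions: 3 in bin 0 (rich), 7 elsewhere
        positions = [1, 500, 1000] + [1500, 2200, 2300, 3100, 3200, 3900, 3500]
        cat = self._catalog(positions)
        fracs, _ = gc_rich_fraction(cat, gc)
        assert fracs["p"] == pytest.approx(0.3)

    def test_censored_bins_excluded_from_both_sides(self):
        gc = simple_gc_track([60, 40])
        gc.censored["c"][1] = True
        cat = self._catalog([100, 1100, 1200])  # 2 SNVs in censored bin
        fracs, _ = gc_rich_fraction(cat, gc)
        assert fracs["p"] == pytest.approx(1.0)

    def test_patient_with_no_retained_snvs_excluded(self):
        gc = simple_gc_track([60])
        gc.censored["c"][0] = True
        cat = self._catalog([100])
        fracs, n_excluded = gc_rich_fraction(cat, gc)
        assert len(fracs) == 0 and n_excluded == 1

    def test_group_stats_and_rank_sum(self):
        fracs = pd.Series({"a1": 0.10, "a2": 0.11, "a3": 0.09,
                           "b1": 0.03, "b2": 0.02, "b3": 0.04})
        groups = pd.Series({"a1": "ref", "a2": "ref", "a3": "ref",
                            "b1": "low", "b2": "low", "b3": "low"})
        stats = group_fraction_stats(fracs, groups, "ref").set_index("group")
        assert stats.loc["low", "median"] == pytest.approx(0.03)
        assert stats.loc["low", "p_vs_reference"] == pytest.approx(0.1)


class TestReplicationTiming:
    def test_hand_assigned_tertiles(self):
        gc = simple_gc_track([60, 40, 60, 40, 60, 40])
        timing = BinnedTrack(1000, {"c": np.array([1.0, 2, 3, 4, 5, 6])})
        positions = [100, 1100, 2100, 3100, 4100, 5100]
        snvs = pd.DataFrame({"chrom": "c", "pos": positions, "ref": "C",
                             "alt": "A", "patient": "p",
                             "mutation_type": "C>A"})
        cat = SnvCatalog(snvs, pd.DataFrame([patient_row("p")]))
        out = stratify_by_replication_timing(cat, timing, gc)
        # tertiles: bins (0,1), (2,3), (4,5); one rich bin in each
        assert out["early"]["p"] == pytest.approx(0.5)
        assert out["late"]["p"] == pytest.approx(0.5)

    def test_constant_timing_warns_and_splits_by_index(self):
        gc = simple_gc_track([60, 40, 60])
        timing = BinnedTrack(1000, {"c": np.ones(3)})
        snvs = pd.DataFrame({"chrom": "c", "pos": [100], "ref": "C",
                             "alt": "A", "patient": "p",
                             "mutation_type": "C>A"})
        cat = SnvCatalog(snvs, pd.DataFrame([patient_row("p")]))
        with pytest.warns(UserWarning, match="constant replication timing"):
            stratify_by_replication_timing(cat, timing, gc)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(13)
    return Genome({"c": "".join(rng.choice(list("ACGT"), size=100_000))})


class TestSnvSimulation:
    def test_zero_exposure_zero_counts_empty_catalog(self, genome):
        cat = simulate_snv_catalog(genome, [PatientSpec("p", {})], seed=0)
        assert len(cat.snvs) == 0

    def test_context_fidelity_by_sequence_lookup(self, genome):
        profiles = {"only_tct": SignatureProfile.from_contexts("C>A",
                                                               {"TCT": 1.0})}
        cat = simulate_snv_catalog(
            genome, [PatientSpec("p", {"C>A": 500},
                                 {"C>A": {"only_tct": 1.0}})],
            profiles=profiles, seed=1)
        target = fold_trinuc("TCT")
        seq = genome.seq("c")
        for _, row in cat.snvs.iterrows():
            pos = row["pos"] - 1
            assert fold_trinuc(seq[pos - 1:pos + 2]) == target
            assert fold_mutation_type(row["ref"], row["alt"]) == "C>A"

    def test_requested_counts_emitted_exactly(self, genome):
        cat = simulate_snv_catalog(
            genome, [PatientSpec("p", {"C>A": 1234, "T>G": 77})], seed=2)
        counts = cat.snvs["mutation_type"].value_counts()
        assert counts["C>A"] == 1234 and counts["T>G"] == 77

    def test_absent_context_raises(self):
        genome = Genome({"c": "AT" * 5000})  # no C/G anywhere
        with pytest.raises(Exception, match="absent"):
            simulate_snv_catalog(genome, [PatientSpec("p", {"C>A": 10})],
                                 seed=3)

    def test_reverse_complement_catalog_invariance(self, genome):
        cat = simulate_snv_catalog(
            genome, [PatientSpec("p", {"C>A": 2000})], seed=4)
        gc = gc_per_bin(genome)
        f1, _ = gc_rich_fraction(cat, gc)
        f2, _ = gc_rich_fraction(cat.complemented(), gc)
        pd.testing.assert_series_equal(f1, f2)

    def test_uniform_snvs_track_base_content(self, genome):
        """Counting oracle: C>A SNVs under a flat profile land on C/G bases
        in proportion to each bin class's share of C/G content (+/- 2%)."""
        cat = simulate_snv_catalog(
            genome, [PatientSpec("p", {"C>A": 100_000})], seed=5)
        gc = gc_per_bin(genome)
        fracs, _ = gc_rich_fraction(cat, gc)
        seq = genome.seq("c")
        rich_cg = total_cg = 0
        for b in range(100):
            window = seq[b * 1000:(b + 1) * 1000]
            cg = window.count("C") + window.count("G")
            total_cg += cg
            if gc.rich_mask("c")[b]:
                rich_cg += cg
        assert fracs["p"] == pytest.approx(rich_cg / total_cg, abs=0.02)


def test_expected_fraction_consistent_with_uniform_simulation(genome):
    """Sequence-based expectation equals simulation over opportunity sites."""
    from oxland.gc import expected_gc_rich_fraction, trinucleotide_spectrum

    gc = gc_per_bin(genome)
    spectrum = trinucleotide_spectrum(genome, gc)
    expected = expected_gc_rich_fraction(spectrum, mutation_type="C>A")
    cat = simulate_snv_catalog(genome, [PatientSpec("p", {"C>A": 100_000})],
                               seed=6)
    fracs, _ = gc_rich_fraction(cat, gc)
    assert fracs["p"] == pytest.approx(expected, abs=0.02)


class TestSnvMetaprofile:
    def _uniform_setup(self):
        rng = np.random.default_rng(17)
        genome = Genome({"c": "".join(rng.choice(list("ACGT"), size=20_000))})
        pos = rng.integers(2, 20_000 - 2, size=4000) + 1
        snvs = pd.DataFrame({"chrom": "c", "pos": pos, "ref": "C", "alt": "A",
                             "patient": "p", "mutation_type": "C>A"})
        cat = SnvCatalog(snvs, pd.DataFrame([patient_row("p")]))
        anchors = pd.DataFrame([{"chrom": "c", "pos": p, "strand": "+"}
                                for p in range(2000, 18_000, 1000)])
        return genome, cat, anchors

    def test_doubling_catalog_leaves_profile_unchanged(self):
        genome, cat, anchors = self._uniform_setup()
        prof1 = snv_metaprofile(cat, anchors, 200, 200, genome,
                                smooth_window=None)
        doubled = SnvCatalog(pd.concat([cat.snvs, cat.snvs],
                                       ignore_index=True), cat.patients)
        prof2 = snv_metaprofile(doubled, anchors, 200, 200, genome,
                                smooth_window=None)
        np.testing.assert_allclose(prof1.mean, prof2.mean, atol=1e-9)

    def test_matches_brute_force_counting_oracle(self):
        genome, cat, anchors = self._uniform_setup()
        prof = snv_metaprofile(cat, anchors, 50, 50, genome,
                               smooth_window=None)
        counts = np.zeros(100)
        per_bp = np.zeros(20_000)
        for p in cat.snvs["pos"]:
            per_bp[p - 1] += 1
        for _, a in anchors.iterrows():
            counts += per_bp[a["pos"] - 50:a["pos"] + 50]
        density = counts / len(anchors) * 1e6 / len(cat.snvs)
        gc_local = np.zeros(100)
        gc_mask = genome.gc_mask("c").astype(float)
        for _, a in anchors.iterrows():
            gc_local += gc_mask[a["pos"] - 50:a["pos"] + 50]
        gc_local /= len(anchors)
        oracle = density / (gc_local / genome.gc_fraction())
        np.testing.assert_allclose(prof.mean, oracle, atol=1e-9)

    def test_zero_mutations_rejected(self):
        genome, cat, anchors = self._uniform_setup()
        with pytest.raises(ValueError, match="no C>T"):
            snv_metaprofile(cat, anchors, 50, 50, genome,
                            mutation_type="C>T")
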