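"""Synthetic benchmark generator: geometry, contacts, scores, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rfqa import structure_io
from rfqa.structure_io import observed_contact_map
from rfqa.synthetic_fixtures import (BenchmarkSpec, generate_benchmark,
                                     informative_spec, make_benchmark,
                                     synth_decoys, synth_external_scores,
                                     synth_msa, synth_native,
                                     synth_predicted_contacts,
                                     uninformative_spec)


class TestSynthNative:
    def test_deterministic(self):
        a = synth_native(40, seed=1)
        b = synth_native(40, seed=1)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_contact_density_band(self):
        """Contacts per residue stay in the realistic 1-3 band (8 Å, sep >= 5)."""
        for seed in range(12):
            L = 48 + 4 * (seed % 5)
            native = synth_native(L, seed=seed)
            density = len(observed_contact_map(native)) / L
            assert 1.0 <= density <= 3.0

    def test_self_avoidance(self):
        native = synth_native(64, seed=6)
        d = np.linalg.norm(native.coords[:, None] - native.coords[None, :], axis=-1)
        iu = np.triu_indices(native.length, 2)
        assert d[iu].min() >= 3.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            synth_native(10, seed=0)


class TestSynthDecoys:
    def test_zero_noise_is_exact(self):
        native = synth_native(40, seed=2)
        models, tms = synth_decoys(native, [0.0], 3, seed=3)
        assert np.all(tms == 1.0)

    def test_mean_tm_decreases_with_noise(self):
        """Average decoy quality falls monotonically across noise levels."""
        levels = [0.5, 2.0, 4.0, 8.0]
        means = np.zeros(len(levels))
        for seed in range(6):
            native = synth_native(50, seed=30 + seed)
            _, tms = synth_decoys(native, levels, 3, seed=seed)
            means += tms.reshape(len(levels), 3).mean(axis=1)
        assert np.all(np.diff(means) < 0)

    def test_reproducible(self):
        native = synth_native(40, seed=4)
        m1, t1 = synth_decoys(native, [2.0], 4, seed=5)
        m2, t2 = synth_decoys(native, [2.0], 4, seed=5)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(m1[0].coords, m2[0].coords)

    def test_mirror_flips_correctness_not_contacts(self):
        """Reflected decoys lose the fold but keep their contact map."""
        native = synth_native(50, seed=7)
        plain, plain_tm = synth_decoys(native, [1.0], 3, seed=8)
        mirrored, mirror_tm = synth_decoys(native, [1.0], 3, seed=8, mirror=True)
        assert np.all(plain_tm >= 0.5)
        assert np.all(mirror_tm < 0.5)
        for p, m in zip(plain, mirrored):
            assert (observed_contact_map(p).contacts
                    == observed_contact_map(m).contacts)


class TestSynthPredictedContacts:
    def test_perfect_prediction_equals_native(self):
        native = synth_native(40, seed=9)
        nmap = observed_contact_map(native)
        pred = synth_predicted_contacts(nmap, precision=1.0, coverage=1.0, seed=10)
        assert {(i, j) for i, j, _ in pred.entries} == nmap.contacts

    def test_realised_precision_matches_request(self):
        devs = []
        for seed in range(10):
            native = synth_native(50, seed=40 + seed)
            nmap = observed_contact_map(native)
            pred = synth_predicted_contacts(nmap, precision=0.7, coverage=0.7,
                                            seed=seed)
            sat = {(i, j) for i, j, p in pred.entries if p > 0.5} & nmap.contacts
            n_above = sum(1 for _, _, p in pred.entries if p > 0.5)
            devs.append(len(sat) / n_above)
        assert abs(np.mean(devs) - 0.7) <= 0.05

    def test_deterministic(self):
        native = synth_native(40, seed=11)
        nmap = observed_contact_map(native)
        a = synth_predicted_contacts(nmap, 0.6, 0.5, seed=12)
        b = synth_predicted_contacts(nmap, 0.6, 0.5, seed=12)
        assert a.entries == b.entries

    def test_invalid_parameters_rejected(self):
        native = synth_native(40, seed=13)
        nmap = observed_contact_map(native)
        with pytest.raises(ValueError):
            synth_predicted_contacts(nmap, precision=0.0, coverage=0.5, seed=0)
        with pytest.raises(ValueError):
            synth_predicted_contacts(nmap, precision=0.001, coverage=1.0, seed=0)


class TestSynthExternalScores:
    def test_full_informativeness_is_rank_identical(self):
        rng = np.random.default_rng(14)
        tms = rng.uniform(0.2, 0.9, 30)
        scores = synth_external_scores(tms, informativeness=1.0, seed=15)
        for col in scores.columns:
            rho, _ = spearmanr(scores[col], tms)
            assert rho == pytest.approx(1.0)

    def test_zero_informativeness_uncorrelated(self):
        rhos = []
        rng = np.random.default_rng(16)
        for seed in range(20):
            tms = rng.uniform(0.2, 0.9, 40)
            scores = synth_external_scores(tms, informativeness=0.0, seed=seed)
            rho, _ = spearmanr(scores.iloc[:, 0], tms)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_intermediate_informativeness_band(self):
        """a = 0.7 gives within-target Spearman rho around 0.5-0.85."""
        rhos = []
        rng = np.random.default_rng(17)
        for seed in range(50):
            tms = rng.uniform(0.2, 0.9, 40)
            scores = synth_external_scores(tms, informativeness=0.7, seed=seed)
            rho, _ = spearmanr(scores.iloc[:, 0], tms)
            rhos.append(rho)
        assert 0.5 <= np.mean(rhos) <= 0.85


class TestBenchmark:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BenchmarkSpec(contact_precision=0.0)
        with pytest.raises(ValueError):
            BenchmarkSpec(informativeness=1.5)
        with pytest.raises(ValueError):
            BenchmarkSpec(n_targets=0)

    def test_on_disk_layout_and_counts(self, tmp_path):
        spec = informative_spec(seed=50, n_targets=2, models_per_target=8,
                                length_range=(30, 36))
        bench = make_benchmark(spec, tmp_path / "bench")
        pdbs = list((tmp_path / "bench").glob("T*/*.pdb"))
        rrs = list((tmp_path / "bench").glob("*.rr"))
        assert len(pdbs) == 16 and len(rrs) == 2
        labels = structure_io.read_score_table(tmp_path / "bench" / "labels.tsv")
        scores = structure_io.read_score_table(tmp_path / "bench" / "scores.tsv")
        assert len(labels) == len(scores) == 16

    def test_regeneration_is_byte_identical(self, tmp_path):
        spec = informative_spec(seed=51, n_targets=2, models_per_target=5,
                                length_range=(30, 34))
        make_benchmark(spec, tmp_path / "a")
        make_benchmark(spec, tmp_path / "b")
        for rel in ("labels.tsv", "scores.tsv"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()
        a_pdb = sorted((tmp_path / "a").glob("T*/*.pdb"))[0]
        b_pdb = sorted((tmp_path / "b").glob("T*/*.pdb"))[0]
        assert a_pdb.read_bytes() == b_pdb.read_bytes()

    def test_artifacts_parse_back_cleanly(self, tmp_path):
        import warnings

        spec = informative_spec(seed=52, n_targets=1, models_per_target=4,
                                length_range=(30, 34))
        bench = make_benchmark(spec, tmp_path / "bench")
        bundle = bench.targets[0]
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            for pdb in (tmp_path / "bench" / bundle.target_id).glob("*.pdb"):
                model = structure_io.read_model(pdb, bundle.target_id)
                assert model.length == bundle.native.length
            pred = structure_io.read_predicted_contacts(
                tmp_path / "bench" / f"{bundle.target_id}.rr",
                bundle.native.length)
        assert [(i, j) for i, j, _ in pred.entries] == [
            (i, j) for i, j, _ in bundle.predicted.entries]
        np.testing.assert_allclose([p for _, _, p in pred.entries],
                                   [p for _, _, p in bundle.predicted.entries],
                                   atol=1e-6)  # RR files carry 6 decimals

    def test_uninformative_spec_balances_mirrors(self):
        bench = generate_benchmark(uninformative_spec(seed=60, n_targets=12,
                                                      models_per_target=4))
        per_target_correct = [float(np.mean(t.tms >= 0.5)) for t in bench.targets]
        # chirality decides whole targets: each target is all-correct or all-wrong
        assert all(f in (0.0, 1.0) for f in per_target_correct)
        assert 0 < np.mean(per_target_correct) < 1

    def test_msa_exercises_beff(self):
        from rfqa.featurization import compute_beff
        msa = synth_msa(40, seed=61)
        assert len(msa) == 24
        beff = compute_beff(msa)
        assert 1.0 <= beff <= 24.0
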