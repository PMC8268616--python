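import itertools

import numpy as np
import pandas as pd
import pytest

from phenosig.errors import CalibrationError
from phenosig.signature_deconv import (Calibration, CandidateSignature,
                                       SignatureModel, build_signature_model,
                                       calibrate, candidate_signatures,
                                       deconvolve, fit_power,
                                       percentile_profiles, select_top3,
                                       simulate_dilutions, spillover_fit,
                                       ss_enrichment, _raw_scores)
from phenosig.sc_io import normalize
from phenosig.synthetic_data import simulate_single_cell

from conftest import make_matrix


class TestPercentileProfiles:
    def test_constant_gene_all_percentiles_equal(self):
        X = np.full((1, 20), 3.5)
        prof = percentile_profiles(X, ["G0"], pd.Series(["A"] * 20))
        for p, frame in prof.items():
            assert frame.at["G0", "A"] == 3.5

    def test_linear_interpolation_closed_form(self):
        X = np.arange(100, dtype=float).reshape(1, 100)
        prof = percentile_profiles(X, ["G0"], pd.Series(["A"] * 100))
        assert prof[10].at["G0", "A"] == pytest.approx(9.9)

    def test_percentiles_nondecreasing(self):
        rng = np.random.default_rng(0)
        X = rng.exponential(1.0, size=(30, 60))
        labels = pd.Series(["A"] * 30 + ["B"] * 30)
        prof = percentile_profiles(X, [f"G{i}" for i in range(30)], labels)
        stacked = np.stack([prof[p].values for p in (10, 25, 33, 50, 67, 75, 90)])
        assert (np.diff(stacked, axis=0) >= -1e-12).all()


class TestCandidateSignatures:
    def _profiles(self, lo_target, hi_other, n_genes=10):
        genes = [f"G{i}" for i in range(n_genes)]
        prof = {}
        for p in (10, 25, 33, 50, 67, 75, 90):
            prof[p] = pd.DataFrame({"A": lo_target, "B": hi_other}, index=genes)
        return prof

    def test_large_gap_passes_high_threshold(self):
        prof = self._profiles(1.0, 0.1)
        cands = candidate_signatures(prof, min_genes=8)
        thr08 = [c for c in cands if c.threshold == 0.80 and c.subcluster == "A"]
        assert thr08 and all(len(c.genes) == 10 for c in thr08)

    def test_gap_exactly_at_threshold_excluded(self):
        prof = self._profiles(0.9, 0.1)   # gap exactly 0.80
        cands = candidate_signatures(prof, min_genes=1)
        for c in cands:
            if c.subcluster == "A" and c.threshold == 0.80:
                pytest.fail("boundary gap must be excluded (strict >)")

    def test_monotone_in_threshold(self, small_sim):
        matrix, _ = small_sim
        norm = normalize(matrix).toarray()
        prof = percentile_profiles(norm, matrix.gene_ids, matrix.subclusters)
        cands = candidate_signatures(prof, min_genes=1, max_genes=10 ** 6)
        by_key = {(c.subcluster, c.pair, c.rank, c.threshold): set(c.genes)
                  for c in cands}
        for (sub, pair, rank, thr), genes in by_key.items():
            for thr2 in (0.0, 0.10, 0.50, 0.80):
                if thr2 > thr and (sub, pair, rank, thr2) in by_key:
                    assert by_key[(sub, pair, rank, thr2)] <= genes

    def test_planted_markers_in_rank1_threshold0_candidate(self):
        """At high in-subcluster detection, every planted marker clears the
        (10, 90) rank-1 threshold-0 comparison."""
        matrix, truth = simulate_single_cell(
            n_subclusters=3, cells_per_subcluster=300, n_genes=300,
            markers_per_subcluster=10, marker_detection_target=0.95,
            background_detection=0.02, seed=5)
        norm = normalize(matrix).toarray()
        prof = percentile_profiles(norm, matrix.gene_ids, matrix.subclusters)
        cands = candidate_signatures(prof, min_genes=1, max_genes=10 ** 6)
        for sub, genes in truth.planted_markers.items():
            sig = [c for c in cands if c.subcluster == sub and c.rank == 1
                   and c.pair == (10, 90) and c.threshold == 0.0]
            assert sig, f"no threshold-0 rank-1 candidate for {sub}"
            assert set(genes) <= set(sig[0].genes)


class TestEnrichment:
    def test_whole_transcriptome_set_scores_zero(self):
        expr = pd.Series([3.0, 1.0, 2.0], index=["A", "B", "C"])
        assert ss_enrichment(expr, ["A", "B", "C"]) == 0.0

    def test_top_placement_is_maximal(self):
        """Brute force: among all placements of a 3-gene set in a 6-gene
        ranking, occupying the top 3 ranks maximizes the score."""
        values = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        genes = list("ABCDEF")
        scores = {}
        for members in itertools.combinations(range(6), 3):
            gene_set = [genes[i] for i in members]
            scores[members] = ss_enrichment(pd.Series(values, index=genes),
                                            gene_set)
        assert max(scores, key=scores.get) == (0, 1, 2)
        assert min(scores, key=scores.get) == (3, 4, 5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        expr = pd.Series(rng.normal(size=50),
                         index=[f"G{i}" for i in range(50)])
        gene_set = [f"G{i}" for i in range(0, 20, 3)]
        base = ss_enrichment(expr, gene_set)
        assert ss_enrichment(np.exp(expr), gene_set) == pytest.approx(base)
        assert ss_enrichment(3.0 * expr + 7.0, gene_set) == pytest.approx(base)

    def test_empty_overlap_is_nan(self):
        expr = pd.Series([1.0, 2.0], index=["A", "B"])
        assert np.isnan(ss_enrichment(expr, ["Z"]))

    def test_matrix_and_series_forms_agree(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 4)),
                          index=[f"G{i}" for i in range(30)])
        gene_set = ["G1", "G5", "G9"]
        per_col = [ss_enrichment(df[c], gene_set) for c in df.columns]
        assert np.allclose(ss_enrichment(df, gene_set).values, per_col)


class TestSelectTop3:
    def test_planted_signature_beats_uniform(self, small_sim):
        matrix, truth = small_sim
        norm = normalize(matrix).toarray()
        sub = "SC1"
        planted = CandidateSignature(sub, tuple(truth.planted_markers[sub]),
                                     (10, 90), 1, 0.0)
        uniform = CandidateSignature(sub, tuple(f"GENE{i:05d}"
                                                for i in range(200, 210)),
                                     (25, 75), 1, 0.0)
        top = select_top3([planted, uniform], norm, matrix.gene_ids,
                          matrix.subclusters, n_top=1)
        assert top[sub][0] is planted

    def test_identical_candidates_tie_break_deterministic(self, small_sim):
        matrix, truth = small_sim
        norm = normalize(matrix).toarray()
        sub = "SC1"
        genes = tuple(truth.planted_markers[sub])
        a = CandidateSignature(sub, genes, (10, 90), 1, 0.0)
        b = CandidateSignature(sub, genes, (25, 75), 1, 0.0)
        top = select_top3([b, a], norm, matrix.gene_ids, matrix.subclusters,
                          n_top=2)
        # equal t-statistics: lexicographically smaller parameters first
        assert top[sub][0].pair == (10, 90)


class TestCalibration:
    def test_power_fit_recovers_exact_parameters(self):
        s = np.linspace(0.05, 1.0, 12)
        c = 2.0 * s ** 1.5
        a, b = fit_power(s, c)
        assert a == pytest.approx(2.0, abs=1e-6)
        assert b == pytest.approx(1.5, abs=1e-6)

    def test_calibrate_exact_on_noiseless_series(self):
        scores = np.linspace(0.1, 0.9, 11)
        q01, q99 = np.quantile(scores, [0.01, 0.99])
        s_r = np.clip((scores - q01) / (q99 - q01), 0, 1)
        conc = 2.0 * s_r ** 1.5  # exactly the model calibrate assumes
        cal = calibrate(scores, conc)
        assert cal.a == pytest.approx(2.0, rel=1e-6)
        assert cal.b == pytest.approx(1.5, rel=1e-6)

    def test_constant_scores_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate(np.ones(11), np.linspace(0.008, 0.25, 11))

    def test_too_few_positive_points_rejected(self):
        with pytest.raises(CalibrationError):
            fit_power([0.0, 0.0, 0.5], [0.01, 0.02, 0.03])


class TestDilutions:
    def test_layout_and_determinism(self, small_sim):
        matrix, _ = small_sim
        norm = normalize(matrix)
        prof1, conc = simulate_dilutions(norm, matrix.subclusters, "SC1",
                                         n_cells=500, seed=3,
                                         gene_ids=matrix.gene_ids)
        prof2, _ = simulate_dilutions(norm, matrix.subclusters, "SC1",
                                      n_cells=500, seed=3,
                                      gene_ids=matrix.gene_ids)
        assert prof1.shape[1] == 11 * 3 and len(conc) == 33
        pd.testing.assert_frame_equal(prof1, prof2)

    def test_zero_concentration_contains_no_target_signal(self, small_sim):
        matrix, truth = small_sim
        norm = normalize(matrix)
        prof, _ = simulate_dilutions(norm, matrix.subclusters, "SC1",
                                     concentrations=[0.0], n_cells=400,
                                     reps=1, seed=1, gene_ids=matrix.gene_ids)
        markers = truth.planted_markers["SC1"]
        background = prof.drop(index=[g for gs in truth.planted_markers.values()
                                      for g in gs])
        assert prof.loc[markers].values.mean() < background.values.mean() + 0.1

    def test_raw_score_monotone_in_concentration(self, small_sim):
        from scipy.stats import spearmanr
        matrix, truth = small_sim
        norm = normalize(matrix)
        prof, conc = simulate_dilutions(norm, matrix.subclusters, "SC1",
                                        n_cells=800, seed=2,
                                        gene_ids=matrix.gene_ids)
        scores = _raw_scores(prof, {"SC1": [tuple(truth.planted_markers["SC1"])]},
                             alpha=0.25)["SC1"].values
        assert spearmanr(scores, conc).statistic > 0.9


class TestSpillover:
    def test_duplicated_subcluster_spills_fully(self):
        rng = np.random.default_rng(6)
        n = 150
        block = rng.poisson(0.3, size=(60, n))
        block[:8, :] += rng.poisson(5.0, size=(8, n))
        counts = np.concatenate([block, block], axis=1) + 1
        labels = ["A"] * n + ["B"] * n   # same cells, two labels
        m = make_matrix(counts, subclusters=labels)
        norm = normalize(m).toarray()
        sigs = {"A": [tuple(f"G{i}" for i in range(8))],
                "B": [tuple(f"G{i}" for i in range(8))]}
        cal = {s: Calibration(q01=0.0, q99=1.0, a=1.0, b=1.0) for s in sigs}
        labels_s = pd.Series(labels, index=m.cell_ids)
        K = spillover_fit(norm, labels_s, sigs, cal, m.gene_ids,
                          n_cells=600, seed=0)
        assert K.values[0, 1] > 0.9 and K.values[1, 0] > 0.9

    def test_shared_marker_neighbour_has_larger_spillover(self):
        rng = np.random.default_rng(7)
        n = 150
        base = rng.poisson(0.2, size=(60, 3 * n)) + 1
        # A: genes 0-9; B shares genes 0-4 and owns 10-14; C owns 20-29
        base[0:10, :n] += rng.poisson(6.0, size=(10, n))
        base[0:5, n:2 * n] += rng.poisson(6.0, size=(5, n))
        base[10:15, n:2 * n] += rng.poisson(6.0, size=(5, n))
        base[20:30, 2 * n:] += rng.poisson(6.0, size=(10, n))
        labels = ["A"] * n + ["B"] * n + ["C"] * n
        m = make_matrix(base, subclusters=labels)
        norm = normalize(m).toarray()
        sigs = {"A": [tuple(f"G{i}" for i in range(10))],
                "B": [tuple(f"G{i}" for i in range(5)) +
                      tuple(f"G{i}" for i in range(10, 15))],
                "C": [tuple(f"G{i}" for i in range(20, 30))]}
        cal = {s: Calibration(q01=0.0, q99=1.0, a=1.0, b=1.0) for s in sigs}
        labels_s = pd.Series(labels, index=m.cell_ids)
        K = spillover_fit(norm, labels_s, sigs, cal, m.gene_ids,
                          n_cells=900, seed=1)
        # A's signature spills more into B (shares half its genes) than C does
        assert K.at["A", "B"] > K.at["C", "B"]

    def test_unit_diagonal_and_nonnegative(self, small_sim):
        matrix, truth = small_sim
        norm = normalize(matrix).toarray()
        sigs = {s: [tuple(g)] for s, g in truth.planted_markers.items()}
        cal = {s: Calibration(q01=0.0, q99=0.5, a=0.3, b=1.2) for s in sigs}
        K = spillover_fit(norm, matrix.subclusters, sigs, cal,
                          matrix.gene_ids, n_cells=600, seed=2)
        assert np.allclose(np.diag(K.values), 1.0)
        assert (K.values >= 0).all()


class TestDeconvolve:
    def _toy_model(self):
        sigs = {"A": [("G0", "G1", "G2")], "B": [("G5", "G6", "G7")]}
        cal = {s: Calibration(q01=-0.5, q99=0.5, a=1.0, b=1.0) for s in sigs}
        K = pd.DataFrame(np.eye(2), index=["A", "B"], columns=["A", "B"])
        return SignatureModel(subclusters=["A", "B"], signatures=sigs,
                              calibration=cal, spillover=K)

    def test_identity_spillover_is_noop(self):
        rng = np.random.default_rng(8)
        model = self._toy_model()
        bulk = pd.DataFrame(rng.normal(size=(5, 10)),
                            columns=[f"G{i}" for i in range(10)])
        est = deconvolve(bulk, model)
        raw = _raw_scores(bulk.T, model.signatures, model.alpha)
        for sub in ("A", "B"):
            expected = np.clip(model.calibration[sub].concentration(
                raw[sub].values), 0, None)
            assert np.allclose(est[sub].values, expected, atol=1e-9)

    def test_model_json_round_trip(self, tmp_path):
        model = self._toy_model()
        model.to_json(tmp_path / "model.json")
        back = SignatureModel.from_json(tmp_path / "model.json")
        assert back.signatures == model.signatures
        assert back.calibration["A"] == model.calibration["A"]
        pd.testing.assert_frame_equal(back.spillover, model.spillover)

    def test_calibration_mixture_ranks_its_own_subcluster_highest(self):
        """A 25%-pure mixture of a subcluster yields that subcluster's highest
        abundance estimate among all mixtures.  Needs six subclusters: with
        four, a 25% mixture is exactly the uniform composition and carries no
        signal by construction."""
        matrix, _ = simulate_single_cell(
            n_subclusters=6, cells_per_subcluster=250, n_genes=500,
            markers_per_subcluster=12, marker_detection_target=0.8,
            background_detection=0.02, seed=13)
        model = build_signature_model(matrix, n_mix_cells=600, seed=4)
        norm = normalize(matrix)
        mixes = {}
        for sub in model.subclusters:
            prof, _ = simulate_dilutions(norm, matrix.subclusters, sub,
                                         concentrations=[0.25], n_cells=600,
                                         reps=1, seed=9, gene_ids=matrix.gene_ids)
            mixes[sub] = prof.iloc[:, 0]
        bulk = pd.DataFrame(mixes).T  # mixtures x genes
        est = deconvolve(bulk, model)
        for sub in model.subclusters:
            assert est[sub].idxmax() == sub
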