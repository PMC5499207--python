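import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from rnadx import io
from rnadx.splicing import (
    SplicingOutlierModel,
    annotate_splice_sites,
    classify_event,
    cluster_introns,
    compute_psi,
    load_junctions,
    private_exon_weak_enrichment,
    psi_site_observations,
    test_cluster_one_vs_rest as cluster_test,
)
from rnadx.simulate import SimulationConfig, simulate_junction_table


def _junctions(rows, samples=("A", "B")):
    recs = []
    for chrom, d, a, strand, *counts in rows:
        rec = {"chrom": chrom, "donor": d, "acceptor": a, "strand": strand}
        rec.update({s: c for s, c in zip(samples, counts)})
        recs.append(rec)
    return pd.DataFrame(recs)


class TestLoadJunctions:
    def test_star_coordinates_become_half_open(self, tmp_path):
        tab = _junctions([("chr1", 101, 200, "+", 5, 3)])
        path = tmp_path / "sj.tsv"
        io.write_junction_table(tab, path)
        out = load_junctions(path, coords="star")
        assert out.loc[0, "donor"] == 100 and out.loc[0, "acceptor"] == 200

    def test_duplicates_merged_by_summation(self, tmp_path):
        tab = _junctions(
            [("chr1", 100, 200, "+", 3, 0), ("chr1", 100, 200, "+", 4, 1)]
        )
        path = tmp_path / "sj.tsv"
        io.write_junction_table(tab, path)
        out = load_junctions(path)
        assert len(out) == 1
        assert out.loc[0, "A"] == 7 and out.loc[0, "B"] == 1

    def test_inverted_rows_rejected_with_warning(self, tmp_path):
        tab = _junctions([("chr1", 300, 200, "+", 3, 0), ("chr1", 10, 20, "+", 1, 1)])
        path = tmp_path / "sj.tsv"
        io.write_junction_table(tab, path)
        with pytest.warns(UserWarning, match="acceptor <= donor"):
            out = load_junctions(path)
        assert len(out) == 1

    def test_round_trip_of_simulated_table(self, tmp_path, junc_sim):
        path = tmp_path / "sj.tsv"
        io.write_junction_table(junc_sim.junctions, path)
        out = load_junctions(path)
        merged = junc_sim.junctions.sort_values(io.JUNCTION_KEY).reset_index(drop=True)
        pd.testing.assert_frame_equal(out, merged)


class TestClusterIntrons:
    def test_shared_donor_total_over_threshold_forms_cluster(self):
        tab = _junctions(
            [("chr1", 100, 200, "+", 20, 0), ("chr1", 100, 300, "+", 15, 0)]
        )
        clusters = cluster_introns(tab)
        assert len(clusters) == 1
        assert clusters[0].total_reads == 35

    def test_single_junction_below_minclureads_dropped(self):
        tab = _junctions([("chr1", 100, 200, "+", 29, 0)])
        assert cluster_introns(tab) == []

    def test_overlong_intron_excluded_before_clustering(self):
        tab = _junctions(
            [("chr1", 100, 700_000, "+", 50, 0), ("chr1", 100, 300, "+", 40, 0)]
        )
        clusters = cluster_introns(tab)
        assert len(clusters) == 1
        assert clusters[0].members == [1]

    def test_low_ratio_junction_pruned(self):
        tab = _junctions(
            [
                ("chr1", 100, 200, "+", 2_000_000, 0),
                ("chr1", 100, 300, "+", 10, 0),  # ratio 5e-6 < 1e-5
            ]
        )
        clusters = cluster_introns(tab)
        assert clusters[0].members == [0]

    def test_invariant_to_input_order(self, junc_sim):
        tab = junc_sim.junctions
        shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = {c.cluster_id: c.total_reads for c in cluster_introns(tab)}
        b = {c.cluster_id: c.total_reads for c in cluster_introns(shuffled)}
        assert a == b


class TestComputePsi:
    def test_clpp_worked_example(self):
        # an acceptor overlapped by 136 split reads: 82 skip the exon,
        # 14 support a truncated exon, 40 the canonical junction
        tab = _junctions(
            [
                ("chr19", 500, 1000, "+", 82, 0),   # exon-skipping junction
                ("chr19", 700, 1000, "+", 14, 0),   # truncated-exon junction
                ("chr19", 800, 1000, "+", 40, 0),   # canonical junction
            ],
            samples=("P", "C"),
        )
        psi = compute_psi(tab)
        assert round(100 * psi.psi3.loc[0, "P"]) == 60
        assert round(100 * psi.psi3.loc[1, "P"]) == 10
        assert psi.n3.loc[0, "P"] == 136

    def test_sole_junction_at_donor_has_unit_psi5(self):
        tab = _junctions([("chr1", 100, 200, "+", 7, 0)])
        psi = compute_psi(tab)
        assert psi.psi5.loc[0, "A"] == 1.0
        assert np.isnan(psi.psi5.loc[0, "B"])  # zero denominator

    def test_psi_sums_to_one_per_site_and_sample(self, junc_sim):
        tab = junc_sim.junctions
        psi = compute_psi(tab)
        samples = [c for c in tab.columns if c not in io.JUNCTION_KEY]
        key = list(zip(tab["chrom"], tab["strand"], tab["donor"]))
        sums = psi.psi5.groupby(pd.Index(key)).sum()
        counts = psi.n5.groupby(pd.Index(key)).first()
        for s in samples:
            expressed = counts[s] > 0
            assert np.allclose(sums.loc[expressed, s], 1.0)


class TestAnnotateSpliceSites:
    exons = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [101, 301],
            "end": [200, 400],
            "strand": ["+", "+"],
            "gene_id": ["g", "g"],
            "exon_id": ["e1", "e2"],
        }
    )

    def test_both_and_no_sides_annotated(self):
        tab = _junctions(
            [("chr1", 200, 300, "+", 5, 5), ("chr1", 210, 280, "+", 5, 5)]
        )
        flags = annotate_splice_sites(tab, self.exons)
        assert flags.loc[0, "s"] == 2
        assert flags.loc[1, "s"] == 0

    def test_groups_match_generator_truth(self, junc_sim):
        flags = annotate_splice_sites(junc_sim.junctions, junc_sim.exons)
        for i, row in junc_sim.junctions.iterrows():
            key = (row["chrom"], row["donor"], row["acceptor"], row["strand"])
            assert flags.loc[i, "s"] == junc_sim.truth.junction_groups[key]


# ---------------------------------------------------------------------------
# independent beta-binomial LRT oracle for the two-junction case
# ---------------------------------------------------------------------------

def _bb_loglik(n, N, a, b):
    return float(
        np.sum(
            gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
            + betaln(n + a, N - n + b) - betaln(a, b)
        )
    )


def two_junction_oracle(Y, mask, gamma_floor=0.01):
    """Direct likelihood maximisation of the beta-binomial contrast:
    shared concentration, separate proportions for patient and rest."""
    n, N = Y[:, 0], Y.sum(axis=1)

    def nll_null(theta):
        lg, logit = theta
        g = max(np.exp(lg), gamma_floor)
        p = 1 / (1 + np.exp(-logit))
        return -_bb_loglik(n, N, g * p, g * (1 - p))

    def nll_alt(theta):
        lg, l1, l2 = theta
        g = max(np.exp(lg), gamma_floor)
        p1 = 1 / (1 + np.exp(-l1))
        p2 = 1 / (1 + np.exp(-l2))
        return -(
            _bb_loglik(n[mask], N[mask], g * p1, g * (1 - p1))
            + _bb_loglik(n[~mask], N[~mask], g * p2, g * (1 - p2))
        )

    r0 = min(
        (minimize(nll_null, x0, method="Nelder-Mead",
                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
         for x0 in ([np.log(10), 0.0], [np.log(100), -1.0])),
        key=lambda r: r.fun,
    )
    r1 = min(
        (minimize(nll_alt, x0, method="Nelder-Mead",
                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 6000})
         for x0 in ([np.log(10), 0.0, 0.0], [np.log(100), 1.0, -1.0])),
        key=lambda r: r.fun,
    )
    lrt = max(0.0, 2.0 * (r0.fun - r1.fun))
    return stats.chi2.sf(lrt, df=1)


class TestClusterTest:
    def test_null_identity_when_proportions_match(self):
        Y = np.tile([400.0, 600.0], (20, 1))
        mask = np.zeros(20, dtype=bool)
        mask[0] = True
        p, stat = cluster_test(Y, mask)
        assert stat == pytest.approx(0.0, abs=1e-4)
        assert p > 0.99

    def test_two_junction_case_matches_betabinomial_oracle(self):
        rng = np.random.default_rng(4)
        N = rng.integers(50, 150, 15)
        psi = np.full(15, 0.2)
        psi[0] = 0.85
        n = rng.binomial(N, psi)
        Y = np.column_stack([n, N - n]).astype(float)
        mask = np.zeros(15, dtype=bool)
        mask[0] = True
        p, _ = cluster_test(Y, mask)
        expected = two_junction_oracle(Y, mask)
        assert p == pytest.approx(expected, rel=1e-3, abs=1e-8)

    def test_patient_without_reads_is_not_testable(self):
        Y = np.tile([5.0, 5.0], (10, 1))
        mask = np.zeros(10, dtype=bool)
        mask[0] = True
        Y[0] = 0.0
        p, stat = cluster_test(Y, mask)
        assert np.isnan(p) and np.isnan(stat)

    def test_injected_switch_is_detected(self):
        # patient switches psi 0.05 -> 0.95 at coverage ~100
        rng = np.random.default_rng(5)
        hits = 0
        reps = 25
        for _ in range(reps):
            S = 30
            N = rng.poisson(100, S) + 1
            psi = np.full(S, 0.05)
            psi[0] = 0.95
            n = rng.binomial(N, psi)
            Y = np.column_stack([n, N - n]).astype(float)
            mask = np.zeros(S, dtype=bool)
            mask[0] = True
            p, _ = cluster_test(Y, mask)
            hits += p < 0.05 / 150  # Hochberg-style family of 150 clusters
        assert hits / reps >= 0.95


class TestClassifyEvent:
    exons = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [101, 301, 601],
            "end": [200, 400, 700],
            "strand": ["+"] * 3,
            "gene_id": ["g"] * 3,
            "exon_id": ["e1", "e2", "e3"],
        }
    )

    def _classify(self, rows, delta):
        tab = _junctions(rows)
        flags = annotate_splice_sites(tab, self.exons)
        return classify_event(tab, np.asarray(delta), flags, self.exons)

    def test_junction_spanning_full_exon_is_skipping(self):
        # exon1 end -> exon3 start skips exon2 entirely
        event, _ = self._classify(
            [("chr1", 200, 600, "+", 50, 0), ("chr1", 200, 300, "+", 5, 40)],
            [0.6, -0.6],
        )
        assert event == "exon skipping"

    def test_acceptor_inside_exon_is_truncation(self):
        event, _ = self._classify(
            [("chr1", 200, 330, "+", 50, 0), ("chr1", 200, 300, "+", 5, 40)],
            [0.6, -0.6],
        )
        assert event == "exon truncation"

    def test_acceptor_in_intron_is_elongation(self):
        event, _ = self._classify(
            [("chr1", 200, 280, "+", 50, 0), ("chr1", 200, 300, "+", 5, 40)],
            [0.6, -0.6],
        )
        assert event == "exon elongation"

    def test_novel_interval_between_annotated_exons_is_new_exon(self):
        event, sites = self._classify(
            [
                ("chr1", 200, 240, "+", 30, 0),  # exon1 end -> novel acceptor
                ("chr1", 260, 300, "+", 30, 0),  # novel donor -> exon2 start
                ("chr1", 200, 300, "+", 10, 60),  # canonical
            ],
            [0.4, 0.4, -0.8],
        )
        assert event == "new exon"
        assert sites == ["0:5", "1:3"]

    def test_no_annotation_overlap_is_unclassified(self):
        event, _ = self._classify(
            [("chr1", 5000, 5100, "+", 30, 0), ("chr1", 5000, 5200, "+", 10, 30)],
            [0.5, -0.5],
        )
        assert event == "unclassified"


class TestWeakEnrichment:
    def test_arithmetic_identity(self):
        calls = pd.DataFrame(
            {
                "event_class": ["new exon", "new exon"],
                "event_sites": [["a:5", "b:3"], ["c:5", "d:3"]],
            }
        )
        classes = pd.Series(
            ["weak"] * 4 + ["weak"] * 12 + ["strong"] * 84,
            index=[f"{i}" for i in range(100)].__class__(
                ["a:5", "b:3", "c:5", "d:3"] + [f"x{i}" for i in range(96)]
            ),
        )
        frac, fold = private_exon_weak_enrichment(calls, classes)
        assert frac == 1.0
        assert fold == pytest.approx(1.0 / 0.16)

    def test_no_private_events_gives_empty_result(self):
        calls = pd.DataFrame({"event_class": ["complex"], "event_sites": [[]]})
        classes = pd.Series(["weak"], index=["a:5"])
        frac, fold = private_exon_weak_enrichment(calls, classes)
        assert np.isnan(frac) and np.isnan(fold)


class TestEndToEndSplicing:
    def test_injected_new_exons_recovered_and_classified(self, junc_sim, small_config):
        model = SplicingOutlierModel(
            junc_sim.junctions, junc_sim.annotation, junc_sim.exons
        )
        calls = model.fit().call_events()
        truth = {(c, s) for c, s, _ in junc_sim.truth.splice_outliers}
        found = set(zip(calls["cluster"], calls["sample"]))
        assert truth, "simulation should inject events"
        recovered = truth & found
        assert len(recovered) / len(truth) >= 0.9
        hit_calls = calls[
            [(c, s) in truth for c, s in zip(calls["cluster"], calls["sample"])]
        ]
        assert (hit_calls["event_class"] == "new exon").mean() >= 0.9
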