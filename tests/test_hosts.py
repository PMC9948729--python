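"""Host linking: CRISPR detection, spacer matching, Markov host
prediction, exact Spearman p-values, and the interaction network."""

import math

import numpy as np
import pytest

from pingovir.config import PipelineConfig
from pingovir.io import ContigRecord, SampleMetadata
from pingovir.hosts import (
    build_network,
    detect_crispr_arrays,
    match_spacers,
    predict_host,
    score_sequence,
    spearman_assoc,
    train_markov_model,
)
from pingovir.synthetic import CommunityDesign, GroundTruth, simulate_abundances
from pingovir.quant import median_of_ratios_normalize
from conftest import mutate, random_seq

CFG = PipelineConfig()


def _genome_with_array(rng, repeat_len=30, spacer_len=32, k=4, flank=2000):
    repeat = random_seq(rng, repeat_len)
    spacers = [random_seq(rng, spacer_len) for _ in range(k - 1)]
    array = repeat + "".join(s + repeat for s in spacers)
    genome = random_seq(rng, flank) + array + random_seq(rng, flank)
    return ContigRecord("g", genome), repeat, spacers


class TestCrisprDetection:
    def test_planted_array_recovered_verbatim(self, rng):
        genome, repeat, spacers = _genome_with_array(rng)
        arrays = detect_crispr_arrays(genome)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.n_repeats == 4
        assert a.repeat_consensus == repeat
        assert [s for _, s in a.spacers] == spacers

    def test_two_repeats_not_reported(self, rng):
        repeat = random_seq(rng, 30)
        s = random_seq(rng, 32)
        genome = ContigRecord(
            "g", random_seq(rng, 2000) + repeat + s + repeat + random_seq(rng, 2000)
        )
        assert detect_crispr_arrays(genome) == []

    def test_no_false_positives_on_random_genomes(self):
        """Exact-repeat semantics: zero arrays on 50 random 100-kb
        genomes."""
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            genome = ContigRecord("g", random_seq(r, 100_000))
            hits += len(detect_crispr_arrays(genome))
        assert hits == 0

    def test_identical_spacers_rejected_as_satellite(self, rng):
        repeat = random_seq(rng, 30)
        s = random_seq(rng, 32)
        genome = ContigRecord(
            "g",
            random_seq(rng, 1000) + repeat + s + repeat + s + repeat + random_seq(rng, 1000),
        )
        assert detect_crispr_arrays(genome) == []

    def test_ledger_recovery_on_community(self, small_community):
        """With mutation_rate 0 every planted spacer is recovered
        verbatim from its host."""
        c = small_community
        by_id = {p.id: p for p in c.phages}
        recovered = {}
        for g in c.hosts:
            arrays = detect_crispr_arrays(g)
            recovered[g.id] = [s for a in arrays for _, s in a.spacers]
        assert c.truth.spacer_provenance
        for host_id, _, _, src, offset in c.truth.spacer_provenance:
            assert any(
                by_id[src].seq[offset : offset + len(s)] == s for s in recovered[host_id]
            ), (host_id, src, offset)


class TestSpacerMatching:
    def test_planted_spacer_hits_at_full_identity(self, rng):
        phage = ContigRecord("ph", random_seq(rng, 5000))
        spacer = phage.seq[1000:1032]
        hits = match_spacers([("h", 0, spacer)], [phage])
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 100.0 and h.qcov == 1.0 and h.offset == 1000

    def test_reverse_strand_hit(self, rng):
        from pingovir.triage import revcomp

        phage = ContigRecord("ph", random_seq(rng, 5000))
        spacer = revcomp(phage.seq[2000:2032])
        hits = match_spacers([("h", 0, spacer)], [phage])
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].offset == 2000

    def test_two_mismatches_pass_90_percent(self, rng):
        phage = ContigRecord("ph", random_seq(rng, 5000))
        spacer = list(phage.seq[1000:1032])
        for pos in (5, 20):
            spacer[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[spacer[pos]]
        hits = match_spacers([("h", 0, "".join(spacer))], [phage])
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(100 * 30 / 32)

    def test_four_mismatches_fail_90_percent(self, rng):
        phage = ContigRecord("ph", random_seq(rng, 5000))
        spacer = list(phage.seq[1000:1032])
        for pos in (5, 12, 20, 27):
            spacer[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[spacer[pos]]
        assert match_spacers([("h", 0, "".join(spacer))], [phage]) == []

    def test_community_spacers_link_to_source_phages(self, small_community):
        c = small_community
        spacers = []
        for g in c.hosts:
            for a in detect_crispr_arrays(g):
                for _, s in a.spacers:
                    spacers.append((g.id, len(spacers), s))
        hits = match_spacers(spacers, c.phages)
        hit_pairs = {(h.host_id, h.votu_id) for h in hits}
        truth_pairs = {(host, src) for host, _, _, src, _ in c.truth.spacer_provenance}
        assert truth_pairs <= hit_pairs


class TestMarkovModel:
    def test_uniform_genome_gives_uniform_transitions(self, rng):
        genome = ContigRecord("g", random_seq(rng, 100_000))
        decoys = [ContigRecord("d", random_seq(rng, 5000))]
        model = train_markov_model(genome, 1, decoys)
        probs = np.exp(model.log_probs)
        assert np.abs(probs - 0.25).max() < 0.01

    def test_exact_uniform_model_scores_log_quarter(self):
        model = train_markov_model(
            ContigRecord("g", "ACGT" * 500), 1, [ContigRecord("d", "ACGT" * 100)]
        )
        model.log_probs[:] = math.log(0.25)
        assert score_sequence(model, "AAACCCGGGTTT") == pytest.approx(math.log(0.25))

    def test_determinism(self, rng):
        genome = ContigRecord("g", random_seq(rng, 20_000))
        decoys = [ContigRecord("d", random_seq(rng, 4000))]
        m1 = train_markov_model(genome, 3, decoys)
        m2 = train_markov_model(genome, 3, decoys)
        assert np.array_equal(m1.log_probs, m2.log_probs)
        assert (m1.null_mu, m1.null_sigma) == (m2.null_mu, m2.null_sigma)

    def test_order_bounds(self, rng):
        g = ContigRecord("g", random_seq(rng, 1000))
        with pytest.raises(ValueError):
            train_markov_model(g, 0, [g])
        with pytest.raises(ValueError):
            train_markov_model(g, 9, [g])

    def test_own_genome_scores_at_least_as_high(self):
        """A host's genome is at least as likely under its own model as
        under a model trained on an independent random genome."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = ContigRecord("a", random_seq(r, 30_000))
            b = ContigRecord("b", random_seq(r, 30_000))
            decoys = [ContigRecord("d", random_seq(r, 4000))]
            ma = train_markov_model(a, 2, decoys)
            mb = train_markov_model(b, 2, decoys)
            assert score_sequence(ma, a.seq) >= score_sequence(mb, a.seq)


class TestPredictHost:
    def test_generating_host_ranks_first(self):
        """A phage sampled from host A's order-2 transition model ranks
        host A above an unrelated host in >= 95% of 50 seeds."""
        wins = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            host_a = ContigRecord("A", random_seq(r, 50_000))
            host_b = ContigRecord("B", random_seq(r, 50_000))
            decoys = [ContigRecord(f"d{i}", random_seq(r, 4000)) for i in range(5)]
            gen = train_markov_model(host_a, 2, decoys)
            probs = np.exp(gen.log_probs)
            seq = [0, 1]
            for _ in range(20_000):
                ctx = seq[-2] * 4 + seq[-1]
                seq.append(r.choice(4, p=probs[ctx]))
            phage = ContigRecord("ph", "".join("ACGT"[c] for c in seq))
            ranking = predict_host(
                phage,
                [train_markov_model(host_a, 2, decoys), train_markov_model(host_b, 2, decoys)],
            )
            wins += ranking[0][0] == "A"
        assert wins >= 48  # 96% of 50

    def test_decoy_scores_give_sane_p(self, rng):
        genome = ContigRecord("g", random_seq(rng, 30_000))
        decoys = [ContigRecord(f"d{i}", random_seq(rng, 4000)) for i in range(5)]
        model = train_markov_model(genome, 2, decoys)
        ranking = predict_host(decoys[0], [model])
        assert 0.0 < ranking[0][2] < 1.0

    def test_identical_models_stable_tie_order(self, rng):
        genome = ContigRecord("g", random_seq(rng, 20_000))
        decoys = [ContigRecord("d", random_seq(rng, 4000))]
        m1 = train_markov_model(genome, 2, decoys)
        m2 = train_markov_model(genome, 2, decoys)
        m1.host_id, m2.host_id = "hostB", "hostA"
        phage = ContigRecord("ph", random_seq(rng, 2000))
        ranking = predict_host(phage, [m1, m2])
        assert [r[0] for r in ranking] == ["hostA", "hostB"]

    def test_empty_model_list_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_host(ContigRecord("p", random_seq(rng, 1000)), [])


class TestSpearman:
    def test_perfect_anticorrelation_exact_p(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [6, 5, 4, 3, 2, 1]
        rho, p = spearman_assoc(x, y)
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 720)

    def test_identity(self):
        x = np.arange(7.0)
        rho, _ = spearman_assoc(x, x)
        assert rho == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        rho, p = spearman_assoc([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_exact_vs_t_approximation(self):
        """At n=8 exact enumeration and the t-approximation agree
        closely (worst observed gap 0.024 over these 100 seeded draws;
        the t-approximation is the anticonservative side)."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p_exact = spearman_assoc(x, y, exact_max_n=8)
            _, p_approx = spearman_assoc(x, y, exact_max_n=0)
            assert abs(p_exact - p_approx) <= 0.025

    def test_borderline_rho_at_n7_fails_rho_threshold_not_p(self):
        """rho = -0.786 at n=7: exact two-sided p is 242/5040 = 0.048,
        so it clears p <= 0.05 but is excluded by the rho <= -0.8
        threshold; the next attainable value, -0.821, passes both."""
        x = [1, 2, 3, 4, 5, 6, 7]
        y = [4, 7, 6, 5, 3, 2, 1]  # rho = -0.786
        rho, p = spearman_assoc(x, y)
        assert rho == pytest.approx(-0.7857, abs=1e-3)
        assert p == pytest.approx(242 / 5040)
        assert not (rho <= -0.8)


def _meta(n_producers):
    rows = []
    for i in range(n_producers):
        pid = f"P{i + 1:02d}"
        rows.append((f"{pid}S", pid, "starter", pid))
        rows.append((f"{pid}C", pid, "cheese", pid))
    import pandas as pd

    return SampleMetadata(
        pd.DataFrame(rows, columns=["sample_id", "producer_id", "stage", "pair_id"])
    )


class TestNetwork:
    def _community_matrices(self, seed, beta, n_phage=15, n_hosts=16, n_edges=6):
        d = CommunityDesign(
            n_phage=n_phage, n_hosts=n_hosts, coupling_beta=beta, lognormal_sigma=0.2
        )
        truth = GroundTruth()
        pids = [f"phage_{i:04d}" for i in range(n_phage)]
        hids = [f"host_{h:03d}" for h in range(n_hosts)]
        for i in range(n_edges):
            truth.planted_edges.append((pids[i], hids[i], beta))
        cp, ch, meta = simulate_abundances(d, truth, seed, pids, hids)
        cpn, _ = median_of_ratios_normalize(cp)
        chn, _ = median_of_ratios_normalize(ch)
        return cpn, chn, meta, truth

    def test_empty_matrices_give_empty_network(self):
        import pandas as pd

        edges = build_network(
            pd.DataFrame(), pd.DataFrame(), _meta(7), CFG, mode="starter_vs_cheese"
        )
        assert edges == []

    def test_strong_coupling_recovery(self):
        """beta=8, sigma=0.2, 7 producers: >= 80% of planted edges pass
        the rho <= -0.8, exact p <= 0.05 rule."""
        recovered = total = 0
        for seed in range(40):
            cpn, chn, meta, truth = self._community_matrices(seed, beta=8.0)
            edges = build_network(cpn, chn, meta, CFG, mode="starter_vs_cheese")
            got = {(e.phage_id, e.host_id) for e in edges if "correlation" in e.evidence}
            planted = {(v, h) for v, h, _ in truth.planted_edges}
            recovered += len(got & planted)
            total += len(planted)
        assert recovered / total >= 0.8

    def test_null_false_edge_rate_matches_exact_expectation(self):
        """beta=0: the per-pair false-edge rate equals the exact
        permutation-null probability of rho <= -0.8 & p <= 0.05 at n=7
        (86/5040), within Monte-Carlo tolerance."""
        false_edges = pairs = 0
        for seed in range(60):
            cpn, chn, meta, truth = self._community_matrices(
                seed + 10_000, beta=0.0, n_phage=6, n_hosts=4, n_edges=0
            )
            edges = build_network(cpn, chn, meta, CFG, mode="starter_vs_cheese")
            false_edges += sum(1 for e in edges if "correlation" in e.evidence)
            pairs += 6 * 4
        expected = 86 / 5040  # exact enumeration of n=7 rank pairings
        se = math.sqrt(expected * (1 - expected) / pairs)
        assert abs(false_edges / pairs - expected) < 4 * se + 1e-9

    def test_monotone_in_thresholds(self):
        """Loosening |rho_max| or p_max never removes an edge."""
        cpn, chn, meta, _ = self._community_matrices(3, beta=8.0)
        strict = build_network(cpn, chn, meta, CFG, mode="starter_vs_cheese")
        loose_cfg = PipelineConfig(rho_max=-0.7, p_max=0.10)
        loose = build_network(cpn, chn, meta, loose_cfg, mode="starter_vs_cheese")
        strict_pairs = {(e.phage_id, e.host_id) for e in strict}
        loose_pairs = {(e.phage_id, e.host_id) for e in loose}
        assert strict_pairs <= loose_pairs

    def test_determinism(self):
        cpn, chn, meta, _ = self._community_matrices(4, beta=8.0)
        e1 = build_network(cpn, chn, meta, CFG, mode="starter_vs_cheese")
        e2 = build_network(cpn, chn, meta, CFG, mode="starter_vs_cheese")
        assert [(e.phage_id, e.host_id, e.rho, e.p_value, e.evidence) for e in e1] == [
            (e.phage_id, e.host_id, e.rho, e.p_value, e.evidence) for e in e2
        ]

    def test_spacer_and_markov_evidence_attached(self):
        cpn, chn, meta, _ = self._community_matrices(5, beta=8.0)
        from pingovir.hosts import SpacerHit

        hit = SpacerHit("host_015", 0, "phage_0014", 100.0, 1.0, 10, "+")
        preds = {"phage_0013": [("host_014", -1.3, 0.01), ("host_000", -1.4, 0.5)]}
        edges = build_network(
            cpn, chn, meta, CFG, spacer_hits=[hit], host_predictions=preds,
            mode="starter_vs_cheese",
        )
        by_pair = {(e.phage_id, e.host_id): e.evidence for e in edges}
        assert "crispr" in by_pair[("phage_0014", "host_015")]
        assert "markov" in by_pair[("phage_0013", "host_014")]

    def test_too_few_producers_rejected(self):
        import pandas as pd

        cpn, chn, _, _ = self._community_matrices(6, beta=8.0)
        with pytest.raises(ValueError, match="producers"):
            build_network(cpn, chn, _meta(3), CFG, mode="starter_vs_cheese")
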