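import math

import numpy as np
import pandas as pd
import pytest

from xenotraffic.io_formats import default_design
from xenotraffic.synthetic_data import (
    SimulationConfig,
    expected_counts,
    mutate_sequence,
    read_truth,
    simulate_counts,
    simulate_transcriptomes,
    write_simulation,
    write_truth,
)

from oracles import edlib_identity


class TestMutateSequence:
    def test_rate_zero_is_identity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        assert mutate_sequence(seq, 0.0, seed=1) == seq

    def test_rate_one_changes_every_site(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        out = mutate_sequence(seq, 1.0, seed=1)
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_substitution_fraction_matches_binomial(self, rng):
        """Pooled over 20 seeds, the substituted fraction at rate 0.1 is
        within 3 binomial SD of 0.1."""
        n, rate, seeds = 10_000, 0.1, 20
        seq = "".join(rng.choice(list("ACGT"), size=n))
        subs = 0
        for seed in range(seeds):
            out = mutate_sequence(seq, rate, seed=seed)
            subs += sum(a != b for a, b in zip(seq, out))
        total = n * seeds
        sd = math.sqrt(rate * (1 - rate) * total)
        assert abs(subs - rate * total) <= 3 * sd

    def test_deterministic_given_seed(self):
        seq = "ACGT" * 100
        assert mutate_sequence(seq, 0.3, seed=5) == mutate_sequence(seq, 0.3, seed=5)
        assert mutate_sequence(seq, 0.3, seed=5) != mutate_sequence(seq, 0.3, seed=6)


class TestSimulateTranscriptomes:
    def test_truth_class_sizes_match_config_arithmetic(self):
        cfg = SimulationConfig(n_host_genes=220, n_parasite_genes=180,
                               frac_conserved_orthologs=0.25,
                               frac_mobile_parasite_to_host=0.10,
                               frac_mobile_host_to_parasite=0.05, seed=2)
        host, parasite, refs, truth = simulate_transcriptomes(cfg)
        assert len(host) == 220 and len(parasite) == 180
        assert (truth.mobility == "CD_to_HC").sum() == round(0.10 * 180)
        assert (truth.mobility == "HC_to_CD").sum() == round(0.05 * 220)
        assert truth.conserved_ortholog.sum() == 2 * round(0.25 * 180)
        assert truth.coding.sum() == round(0.8 * 220) + round(0.8 * 180)

    def test_zero_mobile_fractions_give_no_mobile_labels(self):
        cfg = SimulationConfig(n_host_genes=60, n_parasite_genes=60,
                               frac_mobile_parasite_to_host=0.0,
                               frac_mobile_host_to_parasite=0.0, seed=3)
        *_, truth = simulate_transcriptomes(cfg)
        assert (truth.mobility == "none").all()

    def test_infeasible_mobile_fraction_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationConfig(n_host_genes=100, n_parasite_genes=100,
                             frac_conserved_orthologs=0.5,
                             frac_mobile_parasite_to_host=0.6)

    def test_cross_family_identity_bounded_without_conservation(self):
        """With no conserved orthologs and 40% between-family divergence,
        host genes align to parasite-family references at <= 75% global
        identity (alignment oracle on sampled pairs)."""
        cfg = SimulationConfig(n_host_genes=10, n_parasite_genes=10,
                               frac_conserved_orthologs=0.0,
                               between_family_divergence=0.40,
                               frac_mobile_parasite_to_host=0.0,
                               frac_mobile_host_to_parasite=0.0,
                               mean_len_nt=500, seed=4)
        host, parasite, refs, truth = simulate_transcriptomes(cfg)
        rng = np.random.default_rng(0)
        oro = refs["orobanchaceae_like"]
        idents = []
        for _ in range(20):
            h = host[rng.integers(len(host))]
            r = oro[rng.integers(len(oro))]
            idents.append(edlib_identity(h.seq, r.seq))
        assert np.mean(idents) <= 0.75

    def test_conserved_pairs_share_within_family_identity(self):
        """Conserved orthologs are recoverable across species at roughly
        1 - within_family_divergence global identity."""
        cfg = SimulationConfig(n_host_genes=40, n_parasite_genes=40,
                               frac_conserved_orthologs=0.5,
                               within_family_divergence=0.05,
                               mean_len_nt=600, seed=5,
                               frac_mobile_parasite_to_host=0.0,
                               frac_mobile_host_to_parasite=0.0)
        host, parasite, refs, truth = simulate_transcriptomes(cfg)
        n_cons = 20
        idents = [edlib_identity(host[i].seq, parasite[i].seq) for i in range(n_cons)]
        assert min(idents) > 0.90
        # species-exclusive cross-species pairs stay near background
        bg = edlib_identity(host[30].seq, parasite[30].seq)
        assert bg < 0.75

    def test_deterministic_given_seed(self, small_sim_config):
        a = simulate_transcriptomes(small_sim_config)
        b = simulate_transcriptomes(small_sim_config)
        assert a[0] == b[0] and a[1] == b[1]
        assert a[2] == b[2]
        pd.testing.assert_frame_equal(a[3], b[3])


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(n_host_genes=80, n_parasite_genes=80, seed=6)
    *_, truth = simulate_transcriptomes(cfg)
    return cfg, truth


class TestCounts:

    def test_non_mobile_parasite_gene_absent_from_HA(self, sim):
        cfg, truth = sim
        counts = simulate_counts(truth, default_design(), cfg)
        is_para_non_mobile = (
            (truth.species_of_origin == "parasite") & (truth.mobility == "none")
        ).to_numpy()
        ha = counts.group_values("HA")
        assert ha[is_para_non_mobile].sum() == 0

    def test_dilution_one_equalizes_expected_source_and_dest(self, sim):
        _, truth = sim
        cfg = SimulationConfig(n_host_genes=80, n_parasite_genes=80, seed=6,
                               transfer_dilution=1.0)
        *_, truth1 = simulate_transcriptomes(cfg)
        mu = expected_counts(truth1, default_design(), cfg)
        mobile = truth1.mobility == "CD_to_HC"
        cd = mu.group_values("CD")[mobile.to_numpy()].mean(axis=1)
        hc = mu.group_values("HC")[mobile.to_numpy()].mean(axis=1)
        np.testing.assert_allclose(cd, hc, rtol=1e-12)

    def test_poisson_limit_mean_matches_expectation(self, sim):
        """With infinite dispersion the counts are Poisson; the mean of
        1,000 replicate draws sits within 3 SE of the expectation."""
        cfg, truth = sim
        import dataclasses
        small = truth.iloc[:25]
        design = default_design()
        mu = expected_counts(small, design, cfg).values
        acc = np.zeros_like(mu)
        n_draws = 1000
        for seed in range(n_draws):
            c = dataclasses.replace(cfg, nb_dispersion=math.inf, seed=seed)
            acc += simulate_counts(small, design, c).values
        mean = acc / n_draws
        se = np.sqrt(mu / n_draws)
        big = mu > 5
        assert np.all(np.abs(mean[big] - mu[big]) <= 3 * se[big] + 1e-9)

    def test_counts_deterministic_given_seed(self, sim):
        cfg, truth = sim
        design = default_design()
        a = simulate_counts(truth, design, cfg)
        b = simulate_counts(truth, design, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nb_overdispersion_exceeds_poisson(self, sim):
        """At finite dispersion the empirical variance across replicate
        draws exceeds the Poisson variance for high-mean transcripts."""
        cfg, truth = sim
        import dataclasses
        small = truth.iloc[:15]
        design = default_design()
        mu = expected_counts(small, design, cfg).values
        draws = np.stack([
            simulate_counts(small, design, dataclasses.replace(cfg, seed=s)).values
            for s in range(300)
        ])
        big = mu > 500
        var = draws.var(axis=0)[big]
        expect = (mu + mu ** 2 / cfg.nb_dispersion)[big]
        # within a factor band around the NB variance, far above Poisson
        assert np.all(var > 2 * mu[big])
        assert 0.5 < np.median(var / expect) < 2.0


def test_write_simulation_round_trips_through_readers(tmp_path, small_sim_config):
    from xenotraffic.io_formats import read_expression_table, read_fasta

    host, parasite, refs, truth = simulate_transcriptomes(small_sim_config)
    counts = simulate_counts(truth, default_design(), small_sim_config)
    paths = write_simulation(tmp_path, host, parasite, refs, truth, counts)
    assert read_fasta(paths["host_fasta"]) == host
    re_truth = read_truth(paths["truth"])
    assert (re_truth.mobility == truth.mobility).all()
    m = read_expression_table(paths["counts"], default_design())
    np.testing.assert_allclose(m.values, counts.values)
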