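import numpy as np
import pytest
from scipy.integrate import quad

from bgscan import dafi_stats, synthetic_data as sd
from bgscan.io_formats import AncestralSource, read_polarized_snps
from bgscan.snp_annotation import classify_mutation


class TestGenealogy:
    def test_constant_population_moments(self, rng):
        # Kingman n=4: E[T_MRCA] = 2(1-1/4) = 1.5, E[T_tot] = 2(1+1/2+1/3)
        demo = sd.constant_demography()
        tg, tt = [], []
        for _ in range(6000):
            tr = sd.simulate_genealogy({"pop0": 4}, demo, rng=rng)
            tg.append(tr.t_global)
            tt.append(tr.t_tot)
        assert np.mean(tg) == pytest.approx(1.5, rel=0.05)
        assert np.mean(tt) == pytest.approx(11 / 3, rel=0.05)

    def test_two_haploid_moments(self, rng):
        demo = sd.constant_demography()
        tg = [sd.simulate_genealogy({"pop0": 2}, demo, rng=rng).t_global
              for _ in range(4000)]
        assert np.mean(tg) == pytest.approx(1.0, rel=0.07)

    def test_multiplier_rescales_times(self, rng):
        demo = sd.constant_demography()
        tg = [sd.simulate_genealogy({"pop0": 4}, demo, ne_multiplier=0.5,
                                    rng=rng).t_global for _ in range(4000)]
        assert np.mean(tg) == pytest.approx(0.75, rel=0.07)

    def test_branch_lengths_sum_to_t_tot(self, rng):
        demo = sd.two_population_bottleneck()
        tr = sd.simulate_genealogy({"constant": 6, "bottleneck": 6}, demo,
                                   rng=rng)
        assert tr.t_tot == pytest.approx(sum(l for _, l in tr.branches))
        # every internal branch subtends a proper leaf subset
        for leaves, _ in tr.branches:
            assert 0 < len(leaves) <= tr.n_leaves

    def test_isolated_populations_error(self, rng):
        demo = sd.SharedDemography(
            (sd.PopulationModel("a"), sd.PopulationModel("b")))
        with pytest.raises(RuntimeError, match="never coalesce"):
            sd.simulate_genealogy({"a": 2, "b": 2}, demo, rng=rng)

    def test_unknown_population_errors(self, rng):
        with pytest.raises(ValueError, match="unknown population"):
            sd.simulate_genealogy({"nope": 4}, sd.constant_demography(),
                                  rng=rng)

    def test_against_msprime_oracle(self, rng):
        """Independent check of the structured coalescent: mean TMRCA and
        total length for the two-population bottleneck demography must match
        msprime (population sizes Ne = sigma/2 give our time units)."""
        msprime = pytest.importorskip("msprime")
        dem = msprime.Demography()
        dem.add_population(name="constant", initial_size=0.5)
        dem.add_population(name="bottleneck", initial_size=0.05)
        dem.add_population(name="anc", initial_size=0.5)
        dem.add_population_parameters_change(time=0.2,
                                             population="bottleneck",
                                             initial_size=0.5)
        dem.add_population_split(time=0.5,
                                 derived=["constant", "bottleneck"],
                                 ancestral="anc")
        n_rep = 1500
        ms_tg, ms_tt = [], []
        for ts in msprime.sim_ancestry(
                samples={"constant": 5, "bottleneck": 5}, demography=dem,
                ploidy=2, num_replicates=n_rep, random_seed=99):
            t = ts.first()
            ms_tg.append(t.time(t.root))
            ms_tt.append(t.total_branch_length)
        demo = sd.two_population_bottleneck()
        our_tg, our_tt = [], []
        for _ in range(n_rep):
            tr = sd.simulate_genealogy({"constant": 10, "bottleneck": 10},
                                       demo, rng=rng)
            our_tg.append(tr.t_global)
            our_tt.append(tr.t_tot)
        for ours, theirs in ((our_tg, ms_tg), (our_tt, ms_tt)):
            se = np.sqrt(np.var(ours) / n_rep + np.var(theirs) / n_rep)
            assert abs(np.mean(ours) - np.mean(theirs)) < 4 * se


class TestBiasedSpectrum:
    def test_neutral_limit(self):
        pmf = sd.wright_biased_pmf(0.0, 20)
        i = np.arange(1, 20)
        expected = (1 / i) / (1 / i).sum()
        assert np.allclose(pmf, expected)

    def test_gamma_shifts_mean_frequency(self):
        """Mean sample frequency under the discretized density brackets the
        continuous-density oracle and moves in the selection direction."""
        m = 40
        i = np.arange(1, m)
        for gamma in (4.0, -4.0):
            pmf = sd.wright_biased_pmf(gamma, m)
            mean_disc = float(np.sum(pmf * i / m))

            def dens(x, g=gamma):
                return (1 - np.exp(-g * (1 - x))) / (
                    (1 - np.exp(-g)) * x * (1 - x))
            # oracle: density integrated over each sample-frequency cell
            cells = np.array([quad(dens, (k - 0.5) / m, (k + 0.5) / m)[0]
                              for k in i])
            cells /= cells.sum()
            mean_cell = float(np.sum(cells * i / m))
            assert mean_disc == pytest.approx(mean_cell, rel=0.05)
        up = np.sum(sd.wright_biased_pmf(4.0, m) * i / m)
        zero = np.sum(sd.wright_biased_pmf(0.0, m) * i / m)
        down = np.sum(sd.wright_biased_pmf(-4.0, m) * i / m)
        assert down < zero < up


class TestDropMutations:
    def test_site_count_scales_with_theta(self, rng):
        demo = sd.constant_demography()
        counts = {}
        for theta in (1.0, 4.0):
            n = 0
            for _ in range(300):
                tr = sd.simulate_genealogy({"pop0": 8}, demo, rng=rng)
                n += len(sd.drop_mutations(tr, theta, rng=rng))
            counts[theta] = n
        assert counts[4.0] / counts[1.0] == pytest.approx(4.0, rel=0.15)

    def test_biased_classes_shift_frequencies(self, rng):
        demo = sd.constant_demography()
        freqs = {"WS": [], "SW": [], "WWSS": []}
        for _ in range(400):
            tr = sd.simulate_genealogy({"pop0": 10}, demo, rng=rng)
            for s in sd.drop_mutations(tr, 3.0, gamma=4.0, rng=rng):
                if 0 < len(s.carriers) < 20:
                    freqs[s.mclass].append(len(s.carriers) / 20)
        assert np.mean(freqs["SW"]) < np.mean(freqs["WWSS"]) \
            < np.mean(freqs["WS"])

    def test_class_labels_match_bases(self, rng):
        tr = sd.simulate_genealogy({"pop0": 6}, sd.constant_demography(),
                                   rng=rng)
        for s in sd.drop_mutations(tr, 10.0, rng=rng):
            assert s.mclass == classify_mutation(s.ancestral, s.derived)


class TestDeepRescaling:
    def test_deep_rescale_lowers_dafi(self, rng):
        """Shrinking the ancestral size must lower DAF̄ᵢ — the direction of
        the BGS emulation."""
        base = sd.two_population_bottleneck()
        means = []
        for mult in (1.0, 0.5):
            demo = base.deep_rescaled(mult)
            n_der = np.zeros(20)
            s_tot = 0
            for _ in range(1200):
                tr = sd.simulate_genealogy({"constant": 10, "bottleneck": 10},
                                           demo, rng=rng)
                for s in sd.drop_mutations(tr, 4.0, rng=rng):
                    if 0 < len(s.carriers) < 20:
                        n_der[s.carriers] += 1
                        s_tot += 1
            means.append((n_der / (2 * s_tot)).sum())
        assert means[1] < means[0]


class TestGenerateDataset:
    @pytest.fixture(scope="class")
    def small_files(self, tmp_path_factory):
        cfg = sd.SyntheticConfig(
            n_loci=60, samples={"constant": 3, "bottleneck": 3},
            theta=3.0, seed=7,
            bgs_profile=sd.ramp_profile(),
            gbgc_gamma=sd.threshold_gamma(3.0))
        out = tmp_path_factory.mktemp("synth")
        return sd.generate_dataset(cfg, out), cfg

    def test_ingestion_fidelity(self, small_files):
        paths, cfg = small_files
        ds = paths["dataset"]
        table = read_polarized_snps(
            paths["vcf"], AncestralSource(fasta_path=paths["ancestral_fasta"]),
            reference=paths["reference_fasta"])
        # nothing should be lost to any filter rule
        assert table.filter_log == {}
        assert len(table) == len(ds.positions)
        assert np.array_equal(table.dosage_matrix(), ds.dosages)

    def test_truth_alignment(self, small_files):
        paths, cfg = small_files
        ds = paths["dataset"]
        truth = ds.truth.set_index("locus")
        for pos, loc, rr in zip(ds.positions, ds.locus, ds.rr):
            row = truth.loc[loc]
            assert row["rate_cMMb"] == pytest.approx(rr)
            # site positions fall inside their locus slab
            assert loc * ds.slab < pos <= (loc + 1) * ds.slab

    def test_map_matches_truth_rates(self, small_files):
        from bgscan.io_formats import read_recombination_map
        paths, cfg = small_files
        ds = paths["dataset"]
        rmap = read_recombination_map(paths["map"])
        for pos, rr in zip(ds.positions[:50], ds.rr[:50]):
            assert rmap.rate_at("chr1", int(pos)) == pytest.approx(
                rr, rel=1e-5)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sd.SyntheticConfig(n_loci=0)
        with pytest.raises(ValueError):
            sd.SyntheticConfig(samples={"nope": 4})
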