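"""Synthetic venome generator: determinism, abundance structure, detection."""

import numpy as np
import pytest

from venomecorr import (
    ConfigurationError,
    DigestionParams,
    GeneratorConfig,
    sample_venome,
    simulate_fragment_counts,
    simulate_peptide_observations,
)


class TestGeneratorConfig:
    def test_invalid_ranges_name_the_field(self):
        with pytest.raises(ConfigurationError, match="abundance_log10_range"):
            GeneratorConfig(abundance_log10_range=(6.0, 0.0))
        with pytest.raises(ConfigurationError, match="length_range_nt"):
            GeneratorConfig(length_range_nt=(100, 99))
        with pytest.raises(ConfigurationError, match="multiples of 3"):
            GeneratorConfig(length_range_nt=(100, 301))
        with pytest.raises(ConfigurationError, match="quantile"):
            GeneratorConfig(contaminant_abundance_quantile=1.5)
        with pytest.raises(ConfigurationError, match="enzyme"):
            GeneratorConfig(enzymes=("trypsin", "papain"))


class TestSampleVenome:
    def test_empty_config_gives_empty_truth(self):
        truth = sample_venome(
            GeneratorConfig(n_transcripts=0, n_contaminants=0)
        )
        assert truth.transcripts == [] and truth.proteins == []

    def test_same_seed_identical_output(self, small_config):
        a, b = sample_venome(small_config), sample_venome(small_config)
        assert a == b

    def test_different_seed_differs(self, small_config):
        from dataclasses import replace

        other = sample_venome(replace(small_config, seed=99))
        assert other != sample_venome(small_config)

    def test_abundances_normalized_and_structured(self, small_config):
        truth = sample_venome(small_config)
        values = np.array(list(truth.transcript_abundance.values()))
        assert values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (values > 0).all()

    def test_transcripts_are_orfs_and_proteins_their_translation(
        self, small_config
    ):
        from venomecorr import six_frame_translate

        truth = sample_venome(small_config)
        by_tx = {p.source_transcript: p for p in truth.proteins
                 if not p.is_contaminant}
        for tx in truth.transcripts:
            assert tx.sequence.startswith("ATG")
            aa = six_frame_translate(tx.sequence)[1]
            assert aa.endswith("*") and "*" not in aa[:-1]
            assert by_tx[tx.id].sequence == aa[:-1]

    def test_every_biological_protein_maps_to_one_transcript(
        self, small_config
    ):
        truth = sample_venome(small_config)
        biological = [p for p in truth.proteins if not p.is_contaminant]
        assert len(biological) == len(truth.transcripts)
        assert {p.source_transcript for p in biological} == {
            t.id for t in truth.transcripts
        }

    def test_contaminants_flagged_and_low_abundance(self, small_config):
        truth = sample_venome(small_config)
        assert len(truth.contaminant_ids) == small_config.n_contaminants
        bio = [
            truth.protein_abundance[p.id]
            for p in truth.proteins
            if not p.is_contaminant
        ]
        target = np.quantile(
            bio, small_config.contaminant_abundance_quantile
        )
        for cid in truth.contaminant_ids:
            assert truth.protein_abundance[cid] == pytest.approx(target)

    def test_six_decade_span_of_raw_abundances(self):
        """Dynamic range of a 1000-transcript venome: the max/min ratio of a
        log-uniform sample over 6 decades concentrates in [1e5, 1e6]."""
        # independent Monte-Carlo oracle for the order-statistics claim
        rng = np.random.default_rng(0)
        u = rng.uniform(0, 6, size=(10_000, 1000))
        ratio = 10.0 ** (u.max(axis=1) - u.min(axis=1))
        assert np.mean((ratio >= 1e5) & (ratio <= 1e6)) > 0.99
        for seed in range(5):
            truth = sample_venome(
                GeneratorConfig(n_transcripts=1000, n_contaminants=0,
                                seed=seed)
            )
            values = np.array(list(truth.transcript_abundance.values()))
            assert 1e5 <= values.max() / values.min() <= 1e6

    def test_paralog_switch_induces_shared_peptides(self):
        from venomecorr import build_six_frame_database, match_peptides

        config = GeneratorConfig(
            n_transcripts=12,
            n_contaminants=0,
            paralog_fraction=0.6,
            paralog_identity=0.95,
            detection_noise_sigma=0.0,
            seed=3,
        )
        truth = sample_venome(config)
        obs = simulate_peptide_observations(truth)
        db = build_six_frame_database(truth.transcripts)
        matched = match_peptides(obs, db)
        assert any(o.multiplicity > 1 for o in matched)


class TestSimulateFragmentCounts:
    def test_single_transcript_gets_everything(self):
        config = GeneratorConfig(
            n_transcripts=1, n_contaminants=0, total_fragments=100, seed=1
        )
        counts = simulate_fragment_counts(sample_venome(config))
        assert counts["fragments"].tolist() == [100]

    def test_counts_sum_exactly_to_total(self, small_config):
        truth = sample_venome(small_config)
        counts = simulate_fragment_counts(truth)
        assert counts["fragments"].sum() == small_config.total_fragments

    def test_multinomial_expectation_recovers_abundance_ratio(self):
        """Transcripts at 4:1 abundance (equal length) draw fragments at 4:1."""
        ratios = []
        for seed in range(100):
            config = GeneratorConfig(
                n_transcripts=2,
                n_contaminants=0,
                total_fragments=1_000_000,
                seed=seed,
            )
            truth = sample_venome(config)
            # impose exact 4:1 abundance and equal lengths
            t0, t1 = truth.transcripts
            object.__setattr__(t1, "sequence", t0.sequence)
            object.__setattr__(t1, "length_nt", t0.length_nt)
            truth.transcript_abundance[t0.id] = 0.8
            truth.transcript_abundance[t1.id] = 0.2
            counts = simulate_fragment_counts(truth)["fragments"].to_numpy()
            ratios.append(counts[0] / counts[1])
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.01)

    def test_equal_categories_split_evenly(self):
        config = GeneratorConfig(
            n_transcripts=2, n_contaminants=0, total_fragments=1_000_000,
            seed=5,
        )
        truth = sample_venome(config)
        t0, t1 = truth.transcripts
        object.__setattr__(t1, "sequence", t0.sequence)
        object.__setattr__(t1, "length_nt", t0.length_nt)
        truth.transcript_abundance[t0.id] = 0.5
        truth.transcript_abundance[t1.id] = 0.5
        counts = simulate_fragment_counts(truth)["fragments"].to_numpy()
        sd = np.sqrt(1_000_000 * 0.25)
        assert abs(counts[0] - 500_000) < 5 * sd


class TestSimulatePeptideObservations:
    def test_zero_rate_gives_no_observations(self, small_config):
        from dataclasses import replace

        truth = sample_venome(replace(small_config, detection_rate=0.0))
        assert simulate_peptide_observations(truth) == []

    def test_enzyme_outside_config_rejected(self, small_config):
        from dataclasses import replace

        narrow = sample_venome(replace(small_config, enzymes=("trypsin",)))
        with pytest.raises(ConfigurationError, match="glu-c"):
            simulate_peptide_observations(narrow, DigestionParams("glu-c"))

    def test_determinism(self, small_config):
        truth = sample_venome(small_config)
        assert simulate_peptide_observations(
            truth
        ) == simulate_peptide_observations(truth)

    def test_flat_detection_is_poisson_with_rate_kappa(self):
        """Exponent 0, noise 0, kappa 3: every candidate expects count 3."""
        config = GeneratorConfig(
            n_transcripts=1,
            n_contaminants=0,
            length_range_nt=(300, 300),
            detection_rate=3.0,
            detection_exponent=0.0,
            detection_noise_sigma=0.0,
            enzymes=("trypsin",),
            seed=0,
        )
        means = []
        for seed in range(300):
            from dataclasses import replace

            truth = sample_venome(replace(config, seed=seed))
            obs = simulate_peptide_observations(truth)
            from venomecorr import digest, DigestionParams as DP

            protein = truth.proteins[0].sequence
            candidates = {
                p.sequence
                for p in digest(protein, DP("trypsin", 2, 6, 50))
            }
            if not candidates:
                continue
            total = sum(o.count for o in obs)
            means.append(total / len(candidates))
        grand = np.mean(means)
        se = np.std(means) / np.sqrt(len(means))
        assert abs(grand - 3.0) < 3 * max(se, 0.02)

    def test_abundance_ratio_propagates_to_counts(self):
        """Two proteins at 100:1 abundance yield ~100:1 total counts."""
        ratios = []
        for seed in range(60):
            config = GeneratorConfig(
                n_transcripts=2,
                n_contaminants=0,
                length_range_nt=(600, 600),
                detection_rate=500.0,
                detection_exponent=1.0,
                detection_noise_sigma=0.0,
                enzymes=("trypsin",),
                seed=seed,
            )
            truth = sample_venome(config)
            p0, p1 = [p for p in truth.proteins]
            truth.protein_abundance[p0.id] = 100 / 101
            truth.protein_abundance[p1.id] = 1 / 101
            obs = simulate_peptide_observations(truth)
            from venomecorr import match_peptides

            matched = match_peptides(obs, [p0, p1])
            t0 = sum(o.count for o in matched if o.matches == {p0.id})
            t1 = sum(o.count for o in matched if o.matches == {p1.id})
            if t1 > 0:
                ratios.append(t0 / t1)
        assert np.median(ratios) == pytest.approx(100, rel=0.25)

    def test_monotone_detection_in_abundance(self, small_config):
        """With noise 0 and exponent > 0, expected peptide totals increase
        with true abundance (checked via large-count realizations)."""
        from dataclasses import replace

        truth = sample_venome(
            replace(small_config, detection_rate=1e6, n_contaminants=0)
        )
        obs = simulate_peptide_observations(truth)
        from venomecorr import match_peptides

        bio = [p for p in truth.proteins]
        matched = match_peptides(obs, bio)
        totals = {p.id: 0.0 for p in bio}
        for o in matched:
            for pid in o.matches:
                totals[pid] += o.count / o.multiplicity
        order = sorted(bio, key=lambda p: truth.protein_abundance[p.id])
        per_residue = [totals[p.id] / len(p.sequence) for p in order]
        # strongly rank-correlated with abundance
        from scipy.stats import spearmanr

        rho, _ = spearmanr(
            [truth.protein_abundance[p.id] for p in order], per_residue
        )
        assert rho > 0.95
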