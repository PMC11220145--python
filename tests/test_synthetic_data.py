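"""Stutter simulator, its exact expectation model, and cohort generation."""

import hashlib

import numpy as np
import pytest

from cagmosaic import (
    AlleleStructure,
    CohortCoeffs,
    MosaicismModel,
    StutterParams,
    calibrate_p_plus,
    expected_measured_ratios,
    expected_pool_distribution,
    load_scenario,
    simulate_cohort,
    simulate_molecule_pcr,
    simulate_tissue_reads,
    solve_template_freqs,
)
from cagmosaic.pipeline import genotype_reads
from cagmosaic.mosaicism import compute_expansion_ratio
from cagmosaic.synthetic_data import scenario_tissue_readsets, simulate_pcr_pool


class TestStutterParams:
    @pytest.mark.parametrize("kwargs", [
        {"p_minus": -0.1}, {"p_plus": -0.1}, {"p_minus": 0.6, "p_plus": 0.5},
        {"cycles": 0}, {"length_scaling": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StutterParams(**kwargs)

    def test_calibrated_default_reproduces_benchmark(self, calibrated_params):
        """The stored p_plus solves the +1/inherited = 0.023 single-molecule
        benchmark for a 33 CAG template under the exact expectation model."""
        ratios = expected_measured_ratios({33: 1.0}, 33, calibrated_params,
                                          error_rate=0.001)
        assert ratios[1] == pytest.approx(0.023, abs=1e-6)
        assert calibrate_p_plus() == pytest.approx(calibrated_params.p_plus, rel=1e-6)


class TestMoleculePcr:
    def test_no_slip_limit_all_reads_inherited(self, no_stutter):
        readset = simulate_molecule_pcr(AlleleStructure(cag=33), no_stutter,
                                        n_reads=500, seed=1, error_rate=0.0)
        assert readset.length_counts == {("canonical", 33): 500}
        assert readset.truth.read_origin_counts == {(33, 0): 500}

    def test_small_rate_closed_form(self):
        """With backward slips off, the expected fraction of molecules with a
        forward slip is exactly 1 - (1 - p_plus/2)^cycles (a random final
        molecule has Binomial(cycles, 1/2) copy events in its lineage);
        Monte-Carlo mean within 10%."""
        params = StutterParams(p_minus=0.0, p_plus=1e-4, cycles=30,
                               length_scaling=1.0)
        closed_form = 1.0 - (1.0 - params.p_plus / 2.0) ** params.cycles
        fracs = []
        for seed in range(400):
            pool = simulate_pcr_pool({33: 1}, params, np.random.default_rng(seed))
            total = sum(pool.values())
            plus = sum(c for (_, cur), c in pool.items() if cur > 33)
            fracs.append(plus / total)
        assert np.mean(fracs) == pytest.approx(closed_form, rel=0.10)

    def test_pool_matches_exact_expectation(self, calibrated_params):
        """Stochastic branching from a large template pool agrees with the
        linear expectation model on the dominant length classes."""
        n0 = 200_000
        pool = simulate_pcr_pool({33: n0}, calibrated_params,
                                 np.random.default_rng(42))
        total = sum(pool.values())
        sim = {cur: c / total for (_, cur), c in sorted(pool.items())}
        exact = expected_pool_distribution({33: 1.0}, calibrated_params)
        for cag in (31, 32, 33, 34):
            assert sim[cag] == pytest.approx(exact[cag], rel=0.02)

    def test_single_molecule_benchmark_over_seeds(self, calibrated_params):
        """50k-read single-molecule runs over 10 seeds: the mean +1/inherited
        read proportion is consistent with 2.3% (within 3 empirical SE; a
        single-molecule reaction is intrinsically high-variance because an
        early-cycle slip amplifies through the remaining cycles)."""
        props = []
        for seed in range(10):
            readset = simulate_molecule_pcr(AlleleStructure(cag=33),
                                            calibrated_params,
                                            n_reads=50_000, seed=seed)
            gt = genotype_reads(readset.reads)
            profile = compute_expansion_ratio(gt.histogram_by_structure,
                                              gt.allele_long)
            props.append(profile.n_plus[0] / profile.n)
        props = np.array(props)
        se = props.std(ddof=1) / np.sqrt(len(props))
        assert abs(props.mean() - 0.023) < 3 * se


class TestTissueReads:
    def test_determinism_same_seed_same_bytes(self, calibrated_params, tmp_path):
        kwargs = dict(
            inherited=(AlleleStructure(cag=18), AlleleStructure(cag=33)),
            mosaicism=MosaicismModel({1: 0.06, 2: 0.01}),
            params=calibrated_params, depth=2000, n_templates=20_000,
        )
        a = simulate_tissue_reads(seed=9, **kwargs)
        b = simulate_tissue_reads(seed=9, **kwargs)
        c = simulate_tissue_reads(seed=10, **kwargs)
        assert a.reads == b.reads
        pa, pb, pc = tmp_path / "a.fastq", tmp_path / "b.fastq", tmp_path / "c.fastq"
        a.write_fastq(pa); b.write_fastq(pb); c.write_fastq(pc)
        ha, hb, hc = (hashlib.sha256(p.read_bytes()).hexdigest() for p in (pa, pb, pc))
        assert ha == hb
        assert ha != hc

    def test_truth_reconciles_with_emitted_reads(self, calibrated_params):
        readset = simulate_tissue_reads(
            (AlleleStructure(cag=18), AlleleStructure(cag=33)),
            MosaicismModel({1: 0.05}), calibrated_params, depth=1500, seed=4,
            n_templates=20_000)
        assert readset.truth.n_reads() == len(readset.reads) == 1500
        assert sum(readset.length_counts.values()) == 1500

    def test_low_depth_refused(self, calibrated_params):
        with pytest.raises(ValueError, match="depth"):
            simulate_tissue_reads(
                (AlleleStructure(cag=18), AlleleStructure(cag=33)),
                MosaicismModel({}), calibrated_params, depth=50, seed=1)

    def test_invalid_mosaicism_rejected(self):
        with pytest.raises(ValueError):
            MosaicismModel({1: 0.8, 2: 0.4})
        with pytest.raises(ValueError):
            MosaicismModel({11: 0.1})

    def test_putamen_like_recovery(self, calibrated_params):
        """Pipeline-recovered ratio for a putamen-like configuration matches
        the target measured ratio within 3 SE over seeded replicates."""
        scenario = load_scenario("family-A-ten-tissues")
        target = sum(scenario["tissues"]["putamen"]["measured_ratios"].values())
        freqs = solve_template_freqs(
            {int(k): v for k, v in
             scenario["tissues"]["putamen"]["measured_ratios"].items()},
            33, calibrated_params)
        ratios = []
        for seed in range(8):
            readset = simulate_tissue_reads(
                (AlleleStructure(cag=18), AlleleStructure(cag=33)),
                MosaicismModel(freqs), calibrated_params,
                depth=20_000, seed=seed)
            gt = genotype_reads(readset.reads)
            ratios.append(compute_expansion_ratio(
                gt.histogram_by_structure, gt.allele_long).ratio)
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - target) < 3 * se

    def test_putamen_vs_cerebellum_fold_changes(self, calibrated_params):
        """+1 and +2 expansion frequencies are ~2-fold and ~5-fold higher in
        the putamen-like than the cerebellum-like configuration."""
        from cagmosaic import tissue_fold_change
        scenario = load_scenario("family-A-ten-tissues")
        profiles = {}
        for tissue in ("putamen", "cerebellum"):
            sub = dict(scenario)
            sub["tissues"] = {tissue: scenario["tissues"][tissue]}
            counts = np.zeros(11, dtype=int)
            for seed in range(1, 9):
                rs = scenario_tissue_readsets(sub, seed=seed)[tissue]
                gt = genotype_reads(rs.reads)
                p = compute_expansion_ratio(gt.histogram_by_structure,
                                            gt.allele_long)
                counts[0] += p.n
                counts[1:] += np.array(p.n_plus)
            from cagmosaic.mosaicism import ExpansionProfile
            profiles[tissue] = ExpansionProfile(
                inherited_cag=33, n=int(counts[0]), n_plus=tuple(counts[1:]))
        fold1 = tissue_fold_change(profiles["putamen"], profiles["cerebellum"], 1)
        fold2 = tissue_fold_change(profiles["putamen"], profiles["cerebellum"], 2)
        assert fold1 == pytest.approx(2.0, rel=0.2)
        assert fold2 == pytest.approx(5.0, rel=0.3)


class TestSolveTemplateFreqs:
    def test_inversion_reproduces_targets(self, calibrated_params):
        targets = {1: 0.0913333333, 2: 0.0116666667}
        freqs = solve_template_freqs(targets, 33, calibrated_params)
        weights = {33: 1.0 - sum(freqs.values())}
        for i, f in freqs.items():
            weights[33 + i] = f
        got = expected_measured_ratios(weights, 33, calibrated_params)
        assert got[1] == pytest.approx(targets[1], rel=1e-4)
        assert got[2] == pytest.approx(targets[2], rel=1e-4)

    def test_sub_baseline_target_unreachable(self, calibrated_params):
        # a measured +1 ratio below the pure-stutter floor needs no mosaicism
        freqs = solve_template_freqs({1: 0.001}, 33, calibrated_params)
        assert freqs.get(1, 0.0) == 0.0


class TestSimulateCohort:
    def test_noise_free_records_on_plane(self):
        coeffs = CohortCoeffs(intercept=-0.074, beta_cag=0.004, beta_age=0.0001)
        table, truth = simulate_cohort("intermediate", 50, coeffs, (27, 35),
                                       seed=2)
        expected = (coeffs.intercept
                    + coeffs.beta_cag * table["inherited_cag"]
                    + coeffs.beta_age * table["age_at_sampling"])
        # ages are rounded for the table; recompute from the stored truth
        assert np.allclose(table["ratio"], truth["expected_ratio"], atol=1e-12)
        assert np.allclose(table["ratio"], expected, atol=1e-5)

    def test_ratios_truncated_at_zero(self):
        coeffs = CohortCoeffs(intercept=-1.0, beta_cag=0.0, beta_age=0.0,
                              noise_sd=0.5)
        table, _ = simulate_cohort("normal", 200, coeffs, (10, 26), seed=3)
        assert (table["ratio"] >= 0).all()
        assert (table["ratio"] == 0).any()

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            CohortCoeffs(intercept=0, beta_cag=0, beta_age=0, noise_sd=-1)

    def test_determinism(self):
        coeffs = CohortCoeffs(intercept=-0.074, beta_cag=0.004, beta_age=0.0001,
                              noise_sd=0.0065)
        a, _ = simulate_cohort("intermediate", 135, coeffs, (27, 35), seed=77)
        b, _ = simulate_cohort("intermediate", 135, coeffs, (27, 35), seed=77)
        assert a.equals(b)


class TestFullChainCoefficientRecovery:
    @pytest.mark.parametrize("scenario_name,category,mode", [
        ("Normal-cohort-47", "normal", "table1"),
        ("IA-cohort-135", "intermediate", "table1"),
        ("RP-cohort-37", "reduced_penetrance", "table1"),
        ("FP-cohort-88", "full_penetrance", "results_text"),
    ])
    def test_simulate_genotype_ratio_regress_chain(self, scenario_name,
                                                   category, mode,
                                                   calibrated_params):
        """Read-level chain: per-sample target ratios from the cohort model
        are inverted to template pools, reads simulated, the pipeline
        genotypes and measures each sample, and the refitted CAG slope
        recovers the generating coefficient (|bias| < 10% of the coefficient
        plus Monte-Carlo allowance)."""
        from cagmosaic.cohort_models import fit_category_regression
        from cagmosaic.repeat_genotyper import LocusConfig
        import pandas as pd
        # wider shoulder absorption: highly mosaic alleles carry an
        # expansion smear whose sampling noise would otherwise fake peaks
        locus = LocusConfig(stutter_absorb_window=4)
        spec = load_scenario(scenario_name)
        coeffs = CohortCoeffs(**spec["coeffs"])
        n = min(spec["n_samples"], 60)  # chain run at reduced cohort size
        estimates = []
        for rep in range(3):
            table, _ = simulate_cohort(category, n, coeffs,
                                       tuple(spec["cag_range"]),
                                       seed=400_000 + rep)
            rows = []
            for _, rec in table.iterrows():
                target = float(rec["ratio"])
                cag = int(rec["inherited_cag"])
                # distribute the excess over the stutter baseline across
                # +1..+10 (geometric, expansion-biased) before inverting; a
                # single dominant offset would let highly unstable alleles
                # outnumber their inherited reads
                stutter_only = expected_measured_ratios(
                    {cag: 1.0}, cag, calibrated_params)
                excess = max(target - sum(stutter_only.values()), 0.0)
                w = 0.85 ** np.arange(1, 11)
                w /= w.sum()
                offset_targets = {
                    i: stutter_only[i] + excess * w[i - 1] for i in range(1, 11)}
                freqs = solve_template_freqs(offset_targets, cag,
                                             calibrated_params)
                rs = simulate_tissue_reads(
                    (AlleleStructure(cag=max(cag - 16, 5)),
                     AlleleStructure(cag=cag)),
                    MosaicismModel(freqs), calibrated_params,
                    depth=3000, seed=int(rec.name) + rep * 1000,
                    n_templates=50_000)
                gt = genotype_reads(rs.reads, locus)
                profile = compute_expansion_ratio(gt.histogram_by_structure,
                                                  gt.allele_long)
                rows.append({"sample_id": rec["sample_id"],
                             "inherited_cag": cag,
                             "age_at_sampling": rec["age_at_sampling"],
                             "group": "x", "ratio": profile.ratio})
            fit = fit_category_regression(pd.DataFrame(rows), category,
                                          mode=mode, min_records=10)
            estimates.append(fit.beta_cag)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - coeffs.beta_cag) < 0.1 * abs(coeffs.beta_cag) + 2.5 * se
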