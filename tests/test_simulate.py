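"""Synthetic-data generators: Wright-Fisher, sediment counts, damage."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from paleospruce.fixtures import load_table1_fixture
from paleospruce.haplotypes import collapse_haplotypes
from paleospruce.par import detect_events, smooth_par
from paleospruce.popgen import haplotype_diversity
from paleospruce.simulate import (
    SimulationConfig,
    apply_damage,
    generate_narrative_scenario,
    narrative_age_depth_model,
    narrative_par_trajectory,
    recover_par,
    simulate_sediment_record,
    simulate_wright_fisher,
    trajectory_from_par,
)


def _distinct_founders(n):
    base = load_table1_fixture().extant_records[0].bases
    founders = []
    for i in range(n):
        pos = 700 + i  # inside the TL fragment of the concatenated frame
        repl = "A" if base[pos] != "A" else "C"
        founders.append(base[:pos] + repl + base[pos + 1 :])
    return founders


def _pop_heterozygosity(records):
    counts = Counter(r.bases for r in records)
    n = sum(counts.values())
    return 1 - sum((c / n) ** 2 for c in counts.values())


class TestWrightFisher:
    def test_no_mutation_single_founder_is_monomorphic(self):
        cfg = SimulationConfig(trajectory=np.full(30, 20), mu_snp=0, mu_ms=0, seed=1)
        out = simulate_wright_fisher(
            cfg, [29], [10], founders=_distinct_founders(1)
        )
        for recs in out[29].values():
            assert len({r.bases for r in recs}) == 1
        table = collapse_haplotypes(
            out[29]["TL"], positions=range(1, 252)
        )
        assert table.n_haplotypes == 1
        assert haplotype_diversity(table.counts) == 0.0

    def test_sample_larger_than_population_is_error(self):
        cfg = SimulationConfig(trajectory=np.full(5, 10), seed=1)
        with pytest.raises(ValueError, match="exceeds population size"):
            simulate_wright_fisher(cfg, [4], [11])

    def test_population_size_floor_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(trajectory=np.array([10, 1, 10]))

    def test_seed_reproducibility_bitwise(self):
        cfg = dict(trajectory=np.full(40, 25), mu_snp=1e-4, mu_ms=0.01)
        a = simulate_wright_fisher(SimulationConfig(seed=9, **cfg), [39], [12])
        b = simulate_wright_fisher(SimulationConfig(seed=9, **cfg), [39], [12])
        for locus in a[39]:
            assert [r.bases for r in a[39][locus]] == [r.bases for r in b[39][locus]]

    def test_heterozygosity_decay_matches_drift_expectation(self):
        # neutral drift: E[H_t] = H_0 (1 - 1/N)^t; Monte-Carlo mean over
        # replicates within 3 standard errors of the closed form
        N, T, reps = 30, 20, 200
        founders = _distinct_founders(N)
        hets = []
        for rep in range(reps):
            cfg = SimulationConfig(
                trajectory=np.full(T + 1, N), mu_snp=0, mu_ms=0, seed=rep
            )
            out = simulate_wright_fisher(cfg, [T], [N], founders=founders)
            hets.append(_pop_heterozygosity(out[T]["TL"]))
        h0 = 1 - 1 / N
        expected = h0 * (1 - 1 / N) ** T
        se = np.std(hets, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(hets) - expected) < 3 * se

    def test_crash_reduces_diversity(self):
        # a 10-fold crash lowers expected haplotype diversity afterwards
        pre, post = [], []
        traj = np.concatenate([np.full(31, 50), np.full(20, 5)])
        for rep in range(40):
            cfg = SimulationConfig(trajectory=traj, mu_snp=0, mu_ms=0, seed=1000 + rep)
            out = simulate_wright_fisher(
                cfg, [30, 50], [20, 5], founders=_distinct_founders(25)
            )
            pre.append(_pop_heterozygosity(out[30]["TL"]))
            post.append(_pop_heterozygosity(out[50]["TL"]))
        from scipy import stats

        t = stats.ttest_rel(pre, post, alternative="greater")
        assert t.pvalue < 0.01

    def test_mutation_produces_variation(self):
        cfg = SimulationConfig(
            trajectory=np.full(60, 40), mu_snp=5e-4, mu_ms=0.05, seed=4
        )
        out = simulate_wright_fisher(cfg, [59], [40], founders=_distinct_founders(1))
        all_bases = {r.bases for recs in out[59].values() for r in recs}
        assert len(all_bases) > 8  # several mutant haplotypes segregate

    def test_ancient_and_extant_share_aligned_frame(self):
        cfg = SimulationConfig(trajectory=np.full(30, 20), mu_ms=0.05, seed=2)
        out = simulate_wright_fisher(cfg, [10, 29], [8, 8])
        for locus in out[10]:
            lens = {len(r.bases) for r in out[10][locus] + out[29][locus]}
            assert len(lens) == 1
        assert all(r.population == "ancient" for r in out[10]["B"])
        assert all(r.population == "extant" for r in out[29]["B"])


class TestSedimentRecord:
    def test_high_effort_recovers_truth_closely(self):
        truth = narrative_par_trajectory(age_step=500)
        model = narrative_age_depth_model()
        counts = simulate_sediment_record(truth, model, counting_effort=1e6, seed=0)
        rec = recover_par(counts, model).sort_values(
            "age_calBP", ascending=False, ignore_index=True
        )
        rel = np.abs(rec["par"].to_numpy() - truth["par"].to_numpy()) / np.maximum(
            truth["par"].to_numpy(), 1e-9
        )
        assert rel.max() < 0.01

    def test_zero_par_gives_zero_counts(self):
        model = narrative_age_depth_model()
        truth = pd.DataFrame(
            {"age_calBP": [10_000, 9_000], "depth_cm": [490.0, 470.0], "par": [0.0, 0.0]}
        )
        counts = simulate_sediment_record(truth, model, seed=1)
        assert (counts["pollen_count"] == 0).all()

    def test_nonpositive_effort_is_error(self):
        truth = narrative_par_trajectory(age_step=1000)
        with pytest.raises(ValueError):
            simulate_sediment_record(truth, narrative_age_depth_model(), counting_effort=0)

    def test_roundtrip_bias_below_two_percent(self):
        # Monte-Carlo over replicates at a realistic counting effort
        truth = narrative_par_trajectory(age_step=200)
        model = narrative_age_depth_model()
        true_vals = truth["par"].to_numpy()
        ratios = []
        for rep in range(60):
            counts = simulate_sediment_record(truth, model, seed=rep)
            rec = recover_par(counts, model).sort_values(
                "age_calBP", ascending=False, ignore_index=True
            )
            ratios.append(rec["par"].to_numpy() / true_vals)
        bias = np.mean(ratios) - 1
        assert abs(bias) < 0.02


class TestDamageInjection:
    def test_delta_zero_is_identity(self, table1):
        recs = table1.ancient_by_locus["TL"]
        damaged, ledger = apply_damage(recs, 0.0, seed=1)
        assert [r.bases for r in damaged] == [r.bases for r in recs]
        assert len(ledger) == 0

    def test_delta_one_converts_every_c_and_g(self, table1):
        recs = table1.ancient_by_locus["D"][:2]
        damaged, ledger = apply_damage(recs, 1.0, seed=1)
        for rec in damaged:
            assert "C" not in rec.bases and "G" not in rec.bases
        assert len(ledger) == sum(
            r.bases.count("C") + r.bases.count("G") for r in recs
        )
        with pytest.raises(ValueError):
            apply_damage(recs, 1.5)

    def test_lesion_count_within_binomial_interval(self, table1):
        recs = table1.extant_by_locus["TL"]
        delta = 0.05
        n_cg = sum(r.bases.count("C") + r.bases.count("G") for r in recs)
        _, ledger = apply_damage(recs, delta, seed=11)
        mean = delta * n_cg
        sd = np.sqrt(n_cg * delta * (1 - delta))
        assert abs(len(ledger) - mean) < 4 * sd


class TestNarrativeScenario:
    def test_same_seed_is_byte_identical(self):
        a = generate_narrative_scenario(seed=5)
        b = generate_narrative_scenario(seed=5)
        assert a.counts.equals(b.counts)
        for gen in a.samples:
            for locus in a.samples[gen]:
                assert [r.bases for r in a.samples[gen][locus]] == [
                    r.bases for r in b.samples[gen][locus]
                ]

    def test_three_bottlenecks_recovered(self):
        sc = generate_narrative_scenario(seed=8)
        series = smooth_par(recover_par(sc.counts, sc.age_depth))
        events = detect_events(series)
        bottlenecks = [e for e in events if e.kind == "bottleneck"]
        assert len(bottlenecks) == 3
        for got, want in zip(
            (e.start_age for e in bottlenecks), sc.true_bottleneck_onsets
        ):
            assert abs(got - want) <= 400

    def test_population_trajectory_spans_expected_range(self):
        sc = generate_narrative_scenario(seed=0)
        traj = sc.config.trajectory
        # ancient population roughly 1/10 - 1/5 of the extant one
        ancient_n = traj[int(round((15_700 - 11_000) / 25))]
        extant_n = traj[-1]
        assert 0.05 <= ancient_n / extant_n <= 0.6
        assert traj.min() >= 2

    def test_scenario_writes_text_outputs(self, tmp_path):
        generate_narrative_scenario(seed=1, outdir=tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert {
            "par_truth.csv", "pollen_counts.csv", "age_depth.csv", "extant.fasta",
        } <= names


def test_trajectory_from_par_is_monotone_in_par():
    par = np.array([100.0, 500.0, 2000.0])
    n = trajectory_from_par(par)
    assert np.all(np.diff(n) > 0)
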