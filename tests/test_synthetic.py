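"""The synthetic study generator: determinism, calibration, ground truth."""

import numpy as np
import pandas as pd
import pytest

from agonet import hierarchy
from agonet.centrality import centrality_table, degree_centralities
from agonet.ingest import build_pen_network
from agonet.synthetic import (
    SimConfig,
    simulate_pen,
    simulate_study,
    with_effects,
    write_study,
)


SMALL = SimConfig(pen_sizes=(11,) * 3 + (12,) * 2)


class TestConfig:
    def test_probability_validation(self):
        with pytest.raises(ValueError):
            SimConfig(behaviour_type_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SimConfig(isolation_prob=1.5)

    def test_infeasible_correlation_names_pair(self):
        with pytest.raises(ValueError, match="FR"):
            SimConfig(trait_effects={"FR": 1.3})

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError, match="unknown trait"):
            SimConfig(trait_effects={"XYZ": 0.1})

    def test_attack_rate_calibration_identity(self):
        cfg = SimConfig()
        dyads = sum(n * (n - 1) for n in cfg.pen_sizes)
        expect = cfg.target_total_events / (
            dyads * (1 - cfg.isolation_prob) ** 2
            * np.exp(cfg.dominance_effect**2)
        )
        assert cfg.attack_rate == pytest.approx(expect)


class TestDeterminism:
    def test_same_seed_identical_study(self):
        a = simulate_study(SMALL, seed=5)
        b = simulate_study(SMALL, seed=5)
        assert a.records == b.records
        pd.testing.assert_frame_equal(a.feeder, b.feeder)
        pd.testing.assert_frame_equal(a.weights, b.weights)
        pd.testing.assert_frame_equal(a.latent, b.latent)

    def test_different_seeds_differ(self):
        a = simulate_study(SMALL, seed=5)
        b = simulate_study(SMALL, seed=6)
        assert a.records != b.records

    def test_written_files_reproducible(self, tmp_path):
        paths_a = write_study(simulate_study(SMALL, seed=2), tmp_path / "a")
        paths_b = write_study(simulate_study(SMALL, seed=2), tmp_path / "b")
        for name in paths_a:
            assert paths_a[name].read_bytes() == paths_b[name].read_bytes()

    def test_pen_substreams_independent_of_other_pens(self):
        # pen 0 is identical whether or not other pens exist (lambda fixed:
        # the auto-calibrated rate legitimately depends on the study size)
        small = SimConfig(pen_sizes=(11,), base_attack_rate=0.2)
        big = SimConfig(pen_sizes=(11, 12, 13), base_attack_rate=0.2)
        _, recs_small, _ = simulate_pen(small, 7, 0)
        _, recs_big, _ = simulate_pen(big, 7, 0)
        assert recs_small == recs_big


class TestEventModel:
    def test_full_isolation_degenerate(self):
        study = simulate_study(
            SimConfig(pen_sizes=(10, 10), isolation_prob=1.0), seed=0
        )
        assert not study.records
        ranks = []
        for net in study.networks():
            ranks += hierarchy.classify_pen(centrality_table(net))
        assert all(r.category == hierarchy.ISOLATED for r in ranks)

    def test_behaviour_mix_recovered_at_scale(self):
        cfg = SimConfig(
            pen_sizes=(15,) * 8, isolation_prob=0.0, dominance_effect=0.0,
            base_attack_rate=6.0,
        )
        study = simulate_study(cfg, seed=1)
        assert len(study.records) > 8000
        counts = pd.Series([r.behaviour for r in study.records]).value_counts(
            normalize=True
        )
        for prob, name in zip(cfg.behaviour_type_probs,
                              ("head_knock", "bite", "fight", "chase")):
            assert counts.get(name, 0.0) == pytest.approx(prob, abs=0.02)

    def test_default_scale_near_calibration_target(self):
        totals = [len(simulate_study(seed=s).records) for s in range(5)]
        assert 400 <= np.mean(totals) <= 700  # expectation calibrated to 551

    def test_symmetric_attacks_when_no_dominance_effect(self):
        """alpha = 0 removes the out/in asymmetry that dominance creates."""
        def pooled_corr(alpha, seed):
            cfg = SimConfig(pen_sizes=(12,) * 6, dominance_effect=alpha,
                            base_attack_rate=0.3, isolation_prob=0.1)
            outs, ins = [], []
            for pen_index in range(6):
                roster, recs, _ = simulate_pen(cfg, seed, pen_index)
                net = build_pen_network(recs, roster)
                in_d, out_d, _ = degree_centralities(net)
                outs += [out_d[a] for a in net.nodes]
                ins += [in_d[a] for a in net.nodes]
            return np.corrcoef(outs, ins)[0, 1]

        sym = np.mean([pooled_corr(0.0, s) for s in range(6)])
        skew = np.mean([pooled_corr(2.0, s) for s in range(6)])
        assert sym > skew

    def test_dominance_recovery_improves_with_effect_size(self):
        """Sensitivity for latent top-quartile animals rises with alpha."""
        def sensitivity(alpha, seeds):
            hits = totals = 0
            cfg = SimConfig(dominance_effect=alpha)
            for seed in seeds:
                hits_, totals_ = _top_quartile_hits(_events_only(cfg, seed))
                hits += hits_
                totals += totals_
            return hits / totals

        def _events_only(cfg, seed):
            rosters, records, latents = [], [], []
            for pen_index in range(len(cfg.pen_sizes)):
                r, recs, lat = simulate_pen(cfg, seed, pen_index)
                rosters.append(r)
                records.extend(recs)
                latents.append(lat)
            return rosters, records, pd.concat(latents, ignore_index=True)

        def _top_quartile_hits(study):
            rosters, records, latent = study
            by_pen = {r.pen_id: [] for r in rosters}
            for rec in records:
                by_pen[rec.pen_id].append(rec)
            hits = totals = 0
            cut = latent["dominance"].quantile(0.75)
            si_by_animal = {}
            for roster in rosters:
                net = build_pen_network(by_pen[roster.pen_id], roster)
                for r in hierarchy.classify_pen(centrality_table(net)):
                    si_by_animal[r.animal_id] = r
            for _, row in latent.iterrows():
                if row["dominance"] < cut:
                    continue
                rank = si_by_animal[row["animal_id"]]
                if rank.si is None:
                    continue  # never interacted: SI undefined
                totals += 1
                hits += rank.category == hierarchy.DOMINANT
            return hits, totals

        seeds = range(8)
        sens = [sensitivity(a, seeds) for a in (0.0, 1.0, 2.0, 3.0)]
        assert all(b > a for a, b in zip(sens, sens[1:]))


class TestTraitCoupling:
    def test_null_effects_give_null_correlations(self):
        cfg = with_effects(SimConfig(), FR=0.0, OT=0.0, FF=0.0, FInt=0.0,
                           ADG=0.0, BF=0.0)
        study = simulate_study(cfg, seed=3)
        out_deg = {}
        for net in study.networks():
            _, out, _ = degree_centralities(net)
            out_deg.update(out)
        from agonet.traits import trait_table
        from agonet.association import spearman

        table = trait_table(study.weights, study.backfat, study.feeder)
        out_series = pd.Series(out_deg).loc[table.index]
        for trait in ("FR", "OT", "FF", "ADG", "BF"):
            rho = spearman(out_series, table[trait]).rho
            assert abs(rho) < 0.12

    def test_trait_targets_use_configured_marginals(self):
        study = simulate_study(SMALL, seed=4)
        t = study.trait_targets
        assert t["FR"].mean() == pytest.approx(40.6, abs=3.0)
        assert t["OT"].mean() == pytest.approx(59.5, abs=3.5)
        assert t["ADG"].mean() == pytest.approx(0.81, abs=0.05)

    def test_derived_traits_track_targets(self):
        """The logs round-trip: derived traits sit close to planted targets."""
        from agonet.traits import trait_table

        study = simulate_study(SMALL, seed=8)
        table = trait_table(study.weights, study.backfat, study.feeder)
        joined = table.join(study.trait_targets, rsuffix="_target")
        for trait, tol in (("FR", 0.05), ("OT", 0.05), ("FF", 0.10)):
            rel = (joined[trait] - joined[f"{trait}_target"]).abs() / joined[
                f"{trait}_target"
            ]
            assert rel.median() < tol


def test_study_shape_defaults():
    study = simulate_study(seed=0)
    assert len(study.rosters) == 29
    assert len(study.latent) == 326
    sizes = sorted(r.pen_id for r in study.rosters if len(r.animals) == 11)
    assert len(sizes) == 11  # the 11-animal comparison group
    assert sum(1 for r in study.rosters if len(r.animals) == 12) == 8
    assert {r.session_id for r in study.records} <= {
        f"s{k}" for k in range(1, 7)
    }
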