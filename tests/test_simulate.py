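"""Forward-simulator behaviour: founder, propagation, seedlings, observation."""

import numpy as np
import pytest

import clonehet as ch
from clonehet import genotypes as gt
from clonehet.simulate import (
    CloneNode,
    CloneTree,
    HET_GAIN,
    SimConfig,
    apply_observation_model,
    generate_founder,
    propagate_clones,
    simulate_selfed_seedlings,
)


def two_node_tree(years: float) -> CloneTree:
    return CloneTree([CloneNode("root", None, 0.0), CloneNode("clone", "root", years)])


class TestFounder:
    def test_no_divergence_means_homozygous_founder(self):
        cfg = SimConfig(genome_length=50_000, divergence_density=0.0, seed=1)
        truth = generate_founder(cfg)
        assert len(truth.div_positions) == 0
        assert len(truth.founder_het_positions()) == 0

    def test_f1_heterozygous_everywhere(self):
        cfg = SimConfig(genome_length=50_000, founder_selfings=0, seed=2)
        truth = generate_founder(cfg)
        assert len(truth.div_positions) > 0
        assert len(truth.founder_het_positions()) == len(truth.div_positions)

    def test_selfed_het_fraction_matches_closed_form(self):
        """After g0 selfings a fraction (1/2)^g0 of divergent sites stays
        heterozygous (checked against gamete enumeration in the
        inheritance tests); here the simulator must reproduce it."""
        g0 = 2
        fracs, total = [], 0
        for seed in range(30):
            cfg = SimConfig(genome_length=50_000, founder_selfings=g0, seed=seed)
            truth = generate_founder(cfg)
            total += len(truth.div_positions)
            fracs.append(len(truth.founder_het_positions()) / len(truth.div_positions))
        p = 0.5**g0
        # block structure correlates sites within a replicate, so the
        # replicate-to-replicate spread is the honest scale
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - p) <= 4 * se

    def test_het_sites_form_blocks(self):
        cfg = SimConfig(genome_length=200_000, seed=3)
        truth = generate_founder(cfg)
        het = set(truth.founder_het_positions().tolist())
        runs = 1
        states = [int(p in het) for p in truth.div_positions.tolist()]
        runs += sum(a != b for a, b in zip(states, states[1:]))
        # with ~4 expected crossovers per selfing round, far fewer runs
        # than sites means contiguous blocks
        assert runs < len(states) / 5

    def test_tiny_expected_divergence_warns(self):
        with pytest.warns(UserWarning, match="divergent"):
            generate_founder(SimConfig(genome_length=100, divergence_density=1e-3, seed=4))

    def test_reproducible(self):
        cfg = SimConfig(genome_length=50_000, seed=9)
        a, b = generate_founder(cfg), generate_founder(cfg)
        assert np.array_equal(a.div_positions, b.div_positions)
        assert np.array_equal(a.founder_haps, b.founder_haps)


class TestPropagation:
    def test_no_mutation_no_conversion_leaves_equal_founder(self):
        cfg = SimConfig(genome_length=50_000, somatic_rate=0.0,
                        conversion_rate=0.0, seed=5)
        tree = CloneTree.caterpillar(list("ABCD"), 100.0)
        truth = propagate_clones(generate_founder(cfg), tree, cfg)
        assert truth.events == []
        founder_state = {
            int(p): str(gt.NAMES[c])
            for p, c in zip(truth.div_positions, truth.founder_class_codes())
            if gt.NAMES[c] != gt.REF
        }
        for leaf in tree.leaves():
            assert truth.clone_classes[leaf] == founder_state

    def test_poisson_mean_events_per_branch(self):
        """mu*L*t = 3 expected gains per branch, within 3 Poisson SE."""
        mu, L, t = 1e-9, 1e7, 300.0
        counts = []
        for seed in range(60):
            cfg = SimConfig(genome_length=int(L), divergence_density=1e-5,
                            somatic_rate=mu, conversion_rate=0.0, seed=seed)
            truth = propagate_clones(generate_founder(cfg), two_node_tree(t), cfg)
            counts.append(sum(e.kind == HET_GAIN for e in truth.events))
        mean = mu * L * t
        se = np.sqrt(mean / len(counts))
        assert abs(np.mean(counts) - mean) <= 3 * se

    def test_clade_sharing(self, caterpillar_truth):
        """Somatic HET sites are shared by exactly the clade of the branch
        they arose on — the signal the intersection method detects."""
        _, tree, truth = caterpillar_truth
        for ev in truth.events:
            if ev.kind != HET_GAIN:
                continue
            clade = truth.event_leafset(ev)
            carriers = {
                leaf
                for leaf, state in truth.clone_classes.items()
                if state.get(ev.pos) in (gt.HET, gt.ALT)
            }
            assert carriers == clade

    def test_replay_reconstructs_leaves(self, caterpillar_truth):
        """Leaf genotypes equal an independent replay of the event log,
        and HET counts obey founder + gains - conversions."""
        _, tree, truth = caterpillar_truth
        founder_het = len(truth.founder_het_positions())
        for leaf in tree.leaves():
            assert truth.replay_leaf(leaf) == truth.clone_classes[leaf]
            path = set(truth.tree.path(leaf))
            gains = sum(
                e.kind == HET_GAIN and e.branch in path for e in truth.events
            )
            convs = sum(
                e.kind == "conversion" and e.branch in path for e in truth.events
            )
            n_het = sum(c == gt.HET for c in truth.clone_classes[leaf].values())
            assert n_het == founder_het + gains - convs

    def test_conversion_hits_het_sites(self):
        cfg = SimConfig(genome_length=50_000, somatic_rate=0.0,
                        conversion_rate=5e-3, seed=6)
        tree = two_node_tree(200.0)
        founder = generate_founder(cfg)
        truth = propagate_clones(founder, tree, cfg)
        convs = [e for e in truth.events if e.kind == "conversion"]
        assert convs, "expected conversions at this rate"
        founder_het = set(founder.founder_het_positions().tolist())
        for ev in convs:
            assert ev.pos in founder_het
            assert truth.clone_classes["clone"][ev.pos] == gt.ALT


class TestSeedlings:
    @pytest.mark.parametrize("g,p_het", [(1, 0.5), (2, 0.25)])
    def test_segregation_proportions(self, g, p_het):
        cfg = SimConfig(genome_length=20_000, seed=7)
        founder = generate_founder(cfg)
        truth = simulate_selfed_seedlings(founder, g, 400, cfg)
        het_pos = founder.founder_het_positions()
        n_ref = n_het = n_alt = 0
        for state in truth.seedling_classes.values():
            for p in het_pos.tolist():
                c = state.get(int(p), gt.REF)
                n_ref += c == gt.REF
                n_het += c == gt.HET
                n_alt += c == gt.ALT
        total = n_ref + n_het + n_alt
        # loci are linked within a seedling: use the seedling count, not
        # the locus-pair count, as the effective n for the binomial SE
        se = np.sqrt(p_het * (1 - p_het) / 400)
        assert abs(n_het / total - p_het) <= 3 * se
        assert abs(n_ref / total - n_alt / total) <= 6 * se

    def test_no_recombination_single_block(self):
        cfg = SimConfig(genome_length=20_000, n_scaffolds=1, map_length=0.0,
                        founder_selfings=0, seed=8)
        founder = generate_founder(cfg)
        truth = simulate_selfed_seedlings(founder, 1, 20, cfg)
        het_pos = [int(p) for p in founder.founder_het_positions()]
        for state in truth.seedling_classes.values():
            fates = {state.get(p, gt.REF) for p in het_pos}
            assert len(fates) == 1  # all founder-HET loci share one fate

    def test_invalid_args(self):
        cfg = SimConfig(genome_length=1000, seed=1)
        founder = generate_founder(cfg)
        with pytest.raises(ValueError):
            simulate_selfed_seedlings(founder, 0, 5, cfg)


class TestObservation:
    def test_clean_high_depth_matches_truth(self, caterpillar_truth):
        cfg, tree, truth = caterpillar_truth
        records = apply_observation_model(truth, cfg, mode="wgs")
        matrix = ch.GenotypeMatrix.from_records(records)
        truth_m = truth.clone_matrix()
        truth_frame = truth_m.to_frame()
        obs_frame = matrix.to_frame()
        assert list(obs_frame.index) == list(truth_frame.index)
        disagree = 0
        for key in obs_frame.index:
            for s in obs_frame.columns:
                o = obs_frame.loc[key, s]
                if o != gt.MISSING and o != truth_frame.loc[key, s]:
                    disagree += 1
        # depth 60: heterozygote miscall probability 2*(1/2)^60 per call
        assert disagree == 0

    def test_zero_depth_is_missing(self):
        cfg = SimConfig(genome_length=20_000, depth_mean=1.0,
                        depth_dispersion=0.5, seed=10)
        tree = two_node_tree(50.0)
        truth = propagate_clones(generate_founder(cfg), tree, cfg)
        records = apply_observation_model(truth, cfg, mode="wgs")
        zero_dp = [c for r in records for c in r.calls.values() if c.dp == 0]
        assert zero_dp and all(c.cls == gt.MISSING for c in zero_dp)

    def test_dropout_rate_recovered(self):
        """Truth-HET sites observed homozygous at ~2p(1-p) in GRAS-Di mode."""
        p = 0.2
        cfg = SimConfig(genome_length=100_000, amplicon_fraction=1.0,
                        dropout_prob=p, pcr_error_prob=0.0,
                        depth_mean=60.0, somatic_rate=0.0,
                        conversion_rate=0.0, seed=12)
        tree = two_node_tree(10.0)
        truth = propagate_clones(generate_founder(cfg), tree, cfg)
        records = apply_observation_model(truth, cfg, mode="grasdi")
        het_truth = set(int(x) for x in truth.founder_het_positions())
        by_key = {truth.locate(p_): p_ for p_ in het_truth}
        n_hom = n_obs = 0
        for rec in records:
            if rec.key not in by_key:
                continue
            call = rec.calls["clone"]
            if call.cls == gt.MISSING:
                continue
            n_obs += 1
            n_hom += call.cls in (gt.REF, gt.ALT)
        expected = 2 * p * (1 - p) / (1 - p * p)  # conditioned on non-missing
        se = np.sqrt(expected * (1 - expected) / n_obs)
        assert abs(n_hom / n_obs - expected) <= 3 * se

    def test_grasdi_restricts_to_amplicon_panel(self):
        cfg = SimConfig(genome_length=100_000, amplicon_fraction=0.05,
                        pcr_error_prob=0.0, dropout_prob=0.0, seed=13)
        tree = two_node_tree(50.0)
        truth = propagate_clones(generate_founder(cfg), tree, cfg)
        wgs = apply_observation_model(truth, cfg, mode="wgs")
        grasdi = apply_observation_model(truth, cfg, mode="grasdi")
        assert 0 < len(grasdi) < len(wgs)

    def test_byte_identical_reproducibility(self, tmp_path):
        cfg = SimConfig(genome_length=30_000, somatic_rate=1e-6, seed=14)
        tree = CloneTree.caterpillar(list("WXYZ"), 40.0)
        paths = []
        for i in (1, 2):
            truth = propagate_clones(generate_founder(cfg), tree, cfg)
            records = apply_observation_model(truth, cfg, mode="wgs")
            p = tmp_path / f"run{i}.vcf"
            ch.write_vcf(records, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestCloneTree:
    def test_newick_round_trip(self):
        tree = CloneTree.caterpillar(["A", "B", "C", "D"], 25.0)
        back = CloneTree.from_newick(tree.to_newick())
        assert sorted(back.leaves()) == ["A", "B", "C", "D"]
        assert back.leaf_set_below(back.root) == frozenset("ABCD")

    def test_invalid_trees_rejected(self):
        with pytest.raises(ValueError, match="root"):
            CloneTree([CloneNode("a", None, 0.0), CloneNode("b", None, 0.0)])
        with pytest.raises(ValueError, match="negative"):
            CloneTree([CloneNode("a", None, 0.0), CloneNode("b", "a", -1.0)])
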