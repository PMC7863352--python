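"""Lineage inference, the lineage file format, and Muller layouts."""

import numpy as np
import pytest

from chemoevo.catalog import CloneGenotype, MutationId, SnpRecord
from chemoevo.muller import (
    ROOT,
    Lineage,
    LineageError,
    LineageTree,
    clone_vs_population_concordance,
    infer_lineages,
    lineage_trajectories,
    muller_frames,
    read_lineage_file,
    render_muller,
    write_lineage_file,
)
from chemoevo.simulate import export_population_table, sample_clones, simulate
from conftest import small_sim_config

A, B, C = (MutationId(p, "C", "A") for p in (10, 20, 30))


def record(mut, traj, vessel="1"):
    return SnpRecord(vessel, mut, "seg", "missense", traj)


class TestInferLineages:
    def test_nested_chain(self):
        clones = [
            CloneGenotype("c1", "1", frozenset()),
            CloneGenotype("c2", "1", frozenset({A})),
            CloneGenotype("c3", "1", frozenset({A, B})),
        ]
        tree = infer_lineages(clones)
        by_id = {l.lineage_id: l for l in tree}
        assert by_id["L1"].parent_id == ROOT
        assert by_id["L1"].defining_mutations == {A}
        assert by_id["L2"].parent_id == "L1"
        assert by_id["L2"].defining_mutations == {B}

    def test_incomparable_genotypes_are_siblings(self):
        clones = [
            CloneGenotype("c1", "1", frozenset({A})),
            CloneGenotype("c2", "1", frozenset({B})),
        ]
        tree = infer_lineages(clones)
        assert {l.parent_id for l in tree} == {ROOT}

    def test_identical_genotypes_merge(self):
        clones = [
            CloneGenotype("c1", "1", frozenset({A})),
            CloneGenotype("c2", "1", frozenset({A})),
        ]
        assert len(infer_lineages(clones)) == 1

    def test_population_only_mutation_attaches_by_cotrending(self):
        clones = [
            CloneGenotype("c1", "1", frozenset({A})),
            CloneGenotype("c2", "1", frozenset({A, B})),
        ]
        records = [
            record(A, {50: 0.3, 100: 0.6, 150: 0.9}),
            record(B, {50: 0.0, 100: 0.3, 150: 0.6}),
            record(C, {50: 0.0, 100: 0.28, 150: 0.55}),  # rides with B's lineage
        ]
        tree = infer_lineages(clones, records)
        orphan = next(l for l in tree if C in l.defining_mutations)
        host = tree.lineages[orphan.parent_id]
        assert B in tree.genotype(host.lineage_id)

    def test_uncorrelated_orphan_goes_under_root(self):
        clones = [CloneGenotype("c1", "1", frozenset({A}))]
        records = [
            record(A, {50: 0.1, 100: 0.5, 150: 0.9}),
            record(C, {50: 0.4, 100: 0.2, 150: 0.05}),
        ]
        tree = infer_lineages(clones, records)
        orphan = next(l for l in tree if C in l.defining_mutations)
        assert orphan.parent_id == ROOT

    def test_simulated_sample_matches_truth_genealogy(self):
        cfg = small_sim_config(seed=21, allow_recurrence=False)
        truth = simulate(cfg, "1")
        clones = sample_clones(truth, cfg.n_generations, n=96)
        tree = infer_lineages(clones)
        # genotype-level parent relation must match truth ancestry restricted
        # to sampled genotypes: the parent lineage's genotype is the largest
        # sampled proper subset, which under no-recurrence equals the nearest
        # sampled ancestor's mutation set
        sampled = {c.mutations for c in clones}
        for lin in tree:
            g = tree.genotype(lin.lineage_id)
            parent_geno = tree.genotype(lin.parent_id) if lin.parent_id != ROOT else frozenset()
            ancestors = [h for h in sampled if h < g]
            best = max(ancestors, key=len, default=frozenset())
            assert parent_geno == best


class TestLineageFile:
    def test_chain_file(self, tmp_path):
        path = tmp_path / "lin.tsv"
        path.write_text(
            "#muller-lineages v1\n"
            "lineage_id\tparent_id\tdefining_mutations\tlabel\n"
            "L1\troot\t10:C>A\tgalS\n"
            "L2\tL1\t20:G>T,30:C>A\thfq cohort\n"
            "L3\tL2\t40:C>A\t.\n"
        )
        tree = read_lineage_file(path)
        assert len(tree) == 3
        assert tree.genotype("L3") == {
            MutationId(10, "C", "A"), MutationId(20, "G", "T"),
            MutationId(30, "C", "A"), MutationId(40, "C", "A"),
        }

    def test_round_trip_identity(self, tmp_path):
        cfg = small_sim_config(seed=23)
        truth = simulate(cfg, "1")
        clones = sample_clones(truth, cfg.n_generations, n=96)
        tree = infer_lineages(clones)
        path = tmp_path / "lin.tsv"
        write_lineage_file(tree, path)
        back = read_lineage_file(path)
        assert {
            (l.lineage_id, l.parent_id, l.defining_mutations) for l in tree
        } == {(l.lineage_id, l.parent_id, l.defining_mutations) for l in back}

    def test_orphan_parent_named(self, tmp_path):
        path = tmp_path / "lin.tsv"
        path.write_text(
            "#muller-lineages v1\n"
            "L1\tghost\t10:C>A\tx\n"
        )
        with pytest.raises(LineageError, match="ghost"):
            read_lineage_file(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "lin.tsv"
        path.write_text(
            "#muller-lineages v1\n"
            "L1\troot\t10:C>A\tx\n"
            "L1\troot\t20:G>T\ty\n"
        )
        with pytest.raises(LineageError, match="duplicate"):
            read_lineage_file(path)

    def test_mutation_claimed_twice_on_path_rejected(self):
        with pytest.raises(LineageError, match="re-claims"):
            LineageTree([
                Lineage("L1", ROOT, frozenset({A})),
                Lineage("L2", "L1", frozenset({A})),
            ])

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "lin.tsv"
        path.write_text("L1\troot\t10:C>A\tx\n")
        with pytest.raises(LineageError, match="header"):
            read_lineage_file(path)


class TestLineageTrajectories:
    def test_single_lineage(self):
        tree = LineageTree([Lineage("L1", ROOT, frozenset({A}))])
        series = lineage_trajectories(tree, [record(A, {50: 0.4})])
        assert series.inclusive["L1"][0] == pytest.approx(0.4)
        assert series.exclusive["L1"][0] == pytest.approx(0.4)
        assert series.exclusive[ROOT][0] == pytest.approx(0.6)

    def test_child_overflow_rescaled(self):
        tree = LineageTree([
            Lineage("L1", ROOT, frozenset({A})),
            Lineage("L2", "L1", frozenset({B})),
            Lineage("L3", "L1", frozenset({C})),
        ])
        records = [
            record(A, {50: 0.5}),
            record(B, {50: 0.4}),
            record(C, {50: 0.2}),
        ]
        series = lineage_trajectories(tree, records)
        # children sum 0.6 > parent 0.5: rescale by 5/6, parent exclusive 0
        assert series.inclusive["L2"][0] == pytest.approx(0.4 * 5 / 6)
        assert series.inclusive["L3"][0] == pytest.approx(0.2 * 5 / 6)
        assert series.exclusive["L1"][0] == pytest.approx(0.0)

    def test_cohort_mean_vs_max(self):
        tree = LineageTree([Lineage("L1", ROOT, frozenset({A, B}))])
        records = [record(A, {50: 0.2}), record(B, {50: 0.4})]
        mean = lineage_trajectories(tree, records, estimator="cohort-mean")
        mx = lineage_trajectories(tree, records, estimator="cohort-max")
        assert mean.inclusive["L1"][0] == pytest.approx(0.3)
        assert mx.inclusive["L1"][0] == pytest.approx(0.4)

    def test_missing_trajectory_warns(self):
        tree = LineageTree([Lineage("L1", ROOT, frozenset({A}))])
        with pytest.warns(UserWarning, match="no trajectory"):
            series = lineage_trajectories(tree, [record(B, {50: 0.2})])
        assert series.inclusive["L1"][0] == 0.0


def conservation_and_nesting(layout):
    for i in range(len(layout.times)):
        frame = {lid: (lo, hi) for lid, lo, hi in layout.frame(i)}
        lo, hi = frame[ROOT]
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)
        total_exclusive = 0.0
        for lid, (l, h) in frame.items():
            kids = layout.tree.children(lid)
            kw = sum(frame[k][1] - frame[k][0] for k in kids)
            width = h - l
            assert kw <= width + 1e-9
            total_exclusive += width - kw
            for k in kids:
                kl, kh = frame[k]
                assert kl >= l - 1e-9 and kh <= h + 1e-9
        assert total_exclusive == pytest.approx(1.0, abs=1e-9)


class TestMullerFrames:
    def test_constant_half_is_symmetric(self):
        tree = LineageTree([Lineage("L1", ROOT, frozenset({A}))])
        series = lineage_trajectories(tree, [record(A, {50: 0.5, 100: 0.5})])
        layout = muller_frames(tree, series, interpolation=2)
        for i in range(len(layout.times)):
            frame = dict((lid, (lo, hi)) for lid, lo, hi in layout.frame(i))
            assert frame["L1"] == (pytest.approx(0.25), pytest.approx(0.75))

    def test_all_zero_lineages_leave_ancestor_full(self):
        tree = LineageTree([Lineage("L1", ROOT, frozenset({A}))])
        series = lineage_trajectories(tree, [record(A, {50: 0.0, 100: 0.0})])
        layout = muller_frames(tree, series)
        for i in range(len(layout.times)):
            frame = dict((lid, (lo, hi)) for lid, lo, hi in layout.frame(i))
            assert frame[ROOT] == (pytest.approx(0.0), pytest.approx(1.0))
            lo, hi = frame["L1"]
            assert hi - lo == pytest.approx(0.0)

    def test_simulated_layouts_conserve_and_nest(self):
        cfg = small_sim_config(seed=31)
        truth = simulate(cfg, "1")
        records = export_population_table(truth)
        clones = sample_clones(truth, cfg.n_generations, n=48)
        tree = infer_lineages(clones, records)
        series = lineage_trajectories(tree, records)
        layout = muller_frames(tree, series, interpolation=5)
        conservation_and_nesting(layout)


class TestRender:
    def make_layout(self, seed=33):
        cfg = small_sim_config(seed=seed)
        truth = simulate(cfg, "1")
        records = export_population_table(truth)
        clones = sample_clones(truth, cfg.n_generations, n=48)
        tree = infer_lineages(clones, records)
        series = lineage_trajectories(tree, records)
        return muller_frames(tree, series, interpolation=4)

    def test_two_lineage_document(self):
        tree = LineageTree([
            Lineage("L1", ROOT, frozenset({A})),
            Lineage("L2", ROOT, frozenset({B})),
        ])
        series = lineage_trajectories(
            tree, [record(A, {50: 0.3, 100: 0.4}), record(B, {50: 0.1, 100: 0.2})]
        )
        svg = render_muller(muller_frames(tree, series))
        assert svg.count("<path") == 3  # root + 2 lineages
        assert svg.startswith("<svg")

    def test_rendering_is_deterministic(self, tmp_path):
        layout = self.make_layout()
        a = render_muller(layout, tmp_path / "a.svg")
        b = render_muller(layout, tmp_path / "b.svg")
        assert a == b
        assert (tmp_path / "a.svg").read_bytes() == (tmp_path / "b.svg").read_bytes()

    def test_palette_override(self):
        tree = LineageTree([Lineage("L1", ROOT, frozenset({A}))])
        series = lineage_trajectories(tree, [record(A, {50: 0.5})])
        svg = render_muller(muller_frames(tree, series), palette={"L1": "#123456"})
        assert "#123456" in svg


class TestConcordance:
    def test_identical_frequencies_give_r_one(self):
        clones = []
        idx = 0
        for mut, k in ((A, 2), (B, 4), (C, 8)):
            for _ in range(k):
                idx += 1
                clones.append(CloneGenotype(f"c{idx}", "1", frozenset({mut})))
        for _ in range(16 - idx):
            idx += 1
            clones.append(CloneGenotype(f"c{idx}", "1", frozenset()))
        records = [
            record(A, {100: 2 / 16}), record(B, {100: 4 / 16}), record(C, {100: 8 / 16}),
        ]
        res = clone_vs_population_concordance(clones, records, 100)
        assert res.r == pytest.approx(1.0)

    def test_single_point_r_is_nan(self):
        clones = [CloneGenotype("c1", "1", frozenset({A})),
                  CloneGenotype("c2", "1", frozenset({A}))]
        res = clone_vs_population_concordance(clones, [record(A, {100: 1.0})], 100)
        assert np.isnan(res.r)

    def test_binomial_sampling_recovers_population(self):
        # 96 clones drawn from known genotype frequencies: r should be high
        rng = np.random.default_rng(40)
        ok = 0
        for rep in range(20):
            freqs = {A: 0.6, B: 0.25, C: 0.08}
            clones = []
            for i in range(96):
                muts = frozenset(m for m, f in freqs.items() if rng.random() < f)
                clones.append(CloneGenotype(f"c{i}", "1", muts))
            records = [record(m, {100: f}) for m, f in freqs.items()]
            res = clone_vs_population_concordance(clones, records, 100)
            ok += res.r > 0.9
        assert ok >= 19
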