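"""NSGA-II channel selection: objectives, constraints, sorting, cascade, mirroring."""

import itertools
import warnings

import numpy as np
import pytest

from esiopt.headmodel import ShellModel, build_montage, build_source_space, forward_gain
from esiopt.inverse import lambda2_for_snr
from esiopt.optimize import (
    ChannelMask,
    ConstraintSpec,
    ConstraintViolation,
    GaConfig,
    ParetoRecord,
    check_constraints,
    crowding_distance,
    evaluate_mask,
    mirror_expand,
    nondominated_sort,
    run_cascade,
    run_nsga2,
)
from esiopt.simulate import SimConfig, add_noise, simulate_epochs

REDUCED_LABELS = [
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P3", "P4",
]


@pytest.fixture(scope="module")
def reduced_problem():
    """20 candidate channels, 10 sources, 20 noisy epochs."""
    montage = build_montage("10-10").subset(REDUCED_LABELS)
    src = build_source_space(5, seed=2)
    lf = forward_gain(ShellModel(), montage, src)
    epochs, _ = simulate_epochs(
        lf, np.arange(10), SimConfig(epochs_per_source=2), seed=3, background=False
    )
    epochs = add_noise(epochs, 5.0, seed=4)
    lam = lambda2_for_snr(lf, 5.0)
    return lf, epochs, lam


def _mask_of(indices, g=20):
    bits = np.zeros(g, bool)
    bits[list(indices)] = True
    return ChannelMask(bits)


@pytest.fixture(scope="module")
def exhaustive_3ch(reduced_problem):
    lf, epochs, lam = reduced_problem
    best = (np.inf, None)
    for comb in itertools.combinations(range(20), 3):
        err, _ = evaluate_mask(_mask_of(comb), lf, epochs, lambda2=lam)
        if err < best[0]:
            best = (err, comb)
    return best


class TestEvaluateMask:
    def test_channel_count_is_popcount(self, reduced_problem):
        lf, epochs, lam = reduced_problem
        _, count = evaluate_mask(_mask_of([0, 5, 9, 13]), lf, epochs, lambda2=lam)
        assert count == 4

    def test_full_mask_noiseless_sloreta_is_exact(self, lf72, single_source_epochs):
        epochs, _ = single_source_epochs
        err, count = evaluate_mask(
            ChannelMask(np.ones(lf72.n_channels, bool)), lf72, epochs, lambda2=0.0
        )
        assert (err, count) == (0.0, 72)

    def test_mean_matches_per_epoch_recomputation(self, reduced_problem):
        from esiopt.inverse import apply_inverse, localization_error, make_sloreta

        lf, epochs, lam = reduced_problem
        mask = _mask_of([1, 4, 7, 12, 18])
        mean_err, _ = evaluate_mask(mask, lf, epochs, lambda2=lam)
        op = make_sloreta(lf, lam, mask.bits)
        per_epoch = [
            localization_error(apply_inverse(op, epochs.data[t]), epochs.truth[t], lf.source_space)
            for t in range(epochs.n_trials)
        ]
        assert mean_err == pytest.approx(np.mean(per_epoch))

    def test_empty_mask_rejected(self, reduced_problem):
        lf, epochs, lam = reduced_problem
        with pytest.raises(ConstraintViolation):
            evaluate_mask(_mask_of([]), lf, epochs, lambda2=lam)


@pytest.fixture(scope="module")
def montage():
    return build_montage("10-10").subset(REDUCED_LABELS)


class TestCheckConstraints:

    def test_symmetry_midline_exempt(self, montage):
        mask = ChannelMask.from_labels(["F3", "C3", "CP5", "F4", "C4", "CP6", "Cz"], montage)
        assert check_constraints(mask, ConstraintSpec(symmetric=True), montage)

    def test_symmetry_unbalanced_counts(self, montage):
        mask = ChannelMask.from_labels(["F3", "C3", "CP5", "T7", "F4", "C4"], montage)
        assert not check_constraints(mask, ConstraintSpec(symmetric=True), montage)

    def test_cascade_child_must_stay_inside_parent(self, montage):
        parent = ChannelMask.from_labels(["F3", "F4", "C3", "C4"], montage)
        inside = ChannelMask.from_labels(["F3", "C4"], montage)
        outside = ChannelMask.from_labels(["F3", "T7"], montage)
        spec = ConstraintSpec(parent_mask=parent)
        assert check_constraints(inside, spec, montage)
        assert not check_constraints(outside, spec, montage)

    def test_allowed_label_restriction(self, montage):
        spec = ConstraintSpec(allowed_labels=frozenset(["F3", "F4", "Cz"]))
        assert check_constraints(ChannelMask.from_labels(["F3", "Cz"], montage), spec, montage)
        assert not check_constraints(ChannelMask.from_labels(["F3", "T8"], montage), spec, montage)


class TestNondominatedSort:
    def test_single_individual(self):
        rec = ParetoRecord(_mask_of([0]), 5.0, 1)
        assert nondominated_sort([rec]) == [[0]]

    def test_pairwise_dominance(self):
        a = ParetoRecord(_mask_of([0] * 1), 5.0, 8)
        b = ParetoRecord(_mask_of([1]), 7.0, 16)
        assert a.dominates(b) and not b.dominates(a)
        assert nondominated_sort([a, b]) == [[0], [1]]

    def test_matches_quadratic_oracle_on_random_population(self):
        rng = np.random.default_rng(10)
        recs = [
            ParetoRecord(_mask_of([i % 20]), float(rng.integers(0, 8)), int(rng.integers(1, 6)))
            for i in range(50)
        ]
        fronts = nondominated_sort(recs)
        # oracle: peel off non-dominated layers by exhaustive pairwise checks
        remaining = list(range(50))
        expected = []
        while remaining:
            layer = [
                i
                for i in remaining
                if not any(recs[j].dominates(recs[i]) for j in remaining if j != i)
            ]
            expected.append(sorted(layer))
            remaining = [i for i in remaining if i not in layer]
        assert [sorted(f) for f in fronts] == expected

    def test_crowding_boundary_members_infinite(self):
        recs = [
            ParetoRecord(_mask_of([i]), float(e), c)
            for i, (e, c) in enumerate([(1.0, 5), (2.0, 4), (3.0, 3), (4.0, 2)])
        ]
        cd = crowding_distance(recs, [0, 1, 2, 3])
        assert np.isinf(cd[0]) and np.isinf(cd[3])
        assert np.all(np.isfinite(cd[1:3]))


class TestRunNsga2:
    def test_archive_reaches_exhaustive_optimum(self, reduced_problem, exhaustive_3ch):
        lf, epochs, lam = reduced_problem
        res = run_nsga2(
            lf,
            epochs,
            cfg=GaConfig(population_size=30, n_generations=25, seed=7, lambda2=lam),
        )
        best3 = res.best_per_count().get(3)
        assert best3 is not None
        assert best3.mean_loc_error <= exhaustive_3ch[0] + 1e-9

    def test_same_seed_reproduces_archive(self, reduced_problem):
        lf, epochs, lam = reduced_problem
        cfg = GaConfig(population_size=10, n_generations=5, seed=1, lambda2=lam)
        a = run_nsga2(lf, epochs, cfg=cfg)
        b = run_nsga2(lf, epochs, cfg=cfg)
        assert [r.mask.key() for r in a.archive] == [r.mask.key() for r in b.archive]
        assert [r.mean_loc_error for r in a.archive] == [r.mean_loc_error for r in b.archive]

    def test_archive_satisfies_constraints(self, reduced_problem):
        lf, epochs, lam = reduced_problem
        spec = ConstraintSpec(symmetric=True)
        res = run_nsga2(
            lf,
            epochs,
            spec=spec,
            cfg=GaConfig(population_size=10, n_generations=5, seed=2, lambda2=lam),
        )
        assert all(check_constraints(r.mask, spec, lf.montage) for r in res.archive)

    def test_pareto_front_is_mutually_nondominating(self, reduced_problem):
        lf, epochs, lam = reduced_problem
        res = run_nsga2(
            lf, epochs, cfg=GaConfig(population_size=20, n_generations=10, seed=3, lambda2=lam)
        )
        front = res.pareto_front()
        assert all(
            not a.dominates(b) for a in front for b in front if a is not b
        )
        counts = [r.n_channels for r in front]
        errors = [r.mean_loc_error for r in front]
        assert counts == sorted(counts)
        assert all(a >= b for a, b in zip(errors, errors[1:]))

    def test_best_at_count_monotone(self, reduced_problem):
        lf, epochs, lam = reduced_problem
        res = run_nsga2(
            lf, epochs, cfg=GaConfig(population_size=30, n_generations=20, seed=4, lambda2=lam)
        )
        best = res.best_per_count()
        for small, large in ((3, 6), (4, 8), (6, 10)):
            if small in best and large in best:
                assert best[large].mean_loc_error <= best[small].mean_loc_error + 1e-9

    def test_added_constraint_never_helps_exhaustive_optimum(
        self, reduced_problem, exhaustive_3ch
    ):
        lf, epochs, lam = reduced_problem
        allowed = set(REDUCED_LABELS[:10])
        allowed_idx = [i for i, l in enumerate(lf.montage.labels) if l in allowed]
        constrained_best = min(
            evaluate_mask(_mask_of(c), lf, epochs, lambda2=lam)[0]
            for c in itertools.combinations(allowed_idx, 3)
        )
        assert constrained_best >= exhaustive_3ch[0] - 1e-12

    def test_infeasible_symmetry_hits_rejection_cap(self):
        montage = build_montage("10-10").subset(["C3", "C5"])  # both left
        src = build_source_space(5, seed=0)
        lf = forward_gain(ShellModel(), montage, src)
        epochs, _ = simulate_epochs(lf, np.arange(4), SimConfig(epochs_per_source=1), seed=0)
        with pytest.raises(ConstraintViolation, match="rejections"):
            run_nsga2(
                lf,
                epochs,
                spec=ConstraintSpec(symmetric=True),
                cfg=GaConfig(population_size=4, n_generations=1, seed=0),
            )


class TestCascade:
    def test_three_stage_nesting_and_monotonicity(self, reduced_problem):
        lf, epochs, lam = reduced_problem
        staged = run_cascade(
            lf,
            epochs,
            counts=(8, 5, 3),
            cfg=GaConfig(population_size=20, n_generations=12, seed=5, lambda2=lam),
        )
        assert list(staged) == [8, 5, 3]
        masks = {c: rec.mask for c, (rec, _) in staged.items()}
        assert not np.any(masks[5].bits & ~masks[8].bits)
        assert not np.any(masks[3].bits & ~masks[5].bits)
        errors = {c: rec.mean_loc_error for c, (rec, _) in staged.items()}
        assert errors[8] <= errors[5] + 1e-9 <= errors[3] + 2e-9

    def test_degenerate_single_stage(self, reduced_problem):
        lf, epochs, lam = reduced_problem
        staged = run_cascade(
            lf,
            epochs,
            counts=(3,),
            cfg=GaConfig(population_size=10, n_generations=5, seed=6, lambda2=lam),
        )
        assert list(staged) == [3]

    def test_non_decreasing_counts_rejected(self, reduced_problem):
        lf, epochs, lam = reduced_problem
        with pytest.raises(ValueError):
            run_cascade(lf, epochs, counts=(8, 8), cfg=GaConfig(population_size=4, n_generations=1))


class TestMirrorExpand:
    def test_lateral_channel_gains_partner(self):
        montage = build_montage("10-10")
        out = mirror_expand(ChannelMask.from_labels(["C3"], montage), montage)
        assert set(out.labels(montage)) == {"C3", "C4"}

    def test_midline_is_fixed_point(self):
        montage = build_montage("10-10")
        out = mirror_expand(ChannelMask.from_labels(["Cz"], montage), montage)
        assert out.labels(montage) == ["Cz"]

    def test_result_is_symmetric(self):
        montage = build_montage("10-10")
        mask = ChannelMask.from_labels(["F3", "C3", "T8", "Pz", "FC1"], montage)
        out = mirror_expand(mask, montage)
        assert check_constraints(out, ConstraintSpec(symmetric=True), montage)

    def test_missing_partner_warns_and_skips(self):
        montage = build_montage("10-10").subset(["C3", "Cz"])
        mask = ChannelMask.from_labels(["C3"], montage)
        with pytest.warns(UserWarning, match="C4"):
            out = mirror_expand(mask, montage)
        assert out.labels(montage) == ["C3"]
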