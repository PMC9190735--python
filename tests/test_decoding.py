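import numpy as np
import pandas as pd
import pytest

import chronodecode as cd
from chronodecode.decoding import _cross_accuracy
from conftest import make_epochs
from oracles import pairwise_supertrial_accuracy_oracle


def _toy_supertrials(n_cond=3, n_super=3, n_ch=2, n_t=4, sep=4.0, seed=0, scale=1.0):
    """Well-separated random super-trials; sep controls class distance."""
    rng = np.random.default_rng(seed)
    centers = sep * rng.standard_normal((n_cond, 1, n_ch, 1))
    data = scale * (centers + rng.standard_normal((n_cond, n_super, n_ch, n_t)))
    return cd.SuperTrialSet(
        conditions=tuple(f"c{i}" for i in range(n_cond)),
        data=data,
        time_ms=np.arange(float(n_t)),
        provenance={},
    )


class TestPairwiseDecode:
    def test_matches_hard_margin_oracle_on_2channel_toy(self):
        """3-fold leave-one-super-trial-out equals direct geometric evaluation."""
        st = _toy_supertrials(n_cond=4, sep=5.0, seed=3)
        acc = cd.pairwise_decode(st)
        np.testing.assert_allclose(acc, pairwise_supertrial_accuracy_oracle(st.data))

    def test_noiseless_separable_is_perfect(self):
        st = _toy_supertrials(seed=1)
        st.data = np.round(st.data * 0) + np.arange(3)[:, None, None, None] * 10.0
        assert (cd.pairwise_decode(st) == 100.0).all()

    def test_label_swap_invariance(self):
        st = _toy_supertrials(n_cond=2, seed=2)
        swapped = cd.SuperTrialSet(conditions=st.conditions,
                                   data=st.data[::-1].copy(),
                                   time_ms=st.time_ms, provenance={})
        np.testing.assert_allclose(cd.pairwise_decode(st), cd.pairwise_decode(swapped))

    def test_channel_permutation_invariance(self):
        st = _toy_supertrials(n_cond=3, n_ch=5, seed=4)
        perm = np.random.default_rng(0).permutation(5)
        permuted = cd.SuperTrialSet(conditions=st.conditions,
                                    data=st.data[:, :, perm, :].copy(),
                                    time_ms=st.time_ms, provenance={})
        np.testing.assert_allclose(cd.pairwise_decode(st), cd.pairwise_decode(permuted),
                                   atol=1e-9)

    def test_single_condition_raises(self):
        st = _toy_supertrials(n_cond=1)
        with pytest.raises(ValueError, match="2 conditions"):
            cd.pairwise_decode(st)

    def test_repetition_average_uses_factory(self, epochs_null):
        calls = []

        def factory(s):
            calls.append(s)
            return cd.make_object_supertrials(epochs_null, seed=s)

        cd.pairwise_decode(factory, n_repetitions=4, seed=0)
        assert len(calls) == 4
        assert len(set(calls)) == 4  # fresh partition every repetition


class TestObjectAndCategory:
    def test_object_decode_recovers_onset_structure(self, epochs_signal):
        acc = cd.object_decode(epochs_signal, n_repetitions=3, seed=0)
        t = epochs_signal.time_ms
        assert acc[t < 50].mean() < 57.0
        assert acc[t > 150].mean() > 95.0

    def test_category_decode_at_chance_without_category_signal(self, small_design):
        """Object-only patterns must not produce category information.

        Uses 24 objects so each category level (12 objects) averages enough
        idiosyncratic patterns for the leak to wash out within one draw.
        """
        from dataclasses import replace

        design = replace(small_design, n_objects=24)
        ss = cd.build_stimulus_set(24, 3, seed=4)
        ep = make_epochs(design, ss, seed=300, snr=3.0, category_strength=0.0)
        acc = cd.category_decode(ep, ss, n_repetitions=4, seed=0)
        assert abs(acc.mean() - 50.0) < 4.0

    def test_category_average_lifted_by_single_informative_dimension(
        self, small_design, stimset8
    ):
        ep = make_epochs(small_design, stimset8, seed=301, snr=4.0,
                         object_strength=0.0, category_onset_ms=100.0)
        mean, per_dim = cd.category_decode(ep, stimset8, n_repetitions=4, seed=1,
                                           return_dimensions=True)
        post = ep.time_ms > 200
        per_dim_mean = np.mean([a[post].mean() for a in per_dim.values()])
        np.testing.assert_allclose(mean[post].mean(), per_dim_mean, atol=1e-9)
        assert mean[post].mean() > 75.0

    def test_symmetric_level_relabel_leaves_accuracy_unchanged(
        self, epochs_signal, stimset8
    ):
        dim = stimset8.dimensions[0]
        flipped = cd.StimulusSet(
            object_ids=stimset8.object_ids,
            labels=stimset8.labels.assign(**{dim: 1 - stimset8.labels[dim]}),
        )
        a = cd.category_decode(epochs_signal, stimset8, n_repetitions=2, seed=5,
                               dimensions=(dim,))
        b = cd.category_decode(epochs_signal, flipped, n_repetitions=2, seed=5,
                               dimensions=(dim,))
        np.testing.assert_allclose(a, b)


class TestLeaveOneObjectOut:
    def test_shared_category_pattern_near_perfect(self, small_design, stimset8):
        ep = make_epochs(small_design, stimset8, seed=310, snr=4.0,
                         object_strength=0.0, category_onset_ms=100.0)
        dim = stimset8.dimensions[0]
        acc = cd.leave_one_object_out_category_decode(ep, stimset8, dim)
        assert acc[ep.time_ms > 200].mean() > 90.0

    def test_idiosyncratic_object_patterns_give_no_category_information(
        self, small_design
    ):
        """No shared category pattern: generalization across objects fails.

        The scheme must never manufacture above-chance category accuracy
        from object-specific patterns. (It can land below chance: holding
        out an object leaves its class one exemplar short, and that
        imbalance biases the intercept toward the majority class.)
        """
        from dataclasses import replace

        design = replace(small_design, n_objects=24, epoch_window=(-100.0, 200.0))
        ss = cd.build_stimulus_set(24, 3, seed=2)
        ep = make_epochs(design, ss, seed=311, snr=4.0, category_strength=0.0,
                         object_onset_ms=0.0, category_onset_ms=100.0)
        acc = cd.leave_one_object_out_category_decode(ep, ss, ss.dimensions[0])
        assert acc.mean() < 52.0

    def test_pure_noise_never_above_chance(self, small_design, stimset8):
        """Null data stay at or below chance (the scheme is conservative:
        the held-out class's missing exemplar biases folds toward errors)."""
        ep = make_epochs(small_design, stimset8, seed=312, snr=0.0)
        acc = cd.leave_one_object_out_category_decode(ep, stimset8,
                                                      stimset8.dimensions[0])
        assert acc.mean() < 53.0

    def test_two_training_objects_equals_pair_oracle(self, stimset8):
        """With one held-out object and a single training pair per level the
        fold reduces to 2-point hard-margin classification."""
        from oracles import hard_margin_classify

        rng = np.random.default_rng(8)
        ss = cd.build_stimulus_set(4, 1, seed=0)
        n_t = 3
        data, labels = [], []
        for obj in ss.object_ids:
            for _ in range(2):
                data.append(10 * rng.standard_normal((2, n_t)))
                labels.append(obj)
        # both trials of an object identical => object average = trial
        data = np.stack([data[2 * i] for i in range(4) for _ in range(2)])
        ep = cd.EpochArray(
            data=data, time_ms=np.arange(float(n_t)), fs=1000.0,
            trial_meta=pd.DataFrame({"object_id": labels,
                                     "is_oneback_repeat": [False] * 8}),
        )
        dim = ss.dimensions[0]
        acc = cd.leave_one_object_out_category_decode(ep, ss, dim, normalize=False)
        objects, avg = cd.object_averages(ep)
        lab = np.array([int(ss.labels.loc[o, dim]) for o in objects])
        expected = np.zeros(n_t)
        for o in range(4):
            train = [i for i in range(4) if i != o]
            neg = avg[[i for i in train if lab[i] == 0]]
            pos = avg[[i for i in train if lab[i] == 1]]
            for t in range(n_t):
                tn, tp = neg[:, :, t], pos[:, :, t]
                if len(tn) == 1:
                    tn = np.vstack([tn, tn])
                if len(tp) == 1:
                    tp = np.vstack([tp, tp])
                pred = hard_margin_classify(tn, tp, avg[o, :, t][None])
                expected[t] += pred[0] == (2.0 * lab[o] - 1.0)
        np.testing.assert_allclose(acc, 100.0 * expected / 4)


@pytest.fixture(scope="module")
def modal_pair(small_design, stimset8):
    def build(shared):
        model = cd.make_signal_model(
            stimset8, small_design.n_channels, seed=50, snr=3.0,
            object_onset_ms=50.0, category_onset_ms=100.0,
            shared_modality_code=shared,
        )
        eps = {}
        for i, mod in enumerate(("auditory", "visual")):
            tr = cd.generate_trial_sequence(small_design, mod, seed=60 + i)
            ep = cd.simulate_epochs(tr, stimset8, model, small_design,
                                    seed=70 + i, fs=small_design.fs_target)
            eps[mod] = cd.drop_oneback(ep)
        return eps

    return build


class TestCrossModal:
    def test_shared_code_transfers(self, modal_pair, stimset8):
        eps = modal_pair(True)
        acc = cd.crossmodal_decode(eps["auditory"], eps["visual"], stimset8,
                                   n_repetitions=2, seed=0)
        assert acc[eps["auditory"].time_ms > 200].mean() > 80.0

    def test_orthogonal_code_stays_at_chance(self, modal_pair, stimset8):
        eps = modal_pair(False)
        acc = cd.crossmodal_decode(eps["auditory"], eps["visual"], stimset8,
                                   n_repetitions=2, seed=0)
        assert abs(acc.mean() - 50.0) < 6.0

    def test_copy_of_modality_equals_train_test_on_train(self, epochs_signal, stimset8):
        nn = cd.fit_noise_normalizer(epochs_signal)
        st = cd.apply_normalizer(
            cd.make_category_supertrials(epochs_signal, stimset8,
                                         stimset8.dimensions[0], seed=4), nn)
        direct = _cross_accuracy(st, st, cost=1.0)
        assert direct[epochs_signal.time_ms > 400].mean() > 95.0

    def test_generalization_diagonal_equals_crossmodal(self, modal_pair, stimset8):
        eps = modal_pair(True)
        kw = dict(n_repetitions=1, seed=11, normalize=False)
        cm = cd.crossmodal_decode(eps["auditory"], eps["visual"], stimset8, **kw)
        tg = cd.temporal_generalization(eps["auditory"], eps["visual"], stimset8, **kw)
        np.testing.assert_allclose(np.diag(tg), cm)

    def test_sustained_shared_code_generalizes_off_diagonal(self, modal_pair, stimset8):
        eps = modal_pair(True)
        tg = cd.temporal_generalization(eps["auditory"], eps["visual"], stimset8,
                                        n_repetitions=1, seed=3)
        t = eps["auditory"].time_ms
        post = t > 250
        block = tg[np.ix_(post, post)]
        assert (block > 65.0).mean() > 0.9  # broad above-chance block

    def test_mismatched_time_axes_raise(self, epochs_signal, small_design, stimset8):
        from dataclasses import replace

        short = replace(small_design, epoch_window=(-100.0, 300.0))
        other = make_epochs(short, stimset8, seed=99, category_onset_ms=150.0)
        with pytest.raises(ValueError, match="time axis"):
            cd.crossmodal_decode(epochs_signal, other, stimset8, n_repetitions=1)


class TestAccuracyTimecourse:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError, match="0, 100"):
            cd.AccuracyTimecourse(values=np.array([[101.0]]), time_ms=np.array([0.0]))

    def test_stack_and_group_mean(self):
        acc = cd.AccuracyTimecourse.stack(
            [np.array([50.0, 60.0]), np.array([70.0, 80.0])],
            time_ms=np.array([0.0, 5.0]), scheme="object",
        )
        assert acc.n_participants == 2
        np.testing.assert_allclose(acc.group_mean(), [60.0, 70.0])
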