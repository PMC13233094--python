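"""Synthetic RDK study: designs, counterbalancing, responders, pipeline closure."""

import numpy as np
import pytest

from curriculumnet import (
    CURRICULA,
    ResponderParams,
    analyze_study,
    design_experiment,
    generate_study,
    read_participant_csv,
    simulate_participant,
    xor_responder_params,
)
from curriculumnet.human import N_TEST, N_TRAIN


def _train_trials(design):
    return [t for t in design.trials if t.phase == "train"]


def _test_trials(design):
    return [t for t in design.trials if t.phase == "test"]


class TestDesign:
    def test_ascending_coherence_ramp(self):
        design = design_experiment("ascending", participant_id=0, seed=0)
        coh = [t.motion_coherence for t in _train_trials(design)]
        assert coh[0] == pytest.approx(1.0)
        assert coh[-1] == pytest.approx(0.40)
        assert (np.diff(coh) < 0).all()

    def test_hard_constant_coherence(self):
        design = design_experiment("hard", participant_id=1, seed=0)
        assert all(t.motion_coherence == pytest.approx(0.40) for t in _train_trials(design))

    def test_random_permutes_ascending_multiset(self):
        asc = design_experiment("ascending", 0, seed=0)
        ran = design_experiment("random", 0, seed=0)
        np.testing.assert_allclose(
            sorted(t.motion_coherence for t in _train_trials(ran)),
            sorted(t.motion_coherence for t in _train_trials(asc)),
        )

    @pytest.mark.parametrize("curriculum", CURRICULA)
    def test_xor_rule_holds_on_every_trial(self, curriculum):
        design = design_experiment(curriculum, participant_id=3, seed=5)
        assert len(design.trials) == N_TRAIN + N_TEST
        for t in design.trials:
            expected = "J" if t.xor_sign * design.response_mapping > 0 else "F"
            assert t.correct_response == expected

    def test_test_phase_composition(self):
        design = design_experiment("ascending", 0, seed=2)
        test = _test_trials(design)
        assert len(test) == 16
        assert all(t.motion_coherence == pytest.approx(0.40) for t in test)
        pairings = {}
        for t in test:
            pairings[t.pairing] = pairings.get(t.pairing, 0) + 1
        assert pairings == {p: 4 for p in pairings} and len(pairings) == 4

    def test_bad_subset_exposure_ramp(self):
        # fraction of first-subset trials: first 20 trials vs last 20 differ by
        # ~0.81 in expectation for the affine 1 -> 0 ramp; demand >= 0.6
        diffs = []
        for pid in range(30):
            design = design_experiment("bad", pid, seed=11)
            feature, sign = design.subset_order[0]
            attr = "color_sign" if feature == "color" else "motion_sign"
            in_first = [getattr(t, attr) == sign for t in _train_trials(design)]
            diffs.append(np.mean(in_first[:20]) - np.mean(in_first[-20:]))
        assert np.mean(diffs) >= 0.6

    def test_counterbalancing_across_participants(self):
        mappings = {design_experiment("bad", pid, seed=0).response_mapping for pid in range(4)}
        subsets = {design_experiment("bad", pid, seed=0).subset_order[0] for pid in range(8)}
        assert mappings == {1, -1}
        assert len(subsets) == 4

    def test_unknown_curriculum(self):
        with pytest.raises(ValueError):
            design_experiment("descending", 0)


class TestResponder:
    def test_full_lapse_is_chance(self):
        design = design_experiment("ascending", 0, seed=0)
        learner = ResponderParams(nu=0.0, lapse=0.5)
        acc = np.mean(
            [simulate_participant(design, learner, seed=s).mean() for s in range(40)]
        )
        assert abs(acc - 0.5) < 0.03

    def test_noiseless_oracle_responder_is_perfect(self):
        design = design_experiment("random", 2, seed=1)
        learner = ResponderParams(nu=0.0, lapse=0.0, eta=0.0)
        oracle = xor_responder_params(design.response_mapping)
        correct = simulate_participant(design, learner, seed=0, initial_params=oracle)
        assert correct.mean() == 1.0

    def test_ascending_at_least_bad(self):
        # curriculum sensitivity inherited from the network model; 2 SE slack
        accs = {}
        for arm, curriculum in enumerate(["ascending", "bad"]):
            vals = []
            for i in range(200):
                design = design_experiment(curriculum, arm * 200 + i, seed=21)
                c = simulate_participant(
                    design, seed=np.random.default_rng([21, arm, i])
                )
                vals.append(c[N_TRAIN:].mean())
            accs[curriculum] = (np.mean(vals), np.std(vals) / np.sqrt(len(vals)))
        se = np.hypot(accs["ascending"][1], accs["bad"][1])
        assert accs["ascending"][0] >= accs["bad"][0] - 2 * se

    def test_invalid_learner_params(self):
        with pytest.raises(ValueError):
            ResponderParams(lapse=0.6)
        with pytest.raises(ValueError):
            ResponderParams(nu=-0.1)


class TestStudy:
    def test_singleton_study(self):
        dataset = generate_study(n_per_curriculum=1, master_seed=0)
        assert dataset.frame["participant"].nunique() == 4

    def test_paper_scale_shape(self):
        dataset = generate_study(n_per_curriculum=50, master_seed=0)
        frame = dataset.frame
        assert frame["participant"].nunique() == 200
        assert len(frame) == 200 * (N_TRAIN + N_TEST)
        counts = frame.groupby("curriculum")["participant"].nunique()
        assert (counts == 50).all()

    def test_master_seed_determinism(self):
        a = generate_study(n_per_curriculum=2, master_seed=5).frame
        b = generate_study(n_per_curriculum=2, master_seed=5).frame
        assert a.equals(b)

    def test_pipeline_closure(self):
        dataset = generate_study(n_per_curriculum=5, master_seed=3)
        out = analyze_study(dataset.frame)
        assert len(out["test_contrasts"]) == 6
        assert set(out["achiever_split"]) == set(CURRICULA)
        binned = out["binned_training"]
        assert set(binned["bin"]) == {1, 2, 3, 4, 5}

    def test_csv_round_trip(self, tmp_path):
        dataset = generate_study(n_per_curriculum=2, master_seed=1)
        path = tmp_path / "study.csv"
        dataset.to_csv(path)
        back = read_participant_csv(path)
        assert len(back) == len(dataset.frame)
        dataset.write_metadata(tmp_path / "meta.json")
        assert (tmp_path / "meta.json").exists()

    def test_loader_rejects_malformed(self, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        pd.DataFrame({"participant": [1], "correct": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_participant_csv(path)
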