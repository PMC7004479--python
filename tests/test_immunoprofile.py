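"""ELISA summarisation, reactivity classification and antivenom comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import venomdecomplex as vd
from venomdecomplex.errors import AlignmentError, ContractViolation
from venomdecomplex.immunoprofile import control_check
from venomdecomplex.synthetic import CONTROL_FRACTION, ELISA_AMAX, ELISA_BLANK, ELISA_K


def make_plate(cells, blank=0.0, n_blanks=2):
    """cells: {(fraction, antivenom): [replicate a492 values]} (raw readings)."""
    rows = []
    for (fid, av), reps in cells.items():
        for i, a in enumerate(reps, 1):
            rows.append(
                {"fraction_id": fid, "antivenom": av, "replicate": i,
                 "a492": a, "is_blank": False, "is_control": fid == CONTROL_FRACTION}
            )
    for i in range(1, n_blanks + 1):
        rows.append(
            {"fraction_id": "BLANK", "antivenom": "none", "replicate": i,
             "a492": blank, "is_blank": True, "is_control": False}
        )
    return vd.ElisaPlate(pd.DataFrame(rows))


class TestSummarize:
    def test_triplicate_mean_and_sem(self):
        plate = make_plate({("F1", "AV"): [0.5, 0.6, 0.7]})
        out = vd.summarize_plate(plate)
        row = out.iloc[0]
        assert row["mean_a492"] == pytest.approx(0.6)
        assert row["sem"] == pytest.approx(0.1 / np.sqrt(3), abs=1e-4)  # 0.0577
        assert row["n"] == 3

    def test_replicates_equal_to_blank_give_zero(self):
        plate = make_plate({("F1", "AV"): [0.25, 0.25]}, blank=0.25)
        assert vd.summarize_plate(plate).iloc[0]["mean_a492"] == 0.0

    def test_negatives_clipped_before_averaging(self):
        plate = make_plate({("F1", "AV"): [0.1, 0.1, 0.4]}, blank=0.2)
        # corrected replicates: 0, 0, 0.2 (not -0.1)
        assert vd.summarize_plate(plate).iloc[0]["mean_a492"] == pytest.approx(0.2 / 3)

    def test_sem_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(0)
        reps = list(rng.normal(0.8, 0.05, 300))
        sem3 = vd.summarize_plate(make_plate({("F1", "AV"): reps[:75]})).iloc[0]["sem"]
        sem12 = vd.summarize_plate(make_plate({("F1", "AV"): reps})).iloc[0]["sem"]
        assert sem3 / sem12 == pytest.approx(2.0, rel=0.25)  # 4x replicates -> half SEM

    def test_simulated_true_means_recovered_within_three_sem(self):
        # over 20 seeds, >= 95% of cells must cover the model's true corrected
        # response; the oracle accounts for the zero-truncation of raw reads:
        # E[max(0, mu + eps)] = mu*Phi(mu/sigma) + sigma*phi(mu/sigma)
        from scipy.stats import norm
        from venomdecomplex.synthetic import ELISA_NOISE_SD

        def true_corrected(aff):
            mu = ELISA_BLANK + (ELISA_AMAX * aff / (aff + ELISA_K) if aff > 0 else 0.0)
            z = mu / ELISA_NOISE_SD
            return mu * norm.cdf(z) + ELISA_NOISE_SD * norm.pdf(z) - ELISA_BLANK

        # 3-sigma margin from the generator's known noise model: replicate
        # noise over n=3 plus the shared blank-mean error over 6 blank wells
        # (at sd/3); estimated triplicate SEMs are too unstable for a margin
        margin = 3 * np.sqrt(ELISA_NOISE_SD**2 / 3 + (ELISA_NOISE_SD / 3) ** 2 / 6)
        hits = total = 0
        for seed in range(20):
            truth = vd.make_truth(seed, "indo-like")
            out = vd.summarize_plate(vd.simulate_elisa(truth))
            for _, row in out.iterrows():
                aff = truth.elisa_affinity[row["antivenom"]][row["fraction_id"]]
                hits += abs(row["mean_a492"] - true_corrected(aff)) <= margin
                total += 1
        assert hits / total >= 0.95


class TestClassification:
    @pytest.mark.parametrize(
        "mean,expected",
        [(0.05, "low"), (0.6, "reactive"), (0.15, "indeterminate"),
         (0.0, "low"), (0.2, "reactive"), (1.5, "reactive")],
    )
    def test_bands(self, mean, expected):
        assert vd.classify_reactivity(mean) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ContractViolation):
            vd.classify_reactivity(-0.01)

    @given(
        st.lists(st.floats(0, 1.4, allow_nan=False), min_size=3, max_size=3),
        st.floats(0, 0.5, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=60)
    def test_raising_a_replicate_never_demotes_reactive_to_low(self, reps, bump):
        plate = make_plate({("F1", "AV"): reps})
        before = vd.classify_reactivity(vd.summarize_plate(plate).iloc[0]["mean_a492"])
        raised = make_plate({("F1", "AV"): [reps[0] + bump, reps[1], reps[2]]})
        after = vd.classify_reactivity(vd.summarize_plate(raised).iloc[0]["mean_a492"])
        order = {"low": 0, "indeterminate": 1, "reactive": 2}
        assert order[after] >= order[before]


class TestRelativeImmunoreactivity:
    def _profile(self, means):
        return pd.DataFrame(
            {"fraction_id": list(means), "antivenom": "AV",
             "mean_a492": list(means.values()), "sem": 0.01, "n": 3,
             "is_control": False}
        )

    def test_identical_profiles_give_100_everywhere(self):
        prof = self._profile({"F1": 0.5, "F2": 1.2})
        rel = vd.relative_immunoreactivity(prof, prof)
        assert np.allclose(rel["relative_pct"], 100.0)

    def test_half_reference_gives_50(self):
        rel = vd.relative_immunoreactivity(
            self._profile({"F1": 0.5}), self._profile({"F1": 0.25})
        )
        assert rel["relative_pct"].iloc[0] == pytest.approx(50.0)

    def test_reference_below_floor_flagged_not_infinite(self):
        rel = vd.relative_immunoreactivity(
            self._profile({"F1": 0.01}), self._profile({"F1": 0.4})
        )
        assert bool(rel["undefined"].iloc[0])
        assert np.isnan(rel["relative_pct"].iloc[0])

    def test_fraction_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            vd.relative_immunoreactivity(
                self._profile({"F1": 0.5}), self._profile({"F2": 0.5})
            )


class TestControls:
    def test_passing_and_failing_negative_control(self):
        ok = make_plate({(CONTROL_FRACTION, "AV"): [0.04, 0.04, 0.04]})
        bad = make_plate({(CONTROL_FRACTION, "AV"): [0.8, 0.8, 0.8]})
        assert control_check(vd.summarize_plate(ok), {CONTROL_FRACTION: "negative"})["all_pass"]
        report = control_check(vd.summarize_plate(bad), {CONTROL_FRACTION: "negative"})
        assert not report["all_pass"]
        assert report["controls"][0]["classified"] == "reactive"

    def test_injected_control_failure_detected_on_simulated_plate(self):
        truth = vd.make_truth(2, "thai-like")
        truth.elisa_affinity["DsMAV"][CONTROL_FRACTION] = 0.9  # broken negative control
        plate = vd.simulate_elisa(truth)
        report = control_check(
            vd.summarize_plate(plate),
            {(CONTROL_FRACTION, "DsMAV"): "negative", (CONTROL_FRACTION, "SABU"): "positive"},
        )
        assert not report["all_pass"]
        failing = [c for c in report["controls"] if not c["pass"]]
        assert [c["antivenom"] for c in failing] == ["DsMAV"]

    def test_simulated_controls_pass_by_default(self):
        truth = vd.make_truth(2, "thai-like")
        plate = vd.simulate_elisa(truth)
        report = control_check(
            vd.summarize_plate(plate),
            {(CONTROL_FRACTION, "DsMAV"): "negative", (CONTROL_FRACTION, "SABU"): "positive"},
        )
        assert report["all_pass"]


class TestQualitativePresets:
    def test_zero_affinity_preset_all_fractions_low(self):
        truth = vd.make_truth(7, "thai-like")
        out = vd.immunoprofile_table(vd.summarize_plate(vd.simulate_elisa(truth)))
        sabu = out[(out["antivenom"] == "SABU") & ~out["is_control"]]
        assert len(sabu) == len(truth.fraction_ids)
        assert (sabu["reactivity"] == "low").all()

    def test_high_affinity_preset_late_fractions_reactive(self):
        truth = vd.make_truth(7, "thai-like")
        out = vd.immunoprofile_table(vd.summarize_plate(vd.simulate_elisa(truth)))
        late = [f for f in truth.fraction_ids if truth.fraction_centers[f] >= 100.0]
        dsmav = out[(out["antivenom"] == "DsMAV") & out["fraction_id"].isin(late)]
        assert (dsmav["reactivity"] == "reactive").all()
        assert dsmav["mean_a492"].between(0.2, 1.5).all()
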