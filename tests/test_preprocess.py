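"""Filter chain and artifact-rejection cascade."""

import numpy as np
import pytest

from wakeosc.core import Recording
from wakeosc.preprocess import (
    CLEAN,
    MAJOR,
    MINOR,
    ArtifactMatrix,
    RecordingExcluded,
    filter_chain,
    finalize,
    mark_segments,
    preprocess_recording,
    resolve_removals,
    screen_components,
)
from wakeosc.synthetic import ArtifactEvent, generate_aperiodic, insert_artifacts


class TestFilterChain:
    def test_constant_input_removed(self, full_montage):
        rec = Recording(np.full((128, 500 * 70), 5.0), 500.0, full_montage)
        out = filter_chain(rec, 50.0)
        trim = int(10 * out.fs)
        assert np.abs(out.signal[:, trim:-trim]).max() < 0.01
        assert out.fs == 250.0

    def test_passband_sine_amplitude_preserved(self, single_channel_montage):
        t = np.arange(0, 70, 1 / 500.0)
        rec = Recording(
            np.sin(2 * np.pi * 10 * t)[None, :], 500.0, single_channel_montage
        )
        out = filter_chain(rec, 50.0)
        mid = out.signal[0, int(20 * 250) : int(50 * 250)]
        assert mid.max() == pytest.approx(1.0, abs=0.05)

    def test_line_frequency_attenuated(self, single_channel_montage):
        from scipy.signal import welch as spwelch

        t = np.arange(0, 70, 1 / 500.0)
        sig = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 50 * t)
        rec = Recording(sig[None, :], 500.0, single_channel_montage)
        out = filter_chain(rec, 50.0)
        f, p = spwelch(out.signal[0], fs=250, nperseg=1000)
        p10 = p[np.argmin(np.abs(f - 10))]
        p50 = p[np.argmin(np.abs(f - 50))]
        assert 10 * np.log10(p10 / p50) >= 20.0

    def test_low_sampling_rate_rejected(self, single_channel_montage):
        rec = Recording(np.zeros((1, 1000)), 250.0, single_channel_montage)
        with pytest.raises(ValueError):
            filter_chain(rec, 50.0)


class TestMarkSegments:
    def test_clean_recording_all_clean(self, clean_128ch_recording):
        filtered = filter_chain(clean_128ch_recording, 50.0)
        matrix = mark_segments(filtered)
        assert (matrix.flags == CLEAN).all()

    def test_planted_transient_marked_major(self, clean_128ch_recording):
        dirty, _ = insert_artifacts(
            clean_128ch_recording,
            [ArtifactEvent("transient", 5, 10.0, 1.0)],
            seed=9,
        )
        matrix = mark_segments(filter_chain(dirty, 50.0))
        assert matrix.flags[5, 3] == MAJOR
        assert (matrix.flags == MAJOR).sum() == 1

    def test_decorrelated_channel_marked_minor(self, clean_128ch_recording):
        dirty, _ = insert_artifacts(
            clean_128ch_recording,
            [ArtifactEvent("decorrelate", 20, 0.0, 90.0)],
            seed=9,
        )
        matrix = mark_segments(filter_chain(dirty, 50.0))
        assert (matrix.flags[20] == MINOR).all()


class TestResolveRemovals:
    def _oracle_best_single_removal(self, flags):
        """Exhaustive: which single channel/segment removal clears all
        majors with the least clean-data loss."""
        best = None
        clean = flags == CLEAN
        for ch in range(flags.shape[0]):
            if (flags == MAJOR)[np.arange(flags.shape[0]) != ch].any():
                continue
            loss = clean[ch].sum()
            if best is None or loss < best[0]:
                best = (loss, "channel", ch)
        for seg in range(flags.shape[1]):
            if (flags == MAJOR)[:, np.arange(flags.shape[1]) != seg].any():
                continue
            loss = clean[:, seg].sum()
            if best is None or loss < best[0]:
                best = (loss, "segment", seg)
        return best

    def test_channel_wide_major_drops_channel(self):
        flags = np.zeros((8, 20), dtype=int)
        flags[3, :] = MAJOR
        plan = resolve_removals(ArtifactMatrix(flags))
        kind = self._oracle_best_single_removal(flags)[1]
        assert kind == "channel"
        assert plan.channels == {3} and not plan.segments

    def test_segment_wide_major_drops_segment(self):
        flags = np.zeros((8, 20), dtype=int)
        flags[:, 7] = MAJOR
        plan = resolve_removals(ArtifactMatrix(flags))
        kind = self._oracle_best_single_removal(flags)[1]
        assert kind == "segment"
        assert plan.segments == {7} and not plan.channels

    def test_compliant_matrix_yields_empty_plan(self):
        flags = np.zeros((10, 20), dtype=int)
        flags[0, :6] = MINOR  # exactly 30%
        plan = resolve_removals(ArtifactMatrix(flags))
        assert plan.is_empty

    def test_minor_loop_reaches_30_percent_everywhere(self):
        rng = np.random.default_rng(2)
        flags = (rng.random((16, 30)) < 0.25).astype(int) * MINOR
        plan = resolve_removals(ArtifactMatrix(flags))
        keep_ch = [c for c in range(16) if c not in plan.channels]
        keep_seg = [s for s in range(30) if s not in plan.segments]
        assert keep_ch and keep_seg
        sub = flags[np.ix_(keep_ch, keep_seg)]
        # fractions over the original 30-segment / 16-channel grid
        assert ((sub == MINOR).sum(axis=1) / 30).max() <= 0.30
        assert ((sub == MINOR).sum(axis=0) / 16).max() <= 0.30


class TestScreenComponents:
    def test_shallow_exponent_rejected_steep_kept(self):
        comps = np.vstack(
            [
                generate_aperiodic(
                    1, 60, 250, exponent=0.2, offset=0.5, seed=1,
                    spatial_smoothing_m=0,
                ).signal,
                generate_aperiodic(
                    1, 60, 250, exponent=1.5, offset=0.5, seed=2,
                    spatial_smoothing_m=0,
                ).signal,
            ]
        )
        keep = screen_components(comps, fs=250)
        assert list(keep) == [False, True]

    def test_white_noise_component_rejected(self):
        comp = generate_aperiodic(
            1, 60, 250, exponent=0.0, offset=0.0, seed=3, spatial_smoothing_m=0
        ).signal
        assert not screen_components(comp, fs=250)[0]

    def test_artifact_labels_override(self):
        comp = generate_aperiodic(
            1, 60, 250, exponent=1.5, offset=0.5, seed=2, spatial_smoothing_m=0
        ).signal
        assert not screen_components(comp, fs=250, labels=["muscle"])[0]

    def test_short_component_rejected(self):
        with pytest.raises(ValueError):
            screen_components(np.zeros((1, 100)), fs=250)


class TestFinalize:
    def test_montage_contract_123_channels(self, clean_128ch_recording):
        clean, report = preprocess_recording(clean_128ch_recording, 50.0)
        assert clean.n_channels == 123
        assert not report.excluded
        assert np.abs(clean.signal.mean(axis=0)).max() < 1e-6
        assert not np.isnan(clean.signal).any()

    def test_too_many_channels_excluded(self, clean_128ch_recording):
        filtered = filter_chain(clean_128ch_recording, 50.0)
        from wakeosc.preprocess import RemovalPlan

        plan = RemovalPlan(channels=set(range(26)))
        with pytest.raises(RecordingExcluded) as err:
            finalize(filtered, plan)
        assert err.value.report.reason == "too-many-channels"

    def test_too_short_excluded(self, clean_128ch_recording):
        filtered = filter_chain(clean_128ch_recording, 50.0)
        from wakeosc.preprocess import RemovalPlan

        n_seg = filtered.n_samples // int(3 * filtered.fs)
        plan = RemovalPlan(segments=set(range(n_seg - 10)))  # leave 30 s
        with pytest.raises(RecordingExcluded) as err:
            finalize(filtered, plan)
        assert err.value.report.reason == "too-short"

    def test_cascade_removes_planted_artifacts_keeps_clean_data(
        self, clean_128ch_recording
    ):
        events = [
            ArtifactEvent("transient", 5, 10.0, 1.0),
            ArtifactEvent("transient", 40, 60.0, 1.0),
            ArtifactEvent("decorrelate", 20, 0.0, 90.0),
        ]
        dirty, _ = insert_artifacts(clean_128ch_recording, events, seed=9)
        filtered = filter_chain(dirty, 50.0)
        matrix = mark_segments(filtered)
        plan = resolve_removals(matrix)
        clean, report = finalize(filtered, plan)
        # every artifact-bearing channel or its segment removed
        affected = {"E6", "E21", "E41"}
        seg_len = int(3 * filtered.fs)
        removed_segments = plan.segments | set()
        for label, t in (("E6", 10.0), ("E41", 60.0)):
            assert (
                label in report.channels_removed
                or int(t * filtered.fs) // seg_len in removed_segments
            )
        assert "E21" in report.channels_removed
        # clean-data retention: cells lost over the artifact matrix
        total = matrix.flags.size
        lost = len(plan.channels) * matrix.n_segments + len(plan.segments) * (
            matrix.n_channels - len(plan.channels)
        )
        assert 1 - lost / total >= 0.95

    def test_cascade_idempotent_on_clean_output(self, clean_128ch_recording):
        clean, _ = preprocess_recording(clean_128ch_recording, 50.0)
        matrix = mark_segments(clean)
        plan = resolve_removals(matrix)
        assert plan.is_empty
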