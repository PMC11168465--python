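import itertools
import math

import numpy as np
import pytest

from telotrace import tracking
from telotrace.imaging import ImageStack
from telotrace.synthetic import (
    KineticsConfig,
    SceneConfig,
    _ellipsoid_mask,
    generate_live_movie,
)
from telotrace.tracking import (
    ColocEvent,
    Detection,
    Track,
    assign_coloc_events,
    classify_localization,
    correct_photobleaching,
    estimate_bleach_rate,
    link_detections,
    percent_telomeres_colocalized,
    summarize_cis_trans,
)

VS = (0.3, 0.133, 0.133)


def det(frame, z, y, x, dt=5.0):
    return Detection(frame, frame * dt, np.array([z, y, x]))


class TestPhotobleaching:
    @staticmethod
    def decaying_movie(b=0.02, n=30):
        base = np.random.default_rng(1).uniform(10, 100, size=(1, 4, 16, 16))
        frames = np.stack([base * (1 - b) ** t for t in range(n)])
        return ImageStack(frames, VS, frame_interval=5.0)

    def test_exact_decay_corrected_flat(self):
        movie = self.decaying_movie()
        out = correct_photobleaching(movie)
        means = out.voxels.reshape(out.n_frames, -1).mean(axis=1)
        assert np.allclose(means, means[0], rtol=1e-6)

    def test_constant_movie_unchanged(self):
        arr = np.full((10, 1, 4, 8, 8), 42.0)
        movie = ImageStack(arr, VS, frame_interval=5.0)
        out = correct_photobleaching(movie)
        assert np.allclose(out.voxels, arr)

    def test_single_frame_is_identity(self):
        arr = np.full((1, 1, 4, 8, 8), 7.0)
        movie = ImageStack(arr, VS, frame_interval=5.0)
        assert correct_photobleaching(movie) is movie

    def test_recovers_generator_bleach_rate(self):
        scene = SceneConfig(image_shape=(6, 40, 40), n_cells=1,
                            telomeres_per_cell=(5, 5), background=5.0,
                            poisson_gain=0.0, read_sigma=0.0, seed=6)
        kin = KineticsConfig(bleach_rate=0.02, particles_per_cell=4, seed=6)
        movie, _ = generate_live_movie(scene, kin)
        b = estimate_bleach_rate(movie)
        assert abs(b - 0.02) / 0.02 < 0.10


def brute_force_link(detections_by_frame, max_disp):
    """Exhaustive per-frame minimal-cost matching (maximal match count first)."""
    frames = sorted(detections_by_frame)
    tracks = [[d] for d in detections_by_frame[frames[0]]]
    for f in frames[1:]:
        dets = detections_by_frame[f]
        open_idx = [i for i, tr in enumerate(tracks) if tr[-1].frame == f - 1]
        best = None
        for k in range(min(len(open_idx), len(dets)), -1, -1):
            for rows in itertools.combinations(open_idx, k):
                for cols in itertools.permutations(range(len(dets)), k):
                    cost = 0.0
                    ok = True
                    for i, j in zip(rows, cols):
                        d = np.linalg.norm(tracks[i][-1].position - dets[j].position)
                        if d > max_disp:
                            ok = False
                            break
                        cost += d
                    if ok and (best is None or cost < best[0]):
                        best = (cost, rows, cols)
            if best is not None:
                break  # maximal cardinality found
        _cost, rows, cols = best if best else (0.0, (), ())
        matched = set(cols)
        for i, j in zip(rows, cols):
            tracks[i].append(dets[j])
        for j, d in enumerate(dets):
            if j not in matched:
                tracks.append([d])
    return tracks


class TestLinkDetections:
    def test_single_particle_full_track(self):
        by_frame = {f: [det(f, 1.0, 2.0 + 0.05 * f, 3.0)] for f in range(10)}
        tracks = link_detections(by_frame, max_disp=1.0)
        assert len(tracks) == 1
        assert len(tracks[0].detections) == 10

    def test_two_distant_particles_no_swap(self):
        by_frame = {
            f: [det(f, 1.0, 1.0, 1.0 + 0.02 * f), det(f, 1.0, 5.0, 5.0 - 0.02 * f)]
            for f in range(8)
        }
        tracks = link_detections(by_frame, max_disp=0.5)
        assert len(tracks) == 2
        for tr in tracks:
            ys = tr.positions[:, 1]
            assert np.ptp(ys) < 0.1  # no identity swaps

    def test_gap_closing(self):
        by_frame = {f: [det(f, 1.0, 2.0, 2.0)] for f in range(10) if f != 4}
        tracks = link_detections(by_frame, max_disp=0.5, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].n_gaps == 1

    def test_no_gap_closing_when_gap_exceeds_budget(self):
        by_frame = {f: [det(f, 1.0, 2.0, 2.0)] for f in range(10)
                    if f not in (4, 5)}
        tracks = link_detections(by_frame, max_disp=0.5, max_gap=1)
        assert len(tracks) == 2

    def test_negative_max_disp_is_config_error(self):
        with pytest.raises(ValueError):
            link_detections({0: []}, max_disp=-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_minimal_cost_matching(self, seed):
        rng = np.random.default_rng(seed)
        n_particles = int(rng.integers(2, 6))
        n_frames = int(rng.integers(4, 11))
        by_frame = {}
        pos = rng.uniform(0, 8, size=(n_particles, 3))
        for f in range(n_frames):
            pos = pos + rng.normal(0, 0.15, size=pos.shape)
            by_frame[f] = [Detection(f, f * 5.0, p.copy()) for p in pos]
        got = link_detections(by_frame, max_disp=1.0, max_gap=0)
        expected = brute_force_link(by_frame, max_disp=1.0)

        def canon(trs):
            out = set()
            for tr in trs:
                dets = tr.detections if isinstance(tr, Track) else tr
                out.add(tuple((d.frame, tuple(np.round(d.position, 9)))
                              for d in dets))
            return out

        assert canon(got) == canon(expected)


class TestColocEvents:
    @staticmethod
    def telomere_track(tid, pos, n_frames=12):
        return Track(tid, [Detection(f, f * 5.0, np.asarray(pos, float))
                           for f in range(n_frames)])

    def test_three_frame_run_is_15s_stable(self):
        tel = [self.telomere_track(0, (1.0, 2.0, 2.0))]
        par = [Track(0, [det(f, 1.0, 2.0, 2.0) for f in range(3)])]
        events = assign_coloc_events(par, tel, coloc_radius=0.3,
                                     tolerance_gap=0, frame_interval=5.0)
        assert len(events) == 1
        assert events[0].duration == 15.0
        assert events[0].stable

    def test_single_frame_run_is_5s_not_stable(self):
        tel = [self.telomere_track(0, (1.0, 2.0, 2.0))]
        par = [Track(0, [det(0, 1.0, 2.0, 2.0), det(1, 1.0, 5.0, 5.0)])]
        events = assign_coloc_events(par, tel, frame_interval=5.0)
        assert len(events) == 1
        assert events[0].duration == 5.0
        assert not events[0].stable

    def test_no_telomeres_no_events(self):
        par = [Track(0, [det(0, 1.0, 2.0, 2.0)])]
        assert assign_coloc_events(par, [], frame_interval=5.0) == []

    def test_gap_bridging(self):
        tel = [self.telomere_track(0, (1.0, 2.0, 2.0))]
        dets = [det(f, 1.0, 2.0, 2.0) for f in (0, 1, 3, 4)]
        dets.insert(2, det(2, 1.0, 4.0, 4.0))  # one-frame excursion
        par = [Track(0, dets)]
        events = assign_coloc_events(par, tel, tolerance_gap=1, frame_interval=5.0)
        assert len(events) == 1
        assert events[0].duration == 25.0

    def test_events_do_not_overlap_and_durations_are_frame_multiples(self):
        rng = np.random.default_rng(2)
        tel = [self.telomere_track(i, p, n_frames=40)
               for i, p in enumerate(rng.uniform(0, 6, size=(5, 3)))]
        walk = np.cumsum(rng.normal(0, 0.3, size=(40, 3)), axis=0) + 3.0
        par = [Track(0, [Detection(f, f * 5.0, walk[f]) for f in range(40)])]
        events = assign_coloc_events(par, tel, frame_interval=5.0)
        for e in events:
            assert e.duration % 5.0 == 0.0
        spans = sorted((e.start_frame, e.end_frame) for e in events)
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            assert s2 > e1

    def test_recovers_generator_intervals_within_one_frame(self):
        scene = SceneConfig(image_shape=(6, 48, 48), n_cells=1,
                            telomeres_per_cell=(6, 6), poisson_gain=0.0,
                            read_sigma=0.0, background=0.0, seed=8)
        kin = KineticsConfig(particles_per_cell=25, k_on=20.0,
                             capture_radius=1.0, diffusion_coeff=0.25,
                             duration=600.0, seed=8)
        _movie, truth = generate_live_movie(scene, kin)
        assert len(truth.events) >= 40
        # tracks straight from ground truth; telomeres static
        par = [
            Track(tid, [Detection(r.frame, r.t_s, np.array([r.z_um, r.y_um, r.x_um]))
                        for r in grp.itertuples()])
            for tid, grp in truth.tracks.groupby("track_id")
        ]
        tel = [
            Track(r.object_id,
                  [Detection(f, f * 5.0, np.array([r.z_um, r.y_um, r.x_um]))
                   for f in range(kin.n_frames)])
            for r in truth.foci.itertuples()
        ]
        events = assign_coloc_events(par, tel, coloc_radius=0.3,
                                     tolerance_gap=0, frame_interval=5.0)
        matched = 0
        for t in truth.events.itertuples():
            hit = [e for e in events
                   if e.track_id == t.track_id and e.telomere_id == t.telomere_id
                   and abs(e.start_frame - t.start_frame) <= 1
                   and abs(e.end_frame - t.end_frame) <= 1]
            matched += bool(hit)
        assert matched / len(truth.events) >= 0.95


class TestClassifyLocalization:
    ORIGIN = np.array([1.2, 3.0, 3.0])
    OTHERS = np.array([[1.2, 3.0, 3.0], [1.2, 6.0, 6.0], [2.4, 1.0, 1.0]])

    def test_overlapping_origin(self):
        assert classify_localization(self.ORIGIN, self.ORIGIN, self.OTHERS) \
            == "origin_telomere"

    def test_proximity_threshold_0p6(self):
        near = self.ORIGIN + [0, 0.5, 0]
        far = self.ORIGIN + [0, 0.7, 0]
        assert classify_localization(near, self.ORIGIN, self.OTHERS) \
            == "origin_proximal"
        assert classify_localization(far, self.ORIGIN, self.OTHERS) \
            == "nontelomeric"

    def test_same_z_slice_required_in_slice_mode(self):
        shifted = self.ORIGIN + [0.3, 0.3, 0]  # next z slice at 0.3 μm step
        assert classify_localization(shifted, self.ORIGIN, self.OTHERS,
                                     same_z=True, z_step_um=0.3) \
            == "nontelomeric"
        assert classify_localization(shifted, self.ORIGIN, self.OTHERS,
                                     same_z=False) == "origin_proximal"

    def test_other_telomere(self):
        at_other = np.array([1.2, 6.0, 6.0])
        assert classify_localization(at_other, self.ORIGIN, self.OTHERS) \
            == "other_telomere"

    def test_missing_origin_restricts_classes(self):
        at_other = np.array([1.2, 6.0, 6.0])
        assert classify_localization(at_other, None, self.OTHERS) \
            == "other_telomere"
        away = np.array([1.2, 4.5, 4.5])
        assert classify_localization(away, None, self.OTHERS) == "nontelomeric"


class TestSummarizeCisTrans:
    def test_reported_breakdown(self):
        labels = (["origin_telomere"] * 4 + ["origin_proximal"] * 3
                  + ["other_telomere"] * 57 + ["nontelomeric"] * 344)
        pct = summarize_cis_trans(labels)
        assert pct["n"] == 408
        assert round(pct["cis_percent"], 1) == 1.7
        assert round(pct["other_telomere_percent"], 1) == 14.0
        assert round(pct["nontelomeric_percent"], 1) == 84.3

    def test_all_origin_is_100_cis(self):
        assert summarize_cis_trans(["origin_telomere"] * 5)["cis_percent"] == 100.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            summarize_cis_trans([])

    def test_uniform_placement_matches_telomere_volume_fraction(self):
        """Monte-Carlo: other_telomere% equals the exact in-mask fraction."""
        rng = np.random.default_rng(4)
        grid = (10, 48, 48)
        mask = _ellipsoid_mask(grid, tuple(g / 2 for g in grid),
                               tuple(0.45 * g for g in grid))
        vs = np.asarray(VS)
        idx = np.argwhere(mask)
        tel = idx[rng.choice(len(idx), 15, replace=False)] * vs
        overlap = 0.3
        all_um = idx * vs
        from scipy.spatial.distance import cdist

        f_exact = (cdist(all_um, tel).min(axis=1) <= overlap).mean()
        n = 3000
        sample = all_um[rng.integers(0, len(all_um), n)]
        labels = [
            classify_localization(p, None, tel, overlap_um=overlap, same_z=False)
            for p in sample
        ]
        pct = summarize_cis_trans(labels)
        se = math.sqrt(f_exact * (1 - f_exact) / n)
        assert abs(pct["other_telomere_percent"] / 100 - f_exact) < 3 * se


class TestPercentTelomeresColocalized:
    def test_no_stable_events_is_zero(self):
        events = [ColocEvent(0, 0, 0, 0, 5.0)]
        assert percent_telomeres_colocalized(events, [0, 1]) == 0.0

    def test_every_telomere_stable_is_100(self):
        events = [ColocEvent(i, i, 0, 2, 5.0) for i in range(3)]
        assert percent_telomeres_colocalized(events, [0, 1, 2]) == 100.0

    def test_zero_telomeres_is_error(self):
        with pytest.raises(ValueError):
            percent_telomeres_colocalized([], [])

    def test_monotone_in_binding_rate(self):
        def pct(k_on, seed=12):
            scene = SceneConfig(image_shape=(6, 40, 40), n_cells=1,
                                telomeres_per_cell=(10, 10), poisson_gain=0.0,
                                read_sigma=0.0, background=0.0, seed=seed)
            kin = KineticsConfig(particles_per_cell=4, k_on=k_on,
                                 capture_radius=0.5, diffusion_coeff=0.2,
                                 seed=seed)
            _m, truth = generate_live_movie(scene, kin)
            events = [
                ColocEvent(r.track_id, r.telomere_id, r.start_frame,
                           r.end_frame, 5.0)
                for r in truth.events.itertuples()
            ]
            return percent_telomeres_colocalized(
                events, truth.foci["object_id"].tolist())

        assert pct(0.2) > pct(0.05)
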