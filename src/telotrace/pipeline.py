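"""End-to-end orchestration: fixed-image analysis, live-movie analysis and
the synthetic benchmark, with CSV/JSON/figure reporting."""

from __future__ import annotations

import hashlib
import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .imaging import ImageStack
from . import spots, coloc, tracking, kinetics, synthetic

__all__ = ["RunConfig", "RunReport", "run_fish_pipeline", "run_live_pipeline",
           "run_live_from_tracks", "run_benchmark"]


@dataclass
class RunConfig:
    """Channel roles and module parameters for a pipeline run."""

    mode: str = "fish"  # fish | live | simulate | benchmark
    channels: dict = field(default_factory=lambda: {"dapi": 0, "telomere": 1, "rna_a": 2})
    seed: int = 0
    # detection
    threshold_policy: str = "median_mad"
    k_mad: float = 6.0
    min_voxels: int = 2
    max_voxels: int = 100_000
    # shuffle null
    shuffle: bool = True
    n_shuffles: int = 100
    # tracking
    max_disp_um: float = 1.0
    max_gap: int = 1
    coloc_radius_um: float = 0.3
    tolerance_gap: int = 1

    def __post_init__(self) -> None:
        roles = list(self.channels.values())
        if len(set(roles)) != len(roles):
            raise ValueError("channel roles must map to distinct channels")

    def digest(self) -> str:
        body = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(body.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Tables + summary produced by one pipeline run."""

    tables: dict[str, pd.DataFrame]
    summary: dict
    provenance: dict

    def write(self, out_dir, figures: bool = True) -> None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        payload = {"summary": self.summary, "provenance": self.provenance}
        (out / "run_summary.json").write_text(
            json.dumps(payload, indent=2, default=_jsonable)
        )
        if figures:
            self._write_figures(out)

    def _write_figures(self, out: pathlib.Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if "survival" in self.tables:
            df = self.tables["survival"]
            fig, ax = plt.subplots()
            ax.step(df["t_s"], df["S"], where="post")
            ax.set_xlabel("dwell time (s)")
            ax.set_ylabel("survival (1-CDF)")
            fig.savefig(out / "survival.png", dpi=120)
            plt.close(fig)
        if "per_cell" in self.tables and len(self.tables["per_cell"]):
            df = self.tables["per_cell"]
            fig, ax = plt.subplots()
            ax.hist(df["n_pairs"], bins=range(0, int(df["n_pairs"].max()) + 2))
            ax.set_xlabel("colocalizations per cell")
            ax.set_ylabel("cells")
            fig.savefig(out / "pairs_per_cell.png", dpi=120)
            plt.close(fig)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _foci_table(foci: list, channel_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "object_id": f.object_id,
                "channel": channel_name,
                "cell_id": f.cell_id,
                "z_um": f.centroid_um[0],
                "y_um": f.centroid_um[1],
                "x_um": f.centroid_um[2],
                "integrated_density": f.integrated_density,
                "volume_um3": f.volume_um3,
                "n_voxels": f.n_voxels,
                "peak_count": f.peak_count,
            }
            for f in foci
        ]
    )


# ---------------------------------------------------------------------------


def run_fish_pipeline(stack: ImageStack, config: RunConfig) -> RunReport:
    """Fixed-image chain: nuclei → foci → overlap colocalization (+ shuffle
    null per nucleus) → triple partition against the telomere channel →
    per-cell report and cohort statistics."""
    ch = config.channels
    for role in ("dapi", "telomere", "rna_a"):
        if role not in ch:
            raise ValueError(f"missing channel role {role!r}")
        if ch[role] >= stack.n_channels:
            raise ValueError(f"channel {ch[role]} for role {role!r} not in stack")

    nuclei = spots.segment_nuclei(stack, ch["dapi"])
    det = dict(threshold_policy=config.threshold_policy, k_mad=config.k_mad,
               min_voxels=config.min_voxels, max_voxels=config.max_voxels,
               nuclei=nuclei)
    tel = spots.detect_foci(stack, ch["telomere"], **det)
    rna_a = spots.detect_foci(stack, ch["rna_a"], **det)
    has_b = "rna_b" in ch
    rna_b = spots.detect_foci(stack, ch["rna_b"], **det) if has_b else tel

    pairs = coloc.overlap_colocalize(rna_a, rna_b)
    if has_b:
        labels, b_free = coloc.triple_partition(pairs, rna_a, rna_b, tel)
    else:
        labels, b_free = {}, []

    foci_by_channel = {"rna_a": rna_a, "rna_b": rna_b, "telomere": tel}
    cell_ids = [n.cell_id for n in nuclei]
    per_cell, cohort = coloc.per_cell_report(
        foci_by_channel, pairs, labels, b_free, cell_ids=cell_ids
    )

    envelopes = []
    if config.shuffle and rna_a and rna_b:
        for nuc in nuclei:
            a_in = [f for f in rna_a if f.cell_id == nuc.cell_id]
            b_in = [f for f in rna_b if f.cell_id == nuc.cell_id]
            if not a_in or not b_in:
                continue
            try:
                env = coloc.shuffle_null(
                    a_in, b_in, nuc, n_shuffles=config.n_shuffles,
                    seed=config.seed + nuc.cell_id,
                )
            except ValueError:
                continue
            envelopes.append(
                {"cell_id": nuc.cell_id, "p_value": env.p_value,
                 "significant": env.significant}
            )

    tables = {
        "foci": pd.concat(
            [_foci_table(tel, "telomere"), _foci_table(rna_a, "rna_a")]
            + ([_foci_table(rna_b, "rna_b")] if has_b else []),
            ignore_index=True,
        ),
        "pairs": pd.DataFrame(
            [
                {
                    "focus_a_id": p.focus_a_id,
                    "focus_b_id": p.focus_b_id,
                    "shared_voxels": p.shared_voxels,
                    "center_distance_um": p.center_distance_um,
                    "partition": labels.get((p.focus_a_id, p.focus_b_id), ""),
                }
                for p in pairs
            ]
        ),
        "per_cell": per_cell,
        "shuffle": pd.DataFrame(envelopes),
    }
    summary = dict(cohort)
    summary["n_nuclei"] = len(nuclei)
    prov = {"config_digest": config.digest(), "seed": config.seed,
            "version": __version__}
    return RunReport(tables, summary, prov)


def run_live_pipeline(movie: ImageStack, config: RunConfig,
                      frame_interval: float | None = None) -> RunReport:
    """Live-movie chain: bleach-correct → per-frame detection → linking →
    colocalization events → survival curve, constrained bi-exponential fit,
    Kaplan-Meier cumulative dwell."""
    if not movie.is_timelapse or movie.n_frames < 2:
        raise ValueError("need a time-lapse movie with >= 2 frames")
    dt = frame_interval or movie.frame_interval
    ch = config.channels
    for role in ("particle", "telomere"):
        if role not in ch:
            raise ValueError(f"missing channel role {role!r}")

    corrected = tracking.correct_photobleaching(movie)
    bleach = tracking.estimate_bleach_rate(movie)

    def detections_for(channel: int) -> dict[int, list[tracking.Detection]]:
        by_frame: dict[int, list[tracking.Detection]] = {}
        for f in range(corrected.n_frames):
            frame = corrected.frame(f)
            foci = spots.detect_foci(
                frame, channel, config.threshold_policy, config.k_mad,
                min_voxels=config.min_voxels, max_voxels=config.max_voxels,
            )
            by_frame[f] = [
                tracking.Detection(f, f * dt, fc.centroid_um, fc.integrated_density)
                for fc in foci
            ]
        return by_frame

    particle_tracks = tracking.link_detections(
        detections_for(ch["particle"]), config.max_disp_um, config.max_gap
    )
    telomere_tracks = tracking.link_detections(
        detections_for(ch["telomere"]), config.max_disp_um, config.max_gap
    )
    report = run_live_from_tracks(particle_tracks, telomere_tracks, config, dt)
    report.summary["bleach_rate_per_frame"] = bleach
    return report


def run_live_from_tracks(
    particle_tracks: list, telomere_tracks: list, config: RunConfig,
    frame_interval: float,
) -> RunReport:
    """Dwell-event extraction and kinetics from pre-linked tracks (e.g.,
    CSV tables produced by an external tracker)."""
    dt = frame_interval
    events = tracking.assign_coloc_events(
        particle_tracks, telomere_tracks, config.coloc_radius_um,
        config.tolerance_gap, dt,
    )

    tables = {
        "tracks": pd.DataFrame(
            [
                {"track_id": tr.track_id, "frame": d.frame, "t_s": d.t,
                 "z_um": d.position[0], "y_um": d.position[1], "x_um": d.position[2],
                 "intensity": d.intensity}
                for tr in particle_tracks for d in tr.detections
            ]
        ),
        "events": pd.DataFrame(
            [
                {"track_id": e.track_id, "telomere_id": e.telomere_id,
                 "t_start_s": e.t_start, "t_end_s": e.t_end,
                 "duration_s": e.duration, "stable": e.stable}
                for e in events
            ]
        ),
    }
    summary: dict = {
        "n_particle_tracks": len(particle_tracks),
        "n_telomere_tracks": len(telomere_tracks),
        "n_events": len(events),
    }
    if telomere_tracks:
        summary["pct_telomeres_colocalized"] = tracking.percent_telomeres_colocalized(
            events, [tr.track_id for tr in telomere_tracks]
        )
    if events:
        durations = np.array([e.duration for e in events])
        curve = kinetics.survival_from_dwells(durations)
        tables["survival"] = pd.DataFrame({"t_s": curve.t, "S": curve.S})
        try:
            fit = kinetics.fit_biexponential(curve, seed=config.seed)
            hl_f, hl_s = kinetics.derive_half_life(fit)
            summary["biexp_fit"] = {
                "tau_fast_s": fit.tau_fast, "tau_slow_s": fit.tau_slow,
                "halflife_fast_s": hl_f, "halflife_slow_s": hl_s,
                "A_fast": fit.A_fast, "A_slow": fit.A_slow,
                "r_squared": fit.r_squared, "single_phase": fit.single_phase,
            }
        except (ValueError, kinetics.FitError) as err:
            summary["biexp_fit"] = None
            summary["fit_warning"] = str(err)
        # cumulative dwell per telomere, censored at movie end
        per_tel: dict[int, float] = {}
        last_frame = max(
            (d.frame for tr in particle_tracks + telomere_tracks
             for d in tr.detections), default=0,
        )
        movie_end = last_frame * dt
        for e in events:
            per_tel[e.telomere_id] = per_tel.get(e.telomere_id, 0.0) + e.duration
        cum, cens = [], []
        for tel_id, total in sorted(per_tel.items()):
            cum.append(total)
            cens.append(any(e.telomere_id == tel_id and e.t_end >= movie_end
                            for e in events))
        km = kinetics.km_cumulative_dwell(cum, cens)
        summary["km_median_cumulative_dwell_s"] = km.median
    else:
        summary["fit_warning"] = "no colocalization events; fit skipped"
    prov = {"config_digest": config.digest(), "seed": config.seed,
            "version": __version__}
    return RunReport(tables, summary, prov)


# ---------------------------------------------------------------------------


def run_benchmark(seed: int = 0, n_calibration: int = 100,
                  n_shuffles: int = 100) -> RunReport:
    """Worked-example and calibration checks, reported as a pass/fail table."""
    rows = []

    # cis/trans worked example
    labels = (["origin_telomere"] * 4 + ["origin_proximal"] * 3
              + ["other_telomere"] * 57 + ["nontelomeric"] * 344)
    pct = tracking.summarize_cis_trans(labels)
    rows.append({"check": "cis_trans_percentages",
                 "value": round(pct["cis_percent"], 1),
                 "expected": 1.7,
                 "passed": round(pct["cis_percent"], 1) == 1.7
                 and round(pct["other_telomere_percent"]) == 14
                 and round(pct["nontelomeric_percent"], 1) == 84.3})

    # stability rule at 5 s frames
    e3 = tracking.ColocEvent(0, 0, 0, 2, 5.0)
    e1 = tracking.ColocEvent(0, 0, 0, 0, 5.0)
    rows.append({"check": "stability_rule",
                 "value": (e3.duration, e1.duration),
                 "expected": (15.0, 5.0),
                 "passed": e3.duration == 15.0 and e3.stable
                 and e1.duration == 5.0 and not e1.stable})

    # half-life identity
    fit = kinetics.BiExpFit(0.6, 0.4, 1 / 8.0, 1 / 40.0, 1.0)
    hf, hs = kinetics.derive_half_life(fit)
    ok = math.isclose(hf / fit.tau_fast, math.log(2)) and math.isclose(
        hs / fit.tau_slow, math.log(2))
    rows.append({"check": "halflife_identity", "value": (hf, hs),
                 "expected": "ln2 x tau", "passed": ok})

    # shuffle-null type-I calibration (reduced repeats)
    rate = shuffle_calibration_rate(seed=seed, n_repeats=n_calibration,
                                    n_shuffles=n_shuffles)
    ci = 1.96 * math.sqrt(max(rate * (1 - rate), 1e-9) / n_calibration)
    rows.append({"check": "shuffle_type_I", "value": rate,
                 "expected": "<= 0.05 (binomial CI)",
                 "passed": rate - ci <= 0.05})

    table = pd.DataFrame(rows)
    summary = {"all_passed": bool(table["passed"].all())}
    return RunReport({"benchmark": table}, summary,
                     {"seed": seed, "version": __version__})


def _calibration_instance(seed: int, n_objects: int = 20,
                          n_shuffles: int = 100) -> bool:
    """One null instance: A and B placed uniformly in an ellipsoidal mask."""
    rng = np.random.default_rng(seed)
    shape = (12, 64, 64)
    vs = (0.3, 0.133, 0.133)
    mask = synthetic._ellipsoid_mask(
        shape, tuple(s / 2 for s in shape), tuple(0.45 * s for s in shape)
    )
    stack_shape = shape

    def make_foci(channel: int) -> list[spots.Focus]:
        pts = synthetic.uniform_points_in_mask(mask, n_objects, rng).astype(int)
        out = []
        for i, p in enumerate(pts):
            out.append(
                spots.Focus(
                    object_id=i, channel=channel, voxels=p[None, :],
                    centroid_um=p * np.asarray(vs),
                    integrated_density=1.0,
                    volume_um3=float(np.prod(vs)),
                    grid_shape=stack_shape, voxel_size=vs,
                )
            )
        return out

    env = coloc.shuffle_null(
        make_foci(0), make_foci(1), mask, n_shuffles=n_shuffles,
        seed=int(rng.integers(0, 2**31)),
    )
    return env.significant


def shuffle_calibration_rate(seed: int = 0, n_repeats: int = 1000,
                             n_shuffles: int = 100, n_objects: int = 20) -> float:
    """Fraction of null instances the shuffle test declares significant."""
    hits = sum(
        _calibration_instance(seed * 1_000_003 + i, n_objects, n_shuffles)
        for i in range(n_repeats)
    )
    return hits / n_repeats
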