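"""Seeded synthetic FISH scenes and live-cell movies with ground truth.

The generator plants the statistical structure the analysis chain assumes:
nuclei containing telomere foci with skewed (log-normal) per-focus "length",
focus intensity proportional to length, sparse RNA spots preferentially
placed at long telomeres, diffraction-limited Gaussian blur with Poisson and
Gaussian read noise, and live particles alternating between free diffusion
and telomere-bound states whose bound durations follow a two-component
exponential mixture, with per-frame multiplicative photobleaching.

Everything is driven by a single integer seed: identical config + seed
reproduces arrays and truth tables bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .imaging import ImageStack, DEFAULT_VOXEL_SIZE

__all__ = [
    "SceneConfig",
    "KineticsConfig",
    "GroundTruth",
    "saturating_affinity",
    "generate_fish_scene",
    "generate_live_movie",
    "sample_dwell_times",
    "uniform_points_in_mask",
    "scene_config_from_yaml",
    "kinetics_config_from_yaml",
]

CHANNEL_DAPI = "dapi"
CHANNEL_TELOMERE = "telomere"
CHANNEL_RNA_A = "rna_a"
CHANNEL_RNA_B = "rna_b"
CHANNEL_PARTICLE = "particle"


def saturating_affinity(l50: float = 5.0, p_max: float = 1.0) -> Callable[[float], float]:
    """Monotone non-decreasing placement probability p(L) = p_max·L/(L+l50)."""
    if not 0.0 <= p_max <= 1.0:
        raise ValueError("p_max must be in [0, 1]")

    def p(length: float) -> float:
        return p_max * length / (length + l50)

    return p


def _as_prob_fn(p) -> Callable[[float], float]:
    if p is None:
        return saturating_affinity()
    if callable(p):
        return p
    const = float(p)
    if not 0.0 <= const <= 1.0:
        raise ValueError("constant p_rna_at_telomere must be in [0, 1]")
    return lambda _l: const


@dataclass
class SceneConfig:
    """Parameters of a fixed multi-channel FISH scene."""

    image_shape: tuple[int, int, int] = (16, 192, 192)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    n_cells: int = 4
    telomeres_per_cell: tuple[int, int] = (8, 14)  # inclusive uniform range
    length_log_mu: float = math.log(5.0)  # log-normal "length" (kb-equivalents)
    length_log_sigma: float = 0.5
    intensity_per_length: float = 400.0  # photons per unit length
    rna_spots_per_cell: tuple[int, int] = (2, 5)
    rna_intensity: float = 1500.0  # photons per RNA spot
    n_rna_channels: int = 1
    p_rna_at_telomere: Callable[[float], float] | float | None = None
    p_rna_pair: float = 0.5  # chance a channel-B spot co-places with an A spot
    p_doublet: float = 0.0
    psf_sigma: tuple[float, float, float] = (0.40, 0.13, 0.13)  # μm (z, y, x)
    background: float = 10.0  # photons
    dapi_level: float = 100.0
    poisson_gain: float = 0.0  # 0 disables shot noise
    read_sigma: float = 0.0  # Gaussian read noise, 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.image_shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("image_shape and voxel_size must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.p_doublet <= 1.0 or not 0.0 <= self.p_rna_pair <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_rna_channels not in (0, 1, 2):
            raise ValueError("n_rna_channels must be 0, 1 or 2")
        fn = _as_prob_fn(self.p_rna_at_telomere)
        probe = [fn(l) for l in (0.01, 0.5, 1, 2, 5, 10, 20, 50)]
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probe):
            raise ValueError("p_rna_at_telomere must map lengths into [0, 1]")
        if any(b < a - 1e-9 for a, b in zip(probe, probe[1:])):
            raise ValueError("p_rna_at_telomere must be non-decreasing in length")

    @property
    def channel_names(self) -> tuple[str, ...]:
        names = [CHANNEL_DAPI, CHANNEL_TELOMERE]
        if self.n_rna_channels >= 1:
            names.append(CHANNEL_RNA_A)
        if self.n_rna_channels == 2:
            names.append(CHANNEL_RNA_B)
        return tuple(names)


@dataclass
class KineticsConfig:
    """Parameters of a two-state (free/bound) live-particle movie."""

    frame_interval: float = 5.0  # s
    duration: float = 300.0  # s
    diffusion_coeff: float = 0.05  # μm²/s
    p_fast: float = 0.6
    tau_fast: float = 8.0  # s
    tau_slow: float = 40.0  # s
    k_on: float = 2.0  # per-s binding rate inside the capture radius
    bleach_rate: float = 0.0  # per-frame fractional intensity loss
    capture_radius: float = 0.5  # μm
    bound_jitter: float = 0.05  # μm, particle wobble around the telomere centre
    particles_per_cell: int = 6
    particle_intensity: float = 2000.0
    start_bound: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fast <= 1.0:
            raise ValueError("p_fast must be in [0, 1]")
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ValueError("residence times must be positive")
        if self.tau_fast > self.tau_slow:
            raise ValueError("tau_fast must not exceed tau_slow")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("frame_interval and duration must be positive")
        n = self.duration / self.frame_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("frame_interval must divide duration")
        if self.bleach_rate < 0 or self.bleach_rate >= 1:
            raise ValueError("bleach_rate must be in [0, 1)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1


@dataclass
class GroundTruth:
    """Planted-object tables backing a synthetic scene or movie."""

    nuclei: pd.DataFrame
    foci: pd.DataFrame
    tracks: pd.DataFrame | None = None
    events: pd.DataFrame | None = None

    def to_csv(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.nuclei.to_csv(d / "truth_nuclei.csv", index=False)
        self.foci.to_csv(d / "truth_foci.csv", index=False)
        if self.tracks is not None:
            self.tracks.to_csv(d / "truth_tracks.csv", index=False)
        if self.events is not None:
            self.events.to_csv(d / "truth_events.csv", index=False)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _nucleus_layout(cfg: SceneConfig) -> pd.DataFrame:
    """Ellipsoidal nuclei on a regular grid (voxel-index coordinates)."""
    nz, ny, nx = cfg.image_shape
    ncols = int(math.ceil(math.sqrt(cfg.n_cells)))
    nrows = int(math.ceil(cfg.n_cells / ncols))
    tile_y, tile_x = ny / nrows, nx / ncols
    rows = []
    for i in range(cfg.n_cells):
        r, c = divmod(i, ncols)
        cz, cy, cx = nz / 2.0, (r + 0.5) * tile_y, (c + 0.5) * tile_x
        rows.append(
            {
                "cell_id": i,
                "cz": cz, "cy": cy, "cx": cx,
                "rz": 0.42 * nz, "ry": 0.42 * tile_y, "rx": 0.42 * tile_x,
            }
        )
    return pd.DataFrame(rows)


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((z - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((x - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _sample_in_ellipsoid(rng, center, radii, margin: float = 0.85) -> np.ndarray:
    """Uniform point inside a shrunken ellipsoid (voxel-index coordinates)."""
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u * u) <= 1.0:
            return np.asarray(center) + margin * np.asarray(radii) * u


def uniform_points_in_mask(mask: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` voxel-index points drawn uniformly from ``mask`` (with replacement)."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    return idx[rng.integers(0, idx.shape[0], size=n)].astype(float)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_spot(img: np.ndarray, center_vox: Sequence[float], sigma_vox: Sequence[float],
                 total: float, half_width: float = 4.0) -> None:
    """Add a 3D Gaussian of integrated intensity ``total`` at ``center_vox``.

    The profile is integrated over each voxel with the error function so the
    rendered sum conserves ``total`` up to window/image truncation.
    """
    from scipy.special import ndtr  # standard normal CDF

    axes_w = []
    for ax in range(3):
        c, s = center_vox[ax], max(sigma_vox[ax], 1e-6)
        lo = max(0, int(math.floor(c - half_width * s)))
        hi = min(img.shape[ax] - 1, int(math.ceil(c + half_width * s)))
        if hi < lo:
            return
        edges = np.arange(lo, hi + 2) - 0.5
        w = np.diff(ndtr((edges - c) / s))
        axes_w.append((lo, hi, w))
    (lz, hz, wz), (ly, hy, wy), (lx, hx, wx) = axes_w
    img[lz:hz + 1, ly:hy + 1, lx:hx + 1] += (
        total * wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
    )


def _apply_noise(img: np.ndarray, gain: float, read_sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    out = img
    if gain > 0:
        out = rng.poisson(out / gain) * gain
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# fixed scene
# ---------------------------------------------------------------------------

def generate_fish_scene(cfg: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a multi-channel FISH scene and its planted-object truth.

    Channel order is ``cfg.channel_names``: DAPI (nucleus fill), telomere
    (per-focus total intensity = intensity_per_length × length before
    noise), then one or two RNA channels.
    """
    rng = np.random.default_rng(cfg.seed)
    vs = np.asarray(cfg.voxel_size)
    sigma_vox = np.asarray(cfg.psf_sigma) / vs
    names = cfg.channel_names
    stack = np.zeros((len(names),) + tuple(cfg.image_shape), dtype=float)

    nuclei = _nucleus_layout(cfg)
    dapi = stack[0]
    for row in nuclei.itertuples():
        dapi[_ellipsoid_mask(cfg.image_shape, (row.cz, row.cy, row.cx),
                             (row.rz, row.ry, row.rx))] = cfg.dapi_level

    fwhm_xy_vox = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma_vox[1]
    p_fn = _as_prob_fn(cfg.p_rna_at_telomere)

    foci_rows: list[dict] = []
    object_id = 0
    tel_by_cell: dict[int, list[dict]] = {}

    for row in nuclei.itertuples():
        center, radii = (row.cz, row.cy, row.cx), (row.rz, row.ry, row.rx)
        lo, hi = cfg.telomeres_per_cell
        n_tel = int(rng.integers(lo, hi + 1))
        cell_tel = []
        for _ in range(n_tel):
            pos = _sample_in_ellipsoid(rng, center, radii)
            length = float(rng.lognormal(cfg.length_log_mu, cfg.length_log_sigma))
            total = cfg.intensity_per_length * length
            is_doublet = bool(rng.random() < cfg.p_doublet)
            if is_doublet:
                sep = rng.uniform(0.5, 1.5) * fwhm_xy_vox
                theta = rng.uniform(0, 2 * math.pi)
                off = np.array([0.0, math.sin(theta), math.cos(theta)]) * sep / 2.0
                _render_spot(stack[1], pos - off, sigma_vox, total / 2.0)
                _render_spot(stack[1], pos + off, sigma_vox, total / 2.0)
            else:
                _render_spot(stack[1], pos, sigma_vox, total)
            rec = {
                "object_id": object_id, "cell_id": row.cell_id,
                "channel": CHANNEL_TELOMERE,
                "z_um": pos[0] * vs[0], "y_um": pos[1] * vs[1], "x_um": pos[2] * vs[2],
                "length": length, "intensity": total,
                "is_doublet": is_doublet, "partner_object_id": -1,
            }
            foci_rows.append(rec)
            cell_tel.append({"object_id": object_id, "pos": pos, "length": length})
            object_id += 1
        tel_by_cell[row.cell_id] = cell_tel

    # RNA spots: channel A per p(length); channel B co-places with A spots
    jitter_vox = 0.05 / vs  # 0.05 μm placement jitter at a telomere
    for ci, cname in enumerate(names[2:], start=2):
        for row in nuclei.itertuples():
            center, radii = (row.cz, row.cy, row.cx), (row.rz, row.ry, row.rx)
            lo, hi = cfg.rna_spots_per_cell
            n_rna = int(rng.integers(lo, hi + 1))
            cell_tel = tel_by_cell[row.cell_id]
            a_spots = [r for r in foci_rows
                       if r["cell_id"] == row.cell_id and r["channel"] == CHANNEL_RNA_A]
            for _ in range(n_rna):
                partner = -1
                pos = None
                if cname == CHANNEL_RNA_B and a_spots and rng.random() < cfg.p_rna_pair:
                    a = a_spots[int(rng.integers(0, len(a_spots)))]
                    pos = np.array([a["z_um"], a["y_um"], a["x_um"]]) / vs \
                        + rng.normal(0, 1, 3) * jitter_vox
                    partner = a["partner_object_id"]
                elif cell_tel:
                    t = cell_tel[int(rng.integers(0, len(cell_tel)))]
                    if rng.random() < p_fn(t["length"]):
                        pos = t["pos"] + rng.normal(0, 1, 3) * jitter_vox
                        partner = t["object_id"]
                if pos is None:
                    pos = _sample_in_ellipsoid(rng, center, radii)
                _render_spot(stack[ci], pos, sigma_vox, cfg.rna_intensity)
                foci_rows.append(
                    {
                        "object_id": object_id, "cell_id": row.cell_id, "channel": cname,
                        "z_um": pos[0] * vs[0], "y_um": pos[1] * vs[1], "x_um": pos[2] * vs[2],
                        "length": np.nan, "intensity": cfg.rna_intensity,
                        "is_doublet": False, "partner_object_id": partner,
                    }
                )
                object_id += 1

    stack[1:] += cfg.background
    img = _apply_noise(stack, cfg.poisson_gain, cfg.read_sigma, rng)

    nuclei_um = nuclei.copy()
    for col, ax in (("cz", 0), ("cy", 1), ("cx", 2)):
        nuclei_um[col.replace("c", "") + "_um"] = nuclei_um[col] * vs[ax]
    truth = GroundTruth(nuclei=nuclei_um, foci=pd.DataFrame(foci_rows))
    return ImageStack(img, cfg.voxel_size, None, names), truth


# ---------------------------------------------------------------------------
# dwell-time draws
# ---------------------------------------------------------------------------

def sample_dwell_times(
    n: int,
    p_fast: float,
    tau_fast: float,
    tau_slow: float,
    censor_at: float = math.inf,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw i.i.d. mixture-exponential dwell times with right-censoring.

    Returns ``(durations, censored, population)`` where ``population`` is
    ``"fast"``/``"slow"`` per draw and values ≥ ``censor_at`` are returned
    as ``censor_at`` with ``censored=True``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if tau_fast <= 0 or tau_slow <= 0:
        raise ValueError("residence times must be positive")
    if not 0.0 <= p_fast <= 1.0:
        raise ValueError("p_fast must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    fast = rng.random(n) < p_fast
    tau = np.where(fast, tau_fast, tau_slow)
    d = rng.exponential(tau)
    censored = d >= censor_at
    d = np.minimum(d, censor_at)
    pop = np.where(fast, "fast", "slow")
    return d, censored, pop


# ---------------------------------------------------------------------------
# live movie
# ---------------------------------------------------------------------------

def generate_live_movie(
    scene: SceneConfig, kin: KineticsConfig
) -> tuple[ImageStack, GroundTruth]:
    """Simulate and render a two-channel (particle, telomere) movie.

    Particles free-diffuse inside the nucleus; within ``capture_radius`` of
    a telomere they bind with per-frame probability ``1−exp(−k_on·Δt)`` and
    stay snapped to the telomere centroid (plus jitter) for a duration drawn
    from the exponential mixture. Per-frame multiplicative bleaching
    ``(1−bleach_rate)^t`` is applied to the whole rendered frame.
    """
    rng = np.random.default_rng(kin.seed)
    vs = np.asarray(scene.voxel_size)
    sigma_vox = np.asarray(scene.psf_sigma) / vs
    dt = kin.frame_interval
    n_frames = kin.n_frames

    nuclei = _nucleus_layout(scene)
    telomeres = []
    tel_id = 0
    for row in nuclei.itertuples():
        lo, hi = scene.telomeres_per_cell
        for _ in range(int(rng.integers(lo, hi + 1))):
            pos = _sample_in_ellipsoid(rng, (row.cz, row.cy, row.cx),
                                       (row.rz, row.ry, row.rx))
            length = float(rng.lognormal(scene.length_log_mu, scene.length_log_sigma))
            telomeres.append(
                {"telomere_id": tel_id, "cell_id": row.cell_id, "pos": pos,
                 "length": length,
                 "intensity": scene.intensity_per_length * length}
            )
            tel_id += 1
    if not telomeres and kin.k_on > 0:
        raise ValueError("k_on > 0 requires at least one telomere")

    tel_pos_um = np.array([t["pos"] for t in telomeres]) * vs if telomeres else \
        np.empty((0, 3))
    p_bind = 1.0 - math.exp(-kin.k_on * dt) if kin.k_on > 0 else 0.0
    sqrt_step = math.sqrt(2.0 * kin.diffusion_coeff * dt)

    def _diffuse(pos, center, radii, rng):
        """One diffusion step confined to the nucleus (resampled at the wall)."""
        for _ in range(25):
            cand = pos + rng.normal(0, 1, 3) * (sqrt_step / vs)
            if np.sum(((cand - center) / radii) ** 2) <= 1.0:
                return cand
        return pos

    track_rows: list[dict] = []
    event_rows: list[dict] = []
    track_id = 0
    for row in nuclei.itertuples():
        center = np.array([row.cz, row.cy, row.cx])
        radii = np.array([row.rz, row.ry, row.rx])
        cell_tel = [t for t in telomeres if t["cell_id"] == row.cell_id]
        for _ in range(kin.particles_per_cell):
            pos = _sample_in_ellipsoid(rng, center, radii)
            bound_left, cur_tel, cur_pop = 0, -1, ""
            start_frame = -1

            def _draw_binding():
                fast = rng.random() < kin.p_fast
                tau = kin.tau_fast if fast else kin.tau_slow
                d = float(rng.exponential(tau)) if math.isfinite(tau) else math.inf
                m = max(1, int(math.ceil(d / dt))) if math.isfinite(d) else n_frames + 1
                return ("fast" if fast else "slow"), d, m

            if kin.start_bound and cell_tel:
                t0 = cell_tel[int(rng.integers(0, len(cell_tel)))]
                cur_tel = t0["telomere_id"]
                cur_pop, d_true, bound_left = _draw_binding()
                pos = np.asarray(t0["pos"], dtype=float)
                start_frame = 0

            for f in range(n_frames):
                if bound_left > 0:
                    tel = next(t for t in cell_tel if t["telomere_id"] == cur_tel)
                    render_pos = tel["pos"] + rng.normal(0, 1, 3) * (kin.bound_jitter / vs)
                    track_rows.append(
                        {"track_id": track_id, "frame": f, "t_s": f * dt,
                         "z_um": render_pos[0] * vs[0], "y_um": render_pos[1] * vs[1],
                         "x_um": render_pos[2] * vs[2],
                         "bound": True, "telomere_id": cur_tel, "population": cur_pop}
                    )
                    bound_left -= 1
                    if bound_left == 0:
                        event_rows.append(
                            {"track_id": track_id, "telomere_id": cur_tel,
                             "start_frame": start_frame, "end_frame": f,
                             "duration_s": (f - start_frame + 1) * dt,
                             "duration_true_s": d_true, "population": cur_pop,
                             "completed": True}
                        )
                        # released: the particle diffuses away during the
                        # remainder of the frame interval
                        pos = _diffuse(np.asarray(tel["pos"], dtype=float),
                                       center, radii, rng)
                        cur_tel, cur_pop = -1, ""
                    elif f == n_frames - 1:
                        event_rows.append(
                            {"track_id": track_id, "telomere_id": cur_tel,
                             "start_frame": start_frame, "end_frame": f,
                             "duration_s": (f - start_frame + 1) * dt,
                             "duration_true_s": d_true, "population": cur_pop,
                             "completed": False}
                        )
                else:
                    track_rows.append(
                        {"track_id": track_id, "frame": f, "t_s": f * dt,
                         "z_um": pos[0] * vs[0], "y_um": pos[1] * vs[1],
                         "x_um": pos[2] * vs[2],
                         "bound": False, "telomere_id": -1, "population": ""}
                    )
                    pos = _diffuse(pos, center, radii, rng)
                    # attempt binding for the next frame
                    if cell_tel and p_bind > 0:
                        d_um = np.linalg.norm(
                            (np.array([t["pos"] for t in cell_tel]) - pos) * vs, axis=1
                        )
                        j = int(np.argmin(d_um))
                        if d_um[j] <= kin.capture_radius and rng.random() < p_bind:
                            cur_tel = cell_tel[j]["telomere_id"]
                            cur_pop, d_true, bound_left = _draw_binding()
                            start_frame = f + 1
            track_id += 1

    # render
    movie = np.zeros((n_frames, 2) + tuple(scene.image_shape), dtype=float)
    track_cols = ["track_id", "frame", "t_s", "z_um", "y_um", "x_um",
                  "bound", "telomere_id", "population"]
    tracks = pd.DataFrame(track_rows, columns=track_cols)
    for f in range(n_frames):
        par, tel = movie[f, 0], movie[f, 1]
        for t in telomeres:
            _render_spot(tel, t["pos"], sigma_vox, t["intensity"])
        sub = tracks[tracks["frame"] == f]
        for r in sub.itertuples():
            _render_spot(par, np.array([r.z_um, r.y_um, r.x_um]) / vs,
                         sigma_vox, kin.particle_intensity)
        movie[f] += scene.background
        movie[f] *= (1.0 - kin.bleach_rate) ** f
    img = _apply_noise(movie, scene.poisson_gain, scene.read_sigma, rng)

    tel_df = pd.DataFrame(
        [{"object_id": t["telomere_id"], "cell_id": t["cell_id"],
          "channel": CHANNEL_TELOMERE,
          "z_um": t["pos"][0] * vs[0], "y_um": t["pos"][1] * vs[1],
          "x_um": t["pos"][2] * vs[2],
          "length": t["length"], "intensity": t["intensity"],
          "is_doublet": False, "partner_object_id": -1}
         for t in telomeres]
    )
    nuclei_um = nuclei.copy()
    for col, ax in (("cz", 0), ("cy", 1), ("cx", 2)):
        nuclei_um[col.replace("c", "") + "_um"] = nuclei_um[col] * vs[ax]
    truth = GroundTruth(
        nuclei=nuclei_um, foci=tel_df, tracks=tracks,
        events=pd.DataFrame(event_rows) if event_rows else pd.DataFrame(
            columns=["track_id", "telomere_id", "start_frame", "end_frame",
                     "duration_s", "duration_true_s", "population", "completed"]
        ),
    )
    stack = ImageStack(img, scene.voxel_size, kin.frame_interval,
                       (CHANNEL_PARTICLE, CHANNEL_TELOMERE))
    return stack, truth


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def _tupleize(d: dict, keys) -> dict:
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def scene_config_from_yaml(path) -> SceneConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw = _tupleize(raw, ["image_shape", "voxel_size", "telomeres_per_cell",
                          "rna_spots_per_cell", "psf_sigma"])
    p = raw.get("p_rna_at_telomere")
    if isinstance(p, dict):
        raw["p_rna_at_telomere"] = saturating_affinity(
            float(p.get("l50", 5.0)), float(p.get("p_max", 1.0)))
    return SceneConfig(**raw)


def kinetics_config_from_yaml(path) -> KineticsConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return KineticsConfig(**raw)


def scene_config_to_dict(cfg: SceneConfig) -> dict:
    d = asdict(cfg)
    if callable(d.get("p_rna_at_telomere")):
        d["p_rna_at_telomere"] = "<callable>"
    return d
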