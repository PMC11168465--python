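"""Object-based colocalization with a shuffle-based spatial null.

Two foci colocalize when their voxel sets share at least one voxel index.
Significance of an observed A→B nearest-distance distribution is assessed
against ``n_shuffles`` re-placements of the B objects (rigid translations,
shapes preserved) uniformly inside the nuclear domain.

The default decision is an exchangeable rank-envelope test: the observed
CDF and the shuffled CDFs are pooled, each curve is scored by its maximum
studentized pointwise deviation from the pooled mean, and the Monte-Carlo
p-value is the rank of the observed score. Under the null this test is
exact (rejection probability ≤ α by construction). The naive
"CDF exits the pointwise 95% band anywhere" rule is available as
``decision_rule="pointwise"`` but is strongly anti-conservative (empirical
false-positive rate ≈30% in calibration runs) and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spots import Focus, NucleusMask

__all__ = [
    "OverlapPair",
    "ShuffleEnvelope",
    "CellColocReport",
    "overlap_colocalize",
    "shuffle_null",
    "triple_partition",
    "per_cell_report",
]


@dataclass
class OverlapPair:
    """A pair of foci sharing at least one voxel."""

    focus_a_id: int
    focus_b_id: int
    shared_voxels: int
    center_distance_um: float


@dataclass
class ShuffleEnvelope:
    """Observed vs shuffled nearest-distance CDFs and the significance call."""

    distance_grid: np.ndarray  # μm
    observed_cdf: np.ndarray
    mean_null_cdf: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    n_shuffles: int
    p_value: float
    significant: bool
    decision_rule: str = "rank_envelope"

    @property
    def decision(self) -> str:
        return "significant" if self.significant else "not_significant"


@dataclass
class CellColocReport:
    """Per-cell colocalization counts."""

    cell_id: int
    n_a: int
    n_b: int
    n_pairs: int
    n_pairs_telomeric: int
    n_pairs_extratelomeric: int
    n_b_telomeric_without_a: int


def _check_grids(*foci_lists: list[Focus]) -> tuple[int, int, int]:
    shapes = {f.grid_shape for fl in foci_lists for f in fl}
    if len(shapes) > 1:
        raise ValueError(f"foci live on mismatched voxel grids: {shapes}")
    return next(iter(shapes)) if shapes else (0, 0, 0)


def _voxel_key(voxels: np.ndarray, shape) -> np.ndarray:
    return np.ravel_multi_index((voxels[:, 0], voxels[:, 1], voxels[:, 2]), shape)


def overlap_colocalize(A: list[Focus], B: list[Focus]) -> list[OverlapPair]:
    """All (a, b) pairs whose voxel sets intersect.

    An A focus may pair with multiple B foci and vice versa. Distances are
    centroid-to-centroid in μm.
    """
    if not A or not B:
        return []
    shape = _check_grids(A, B)
    b_lookup: dict[int, list[int]] = {}
    for j, b in enumerate(B):
        for key in _voxel_key(b.voxels, shape):
            b_lookup.setdefault(int(key), []).append(j)
    pairs: list[OverlapPair] = []
    for a in A:
        shared: dict[int, int] = {}
        for key in _voxel_key(a.voxels, shape):
            for j in b_lookup.get(int(key), ()):
                shared[j] = shared.get(j, 0) + 1
        for j, count in sorted(shared.items()):
            b = B[j]
            pairs.append(
                OverlapPair(
                    a.object_id,
                    b.object_id,
                    count,
                    float(np.linalg.norm(a.centroid_um - b.centroid_um)),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# shuffle null
# ---------------------------------------------------------------------------

def _valid_anchor_positions(domain: np.ndarray, rel: np.ndarray) -> np.ndarray:
    """Voxel positions p such that every p + offset lies inside ``domain``.

    ``rel`` are voxel offsets relative to the anchor (the bounding-box
    minimum of the object's voxel set).
    """
    ext = rel.max(axis=0) + 1
    nz, ny, nx = domain.shape
    ez, ey, ex = int(ext[0]), int(ext[1]), int(ext[2])
    valid = np.zeros_like(domain)
    if nz >= ez and ny >= ey and nx >= ex:
        acc = np.ones((nz - ez + 1, ny - ey + 1, nx - ex + 1), dtype=bool)
        for dz, dy, dx in rel:
            acc &= domain[dz : dz + nz - ez + 1, dy : dy + ny - ey + 1, dx : dx + nx - ex + 1]
        valid[: nz - ez + 1, : ny - ey + 1, : nx - ex + 1] = acc
    return np.argwhere(valid)


def _nearest_distance_set(a_centroids: np.ndarray, b_centroids: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(a_centroids[:, None, :] - b_centroids[None, :, :], axis=2)
    return d.min(axis=1)


def _cdf_on_grid(dists: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(dists), grid, side="right") / dists.size


def _max_studentized_deviation(curves: np.ndarray) -> np.ndarray:
    """Per-curve max |curve − pooled mean| / pooled sd; sd==0 points score 0."""
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(curves - mean[None, :]) / sd[None, :]
    dev[:, sd == 0] = 0.0
    return dev.max(axis=1)


def shuffle_null(
    A: list[Focus],
    B: list[Focus],
    domain: NucleusMask | np.ndarray,
    n_shuffles: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
    n_grid: int = 64,
    decision_rule: str = "rank_envelope",
    max_retries: int = 1000,
) -> ShuffleEnvelope:
    """Shuffle-based significance of the observed A→B nearest-distance CDF.

    Each shuffle rigidly translates every B object to a uniformly random
    position whose full voxel set stays inside ``domain``. The envelope
    fields hold the pointwise mean and 2.5/97.5 percentiles of the shuffled
    CDFs; the significance decision follows ``decision_rule``
    (``"rank_envelope"`` exact Monte-Carlo test, or ``"pointwise"``).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not A or not B:
        raise ValueError("both object lists must be non-empty")
    if decision_rule not in ("rank_envelope", "pointwise"):
        raise ValueError(f"unknown decision_rule {decision_rule!r}")
    mask = domain.mask if isinstance(domain, NucleusMask) else np.asarray(domain, bool)
    _check_grids(A, B)
    rng = np.random.default_rng(seed)
    vs = np.asarray(B[0].voxel_size)

    # precompute valid anchors per distinct object shape
    anchors_cache: dict[bytes, np.ndarray] = {}
    b_shapes = []
    for b in B:
        rel = b.voxels - b.voxels.min(axis=0)
        key = rel.astype(np.int32).tobytes()
        if key not in anchors_cache:
            anchors = _valid_anchor_positions(mask, rel)
            if anchors.shape[0] == 0:
                raise ValueError(
                    f"object {b.object_id} does not fit inside the domain"
                )
            anchors_cache[key] = anchors
        # centroid offset from the anchor, physical
        centroid_rel = (b.voxels.mean(axis=0) - b.voxels.min(axis=0)) * vs
        b_shapes.append((key, centroid_rel))

    a_centroids = np.array([a.centroid_um for a in A])
    b_centroids = np.array([b.centroid_um for b in B])
    obs_d = _nearest_distance_set(a_centroids, b_centroids)

    # distance grid spanning observed + the domain scale
    span = float(np.max(np.asarray(mask.shape) * vs))
    grid = np.linspace(0.0, max(span, float(obs_d.max()) + 1e-9), n_grid)
    observed_cdf = _cdf_on_grid(obs_d, grid)

    null_cdfs = np.empty((n_shuffles, n_grid))
    for s in range(n_shuffles):
        new_centroids = np.empty_like(b_centroids)
        for j, (key, centroid_rel) in enumerate(b_shapes):
            anchors = anchors_cache[key]
            anchor = anchors[rng.integers(0, anchors.shape[0])]
            new_centroids[j] = anchor * vs + centroid_rel
        null_cdfs[s] = _cdf_on_grid(
            _nearest_distance_set(a_centroids, new_centroids), grid
        )

    mean_null = null_cdfs.mean(axis=0)
    # clipped so the band always brackets the mean (discrete CDF values can
    # push a percentile past the mean when a single shuffle is an outlier)
    lower95 = np.minimum(np.percentile(null_cdfs, 2.5, axis=0), mean_null)
    upper95 = np.maximum(np.percentile(null_cdfs, 97.5, axis=0), mean_null)

    if decision_rule == "pointwise":
        significant = bool(
            np.any((observed_cdf < lower95) | (observed_cdf > upper95))
        )
        p_value = float("nan")
    else:
        pooled = np.vstack([observed_cdf[None, :], null_cdfs])
        scores = _max_studentized_deviation(pooled)
        p_value = float(np.sum(scores >= scores[0]) / pooled.shape[0])
        significant = bool(p_value <= alpha)

    return ShuffleEnvelope(
        grid, observed_cdf, mean_null, lower95, upper95,
        n_shuffles, p_value, significant, decision_rule,
    )


# ---------------------------------------------------------------------------
# triple partitions and per-cell reports
# ---------------------------------------------------------------------------

def triple_partition(
    pairs_ab: list[OverlapPair],
    A: list[Focus],
    B: list[Focus],
    C: list[Focus],
) -> tuple[dict[tuple[int, int], str], list[int]]:
    """Split A∩B pairs into telomeric/extratelomeric against channel C.

    A pair is ``"telomeric"`` iff the union of its two voxel sets shares at
    least one voxel with some C focus. Also returns the ids of B foci that
    overlap C but no A focus (telomere-bound B without A).
    """
    shape = _check_grids(A, B, C)
    a_by_id = {f.object_id: f for f in A}
    b_by_id = {f.object_id: f for f in B}
    c_keys: set[int] = set()
    for c in C:
        c_keys.update(int(k) for k in _voxel_key(c.voxels, shape))

    labels: dict[tuple[int, int], str] = {}
    for p in pairs_ab:
        union = np.vstack([a_by_id[p.focus_a_id].voxels, b_by_id[p.focus_b_id].voxels])
        keys = {int(k) for k in _voxel_key(union, shape)}
        labels[(p.focus_a_id, p.focus_b_id)] = (
            "telomeric" if keys & c_keys else "extratelomeric"
        )

    paired_b = {p.focus_b_id for p in pairs_ab}
    bc_pairs = overlap_colocalize(B, C)
    b_with_c = {p.focus_a_id for p in bc_pairs}
    b_telomeric_without_a = sorted(b_with_c - paired_b)
    return labels, b_telomeric_without_a


def per_cell_report(
    foci_by_channel: dict[str, list[Focus]],
    pairs_ab: list[OverlapPair],
    partition_labels: dict[tuple[int, int], str] | None = None,
    b_telomeric_without_a: list[int] | None = None,
    channel_a: str = "rna_a",
    channel_b: str = "rna_b",
    cell_ids: list[int] | None = None,
    histogram_cap: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell colocalization counts plus cohort summaries.

    Cohort summary reports the percentage of cells with ≥1 A∩B pair, the
    pairs-per-cell histogram with a final aggregated ``≥cap`` bin, and the
    fraction of pairs at telomeres (when a partition is supplied).
    """
    A = foci_by_channel.get(channel_a, [])
    B = foci_by_channel.get(channel_b, [])
    a_cell = {f.object_id: f.cell_id for f in A}
    b_cell = {f.object_id: f.cell_id for f in B}
    if cell_ids is None:
        cell_ids = sorted(
            {f.cell_id for fl in foci_by_channel.values() for f in fl if f.cell_id >= 0}
        )
    partition_labels = partition_labels or {}
    b_telomeric_without_a = b_telomeric_without_a or []

    rows = []
    for cid in cell_ids:
        cell_pairs = [
            p for p in pairs_ab
            if a_cell.get(p.focus_a_id, b_cell.get(p.focus_b_id, -1)) == cid
        ]
        n_tel = sum(
            partition_labels.get((p.focus_a_id, p.focus_b_id)) == "telomeric"
            for p in cell_pairs
        )
        n_ext = sum(
            partition_labels.get((p.focus_a_id, p.focus_b_id)) == "extratelomeric"
            for p in cell_pairs
        )
        rows.append(
            CellColocReport(
                cell_id=cid,
                n_a=sum(1 for f in A if f.cell_id == cid),
                n_b=sum(1 for f in B if f.cell_id == cid),
                n_pairs=len(cell_pairs),
                n_pairs_telomeric=n_tel,
                n_pairs_extratelomeric=n_ext,
                n_b_telomeric_without_a=sum(
                    1 for oid in b_telomeric_without_a if b_cell.get(oid, -1) == cid
                ),
            )
        )
    table = pd.DataFrame([r.__dict__ for r in rows])

    counts = table["n_pairs"].to_numpy() if len(table) else np.array([], dtype=int)
    hist_labels = [str(i) for i in range(histogram_cap)] + [f">={histogram_cap}"]
    hist = {lab: 0 for lab in hist_labels}
    for c in counts:
        hist[str(int(c)) if c < histogram_cap else f">={histogram_cap}"] += 1
    n_labelled = len(partition_labels)
    summary = {
        "n_cells": len(table),
        "pct_cells_with_pair": (
            100.0 * float(np.mean(counts >= 1)) if len(counts) else float("nan")
        ),
        "pairs_per_cell_histogram": hist,
        "telomeric_fraction": (
            sum(v == "telomeric" for v in partition_labels.values()) / n_labelled
            if n_labelled else float("nan")
        ),
        "n_pairs_total": int(counts.sum()) if len(counts) else 0,
    }
    return table, summary
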