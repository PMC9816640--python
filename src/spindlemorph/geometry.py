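"""Geometric quantities derived from a spindle spatial graph.

All lengths are in nm unless noted.  The central coordinate for minus-end
analyses is the relative distance ``D`` along the half-spindle axis: 0 at the
mother centriole of the nearest pole, 1 at the kinetochore (for KMTs) or at
the average kinetochore position (for non-KMTs).  ``D`` is obtained by
orthogonal projection onto that axis and is deliberately not clamped: values
outside [0, 1] are real geometry and are excluded only at the binning stage.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .graph_io import Kinetochore, MicrotubuleTrack, Pole, SpindleReconstruction


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Z-correction
# ---------------------------------------------------------------------------


def apply_z_correction(
    recon: SpindleReconstruction,
    nominal_thickness_nm: float,
    n_sections: int,
    measured_total_nm: float,
) -> SpindleReconstruction:
    """Expand the stack in Z to correct for plastic-section collapse.

    The correction factor is ``(nominal_thickness_nm * n_sections) /
    measured_total_nm``; every z coordinate (track points and centrioles) is
    multiplied by it, x and y are untouched, and the factor is recorded in
    ``metadata["z_factor"]``.
    """
    if nominal_thickness_nm <= 0 or n_sections <= 0 or measured_total_nm <= 0:
        raise GeometryError("Z-correction inputs must all be positive")
    factor = (nominal_thickness_nm * n_sections) / measured_total_nm
    out = copy.deepcopy(recon)
    for t in out.tracks:
        t.points[:, 2] *= factor
    for p in out.poles:
        p.mother[2] *= factor
        p.daughter[2] *= factor
    out.metadata["z_factor"] = factor
    return out


# ---------------------------------------------------------------------------
# polarity and positions
# ---------------------------------------------------------------------------


@dataclass
class PolarizedEnd:
    track_id: str
    polarity: str  # "plus" | "minus"
    position: np.ndarray
    relative_distance: float = np.nan  # D, unitless
    absolute_distance_nm: float = np.nan
    nearest_pole: str | None = None
    tie_flag: bool = False


def assign_polarity(
    track: MicrotubuleTrack, recon: SpindleReconstruction
) -> tuple[PolarizedEnd, PolarizedEnd]:
    """Assign plus/minus polarity to the two ends of a track.

    KMT: the kinetochore-associated end is the plus end.  non-KMT: the end
    closer to the nearest mother centriole is the minus end; an exact tie
    makes end_a the minus end with ``tie_flag`` set.

    Returns ``(plus, minus)``.
    """
    if track.mt_class == "KMT":
        n_assoc = int(track.end_a.kinetochore_associated) + int(track.end_b.kinetochore_associated)
        if n_assoc != 1:
            raise GeometryError(
                f"KMT {track.track_id}: expected exactly one kinetochore-associated end, "
                f"found {n_assoc}"
            )
        if track.end_a.kinetochore_associated:
            plus_pos, minus_pos = track.point_a, track.point_b
        else:
            plus_pos, minus_pos = track.point_b, track.point_a
        return (
            PolarizedEnd(track.track_id, "plus", plus_pos),
            PolarizedEnd(track.track_id, "minus", minus_pos),
        )

    if not recon.poles:
        raise GeometryError("polarity of a non-KMT requires at least one pole")
    d_a = min(float(np.linalg.norm(track.point_a - p.mother)) for p in recon.poles)
    d_b = min(float(np.linalg.norm(track.point_b - p.mother)) for p in recon.poles)
    tie = d_a == d_b
    if d_a <= d_b:
        minus_pos, plus_pos = track.point_a, track.point_b
    else:
        minus_pos, plus_pos = track.point_b, track.point_a
    return (
        PolarizedEnd(track.track_id, "plus", plus_pos),
        PolarizedEnd(track.track_id, "minus", minus_pos, tie_flag=tie),
    )


def relative_position(end_pos: np.ndarray, pole: Pole, reference_pos: np.ndarray) -> float:
    """Normalized position D of a point on the mother-centriole → reference axis.

    D = ((end − mother) · (reference − mother)) / ‖reference − mother‖²;
    0 at the mother centriole, 1 at the reference (kinetochore or average
    kinetochore).  Not clamped.
    """
    axis = np.asarray(reference_pos, float) - pole.mother
    denom = float(axis @ axis)
    if denom == 0.0:
        raise GeometryError("zero-length half-spindle axis (reference == mother centriole)")
    return float((np.asarray(end_pos, float) - pole.mother) @ axis / denom)


def absolute_pole_distance(end_pos: np.ndarray, poles: list[Pole]) -> float:
    """3D distance (nm) of a point to the nearest mother centriole."""
    if not poles:
        raise GeometryError("at least one pole required")
    return min(float(np.linalg.norm(np.asarray(end_pos, float) - p.mother)) for p in poles)


def nearest_pole(end_pos: np.ndarray, poles: list[Pole]) -> Pole:
    if not poles:
        raise GeometryError("at least one pole required")
    return min(poles, key=lambda p: float(np.linalg.norm(np.asarray(end_pos, float) - p.mother)))


# ---------------------------------------------------------------------------
# kinetochores
# ---------------------------------------------------------------------------


def kinetochore_center(kinetochore: Kinetochore, recon: SpindleReconstruction) -> np.ndarray:
    """Component-wise median of the kinetochore's KMT plus-end positions."""
    if not kinetochore.kmt_track_ids:
        raise GeometryError(f"kinetochore {kinetochore.kinetochore_id} has no KMTs")
    plus_positions = []
    for tid in kinetochore.kmt_track_ids:
        track = recon.track_by_id(tid)
        plus, _ = assign_polarity(track, recon)
        plus_positions.append(plus.position)
    return np.median(np.asarray(plus_positions), axis=0)


def average_kinetochore_position(recon: SpindleReconstruction) -> np.ndarray:
    """Mean of all kinetochore centers — the non-KMT axis reference (aK)."""
    centers = [kinetochore_center(k, recon) for k in recon.kinetochores if k.kmt_track_ids]
    if not centers:
        raise GeometryError("no kinetochores with KMTs")
    return np.mean(np.asarray(centers), axis=0)


def interkinetochore_distance(pair: tuple[Kinetochore, Kinetochore],
                              recon: SpindleReconstruction) -> float:
    """3D distance between sister-kinetochore centers, in µm."""
    a, b = pair
    ca = kinetochore_center(a, recon)
    cb = kinetochore_center(b, recon)
    return float(np.linalg.norm(ca - cb)) / 1000.0


def sister_pairs(recon: SpindleReconstruction) -> list[tuple[Kinetochore, Kinetochore]]:
    """Each sister pair once, ordered by the lexicographically smaller id."""
    by_id = {k.kinetochore_id: k for k in recon.kinetochores}
    pairs = []
    for k in recon.kinetochores:
        if k.sister_id is not None and k.kinetochore_id < k.sister_id and k.sister_id in by_id:
            pairs.append((k, by_id[k.sister_id]))
    return pairs


def kmts_per_fiber(recon: SpindleReconstruction) -> pd.Series:
    """Number of KMT tracks per fiber id (fibers with zero KMTs absent)."""
    counts: dict[str, int] = {}
    for t in recon.tracks:
        if t.mt_class == "KMT" and t.fiber_id is not None:
            counts[t.fiber_id] = counts.get(t.fiber_id, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# tortuosity
# ---------------------------------------------------------------------------


def arc_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(np.asarray(points, float), axis=0), axis=1)))


def tortuosity(track: MicrotubuleTrack | np.ndarray) -> float:
    """Polyline arc length divided by end-to-end 3D distance (≥ 1)."""
    pts = track.points if isinstance(track, MicrotubuleTrack) else np.asarray(track, float)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0.0:
        raise GeometryError("tortuosity undefined for coincident endpoints")
    return arc_length(pts) / chord


# ---------------------------------------------------------------------------
# minus-end density and interaction area
# ---------------------------------------------------------------------------


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float  # KDE factor (unitless, multiplies the data std)
    peak_position: float


def minus_end_density(
    d_values: np.ndarray,
    bandwidth_rule: str | float = "scott",
    n_grid: int = 512,
) -> DensityCurve:
    """Gaussian kernel density of minus-end relative positions.

    The grid spans [min(0, data min), max(1, data max)] padded by five
    bandwidths so the trapezoid integral over the grid is ≈ 1.  The peak is
    the grid argmax.  Bandwidth by Scott's rule unless a numeric factor is
    given.
    """
    d = np.asarray(d_values, float)
    if np.unique(d).size < 2:
        raise GeometryError("density needs at least 2 distinct values")
    kde = stats.gaussian_kde(d, bw_method=bandwidth_rule)
    h = float(kde.factor) * float(np.std(d, ddof=1))
    lo = min(0.0, float(d.min())) - 5 * h
    hi = max(1.0, float(d.max())) + 5 * h
    grid = np.linspace(lo, hi, n_grid)
    dens = kde(grid)
    return DensityCurve(grid, dens, float(kde.factor), float(grid[int(np.argmax(dens))]))


@dataclass
class InteractionArea:
    upper_bound: float  # D value
    method: str  # "fixed" | "density_derived"


def interaction_area(
    density_curve: DensityCurve | None = None,
    method: str = "fixed",
    fixed_bound: float = 0.2,
) -> InteractionArea:
    """The pole-proximal region where minus ends concentrate.

    ``fixed``: the configured constant bound (default D < 0.2).
    ``density_derived``: fit a Gaussian to the pole-proximal density peak and
    take μ + 2·HWHM with HWHM = σ√(2 ln 2) ("twice the half-width").
    """
    if method == "fixed":
        return InteractionArea(fixed_bound, "fixed")
    if method != "density_derived":
        raise GeometryError(f"unknown interaction-area method {method!r}")
    if density_curve is None:
        raise GeometryError("density_derived method requires a density curve")

    grid, dens = density_curve.grid, density_curve.density
    i_peak = int(np.argmax(dens))
    # contiguous region around the peak above 10% of the peak height
    thr = 0.1 * dens[i_peak]
    lo = i_peak
    while lo > 0 and dens[lo - 1] > thr:
        lo -= 1
    hi = i_peak
    while hi < len(dens) - 1 and dens[hi + 1] > thr:
        hi += 1
    if hi - lo < 4:
        raise GeometryError("no resolvable pole-proximal density peak")
    x, y = grid[lo : hi + 1], dens[lo : hi + 1]
    sigma0 = max((x[-1] - x[0]) / 4, 1e-3)

    def gauss(x, a, mu, sigma):
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            gauss, x, y, p0=[dens[i_peak], grid[i_peak], sigma0], maxfev=10000
        )
    except RuntimeError as e:  # pragma: no cover
        raise GeometryError(f"Gaussian peak fit failed: {e}") from e
    mu, sigma = float(popt[1]), abs(float(popt[2]))
    hwhm = sigma * np.sqrt(2 * np.log(2))
    return InteractionArea(mu + 2 * hwhm, "density_derived")


# ---------------------------------------------------------------------------
# angles and QC
# ---------------------------------------------------------------------------


def spindle_angle(vertex: np.ndarray, ray_end_1: np.ndarray, ray_end_2: np.ndarray) -> float:
    """Angle in degrees at *vertex* between the rays to the two end points."""
    v1 = np.asarray(ray_end_1, float) - np.asarray(vertex, float)
    v2 = np.asarray(ray_end_2, float) - np.asarray(vertex, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("zero-length ray")
    c = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


@dataclass
class ZUniformity:
    counts: np.ndarray  # endpoints per section
    cv: float
    flagged: bool
    threshold: float


def endpoint_z_uniformity(
    recon: SpindleReconstruction,
    section_boundaries: np.ndarray,
    cv_threshold: float = 0.5,
) -> ZUniformity:
    """Stitching QC: MT endpoints should be roughly uniform along Z.

    Counts track endpoints per Z interval (intervals left-closed, last one
    closed) and reports the coefficient of variation sd/mean of the counts.
    """
    edges = np.asarray(section_boundaries, float)
    if edges.size < 3:
        raise GeometryError("at least 2 sections required")
    zs = np.array([z for t in recon.tracks for z in (t.point_a[2], t.point_b[2])])
    if zs.size == 0:
        raise GeometryError("no endpoints")
    counts, _ = np.histogram(zs, bins=edges)
    mean = counts.mean()
    cv = float(counts.std(ddof=0) / mean) if mean > 0 else float("inf")
    return ZUniformity(counts, cv, cv > cv_threshold, cv_threshold)


# ---------------------------------------------------------------------------
# the per-end summary table
# ---------------------------------------------------------------------------


def ends_table(recon: SpindleReconstruction) -> pd.DataFrame:
    """Tidy per-end table: one row per (track end, observer label).

    Columns: track_id, mt_class, fiber_id, polarity, D, absolute_distance_nm,
    nearest_pole, tie_flag, observer_id, morphology, condition, cell_id.
    Ends without morphology labels appear once with empty observer/morphology.
    D uses the track's own kinetochore center (KMT) or the average kinetochore
    position (non-KMT) as the axis reference and the nearest pole's mother
    centriole as origin.
    """
    try:
        ak = average_kinetochore_position(recon)
    except GeometryError:
        ak = None
    kin_center_cache: dict[str, np.ndarray] = {}
    track_to_kin: dict[str, Kinetochore] = {}
    for k in recon.kinetochores:
        for tid in k.kmt_track_ids:
            track_to_kin[tid] = k

    rows = []
    for t in recon.tracks:
        plus, minus = assign_polarity(t, recon)
        for end in (plus, minus):
            pole = nearest_pole(end.position, recon.poles)
            end.nearest_pole = pole.pole_id
            end.absolute_distance_nm = absolute_pole_distance(end.position, recon.poles)
            if t.mt_class == "KMT" and t.track_id in track_to_kin:
                k = track_to_kin[t.track_id]
                if k.kinetochore_id not in kin_center_cache:
                    kin_center_cache[k.kinetochore_id] = kinetochore_center(k, recon)
                ref = kin_center_cache[k.kinetochore_id]
            else:
                ref = ak
            end.relative_distance = (
                relative_position(end.position, pole, ref) if ref is not None else np.nan
            )
            # which EndAnnotation belongs to this physical end
            ann = t.end_a if np.array_equal(end.position, t.point_a) else t.end_b
            labels = sorted(ann.morphology_by_observer.items()) or [("", "")]
            for obs, morph in labels:
                rows.append(
                    {
                        "track_id": t.track_id,
                        "mt_class": t.mt_class,
                        "fiber_id": t.fiber_id or "",
                        "polarity": end.polarity,
                        "D": end.relative_distance,
                        "absolute_distance_nm": end.absolute_distance_nm,
                        "nearest_pole": end.nearest_pole,
                        "tie_flag": end.tie_flag,
                        "observer_id": obs,
                        "morphology": morph,
                        "condition": recon.condition,
                        "cell_id": recon.cell_id,
                    }
                )
    return pd.DataFrame(rows)
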