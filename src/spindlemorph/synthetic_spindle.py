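"""Synthetic metaphase-spindle generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: two poles
with mother/daughter centrioles on the spindle axis, sister-kinetochore pairs
on a central plate (separation ≈ 1.06 ± 0.21 µm), zero-truncated-Poisson KMT
counts per fiber, minus-end relative positions from a pole-proximal
Normal/uniform mixture, a smooth logistic truth curve p_open(D), two
observers with logit-scale offsets, and an undefined-label fraction.
Everything is reproducible given the seed, and the generating parameters are
returned as a :class:`GroundTruth` so recovery tests can compare against
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .graph_io import (
    EndAnnotation,
    Kinetochore,
    MicrotubuleTrack,
    Pole,
    SpindleReconstruction,
)


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    seed: int = 20220815
    condition: str = "control"
    cell_id: str = "synthetic"
    n_fibers: int = 40  # number of kinetochores (= k-fibers); pairs of two
    kmt_rate: float = 9.19  # Poisson mean before zero-truncation
    n_nonkmt: int = 200
    pole_separation_um: float = 10.0
    plate_radius_um: float = 1.5
    interkinetochore_mean_um: float = 1.06
    interkinetochore_sd_um: float = 0.21
    daughter_offset_um: float = 0.25
    # minus-end position law: w * Normal(mu_d, sigma_d) + (1-w) * Uniform(0, 1)
    minus_peak_mu: float = 0.03
    minus_peak_sigma: float = 0.04
    minus_peak_weight: float = 0.7
    # truth curve on the logit scale: logit p_open(D) = intercept + slope * D
    truth_logit_intercept: float = 0.17
    truth_logit_slope: float = -0.5
    observer_offsets: dict[str, float] = field(
        default_factory=lambda: {"obs1": 0.3, "obs2": -0.3}
    )
    undefined_rate: float = 0.10
    tortuosity_target: float = 1.05
    n_polyline_points: int = 15
    end_jitter_nm: float = 50.0
    # optional Z-collapse emulation for testing the correction
    n_sections: int | None = None
    nominal_thickness_nm: float = 300.0
    collapse_factor: float = 1.0  # measured/nominal thickness ratio


@dataclass
class GroundTruth:
    """Everything needed to recompute every expected statistic."""

    config: GeneratorConfig
    p_open_params: tuple[float, float]  # (intercept, slope) on the logit scale
    observer_offsets: dict[str, float]
    minus_end_D: pd.DataFrame  # track_id, mt_class, fiber_id, D_true, true_open
    interkinetochore_um: np.ndarray
    kmts_per_fiber: dict[str, int]

    def p_open(self, d: np.ndarray) -> np.ndarray:
        a, b = self.p_open_params
        return special.expit(a + b * np.asarray(d, float))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = _unit(v)
    r = rng.standard_normal(3)
    r -= (r @ u) * u
    n = np.linalg.norm(r)
    if n < 1e-12:  # pragma: no cover
        r = np.cross(u, [1.0, 0.0, 0.0])
        n = np.linalg.norm(r)
    return r / n


def _bow_polyline(p0: np.ndarray, p1: np.ndarray, bow: np.ndarray, n_pts: int) -> np.ndarray:
    """Quadratic Bézier-style polyline from p0 to p1 bowed toward *bow*."""
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    mid = 0.5 * (p0 + p1) + bow
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t**2 * p1


def _bow_amplitude_for_tortuosity(target: float) -> float:
    """Control-point offset (fraction of the chord) giving the target
    tortuosity for a quadratic Bézier, by bisection on a unit chord."""
    if target <= 1.0:
        return 0.0
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([1.0, 0.0, 0.0])
    up = np.array([0.0, 1.0, 0.0])

    def tort(h: float) -> float:
        pts = _bow_polyline(p0, p1, h * up, 200)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        return seg  # chord length is 1

    lo, hi = 0.0, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if tort(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_minus_d(cfg: GeneratorConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    from_peak = rng.random(size) < cfg.minus_peak_weight
    d = np.where(
        from_peak,
        rng.normal(cfg.minus_peak_mu, cfg.minus_peak_sigma, size),
        rng.random(size),
    )
    return d


def generate_spindle(config: GeneratorConfig) -> tuple[SpindleReconstruction, GroundTruth]:
    """Build a synthetic spindle reconstruction plus its ground truth.

    Deterministic given ``config.seed``.  Distances internally in nm.
    """
    cfg = config
    if cfg.n_fibers <= 0 and cfg.n_nonkmt <= 0:
        raise GeneratorError("nothing to generate: n_fibers and n_nonkmt are both 0")
    if cfg.n_fibers > 1 and cfg.plate_radius_um <= 0:
        raise GeneratorError("plate radius must be positive for more than one kinetochore")
    if cfg.kmt_rate <= 0:
        raise GeneratorError("kmt_rate must be positive")
    rng = np.random.default_rng(cfg.seed)
    um = 1000.0  # nm per µm

    half_sep = cfg.pole_separation_um * um / 2
    poles = []
    for pole_id, x in (("P1", -half_sep), ("P2", half_sep)):
        mother = np.array([x, 0.0, 0.0])
        direction = _unit(rng.standard_normal(3))
        daughter = mother + cfg.daughter_offset_um * um * direction
        poles.append(Pole(pole_id, mother, daughter))

    bow_frac = _bow_amplitude_for_tortuosity(cfg.tortuosity_target)

    tracks: list[MicrotubuleTrack] = []
    kinetochores: list[Kinetochore] = []
    truth_rows = []
    ikd_um = []
    kmt_counts: dict[str, int] = {}
    observers = sorted(cfg.observer_offsets)

    n_pairs = cfg.n_fibers // 2
    n_single = cfg.n_fibers - 2 * n_pairs
    mt_counter = 0
    kin_counter = 0

    def new_kmt(kin_id: str, fiber_id: str, kin_pos: np.ndarray, mother: np.ndarray):
        nonlocal mt_counter
        d_true = float(_draw_minus_d(cfg, rng, 1)[0])
        axis = kin_pos - mother
        plus = kin_pos + rng.normal(0, cfg.end_jitter_nm, 3)
        minus = mother + d_true * axis
        # perpendicular jitter keeps the projected D exact
        minus = minus + rng.normal(0, cfg.end_jitter_nm) * _perpendicular(axis, rng)
        chord = np.linalg.norm(plus - minus)
        bow = bow_frac * chord * _perpendicular(plus - minus, rng)
        pts = _bow_polyline(plus, minus, bow, cfg.n_polyline_points)
        tid = f"mt_{mt_counter:05d}"
        mt_counter += 1
        track = MicrotubuleTrack(
            tid,
            "KMT",
            fiber_id,
            pts,
            end_a=EndAnnotation(kinetochore_associated=True),
            end_b=EndAnnotation(),
        )
        tracks.append(track)
        truth_rows.append({"track_id": tid, "mt_class": "KMT", "fiber_id": fiber_id, "D_true": d_true})
        return tid

    def make_kinetochore(center: np.ndarray, sister_id: str | None):
        nonlocal kin_counter
        kin_id = f"kin_{kin_counter:03d}"
        kin_counter += 1
        fiber_id = f"fiber_{kin_id}"
        # attach to the pole this kinetochore faces
        mother = poles[0].mother if center[0] < 0 else poles[1].mother
        n_kmt = 0
        while n_kmt == 0:  # zero-truncated Poisson
            n_kmt = int(rng.poisson(cfg.kmt_rate))
        tids = [new_kmt(kin_id, fiber_id, center, mother) for _ in range(n_kmt)]
        kmt_counts[fiber_id] = n_kmt
        kinetochores.append(Kinetochore(kin_id, sister_id, tids))
        return kin_id

    for _ in range(n_pairs):
        r = cfg.plate_radius_um * um * np.sqrt(rng.random())
        phi = 2 * np.pi * rng.random()
        center = np.array([rng.normal(0, 0.1 * um), r * np.cos(phi), r * np.sin(phi)])
        sep = rng.normal(cfg.interkinetochore_mean_um, cfg.interkinetochore_sd_um) * um
        ikd_um.append(sep / um)
        k1_pos = center - np.array([sep / 2, 0, 0])
        k2_pos = center + np.array([sep / 2, 0, 0])
        id1 = f"kin_{kin_counter:03d}"
        id2 = f"kin_{kin_counter + 1:03d}"
        make_kinetochore(k1_pos, id2)
        make_kinetochore(k2_pos, id1)
    for _ in range(n_single):
        r = cfg.plate_radius_um * um * np.sqrt(rng.random())
        phi = 2 * np.pi * rng.random()
        center = np.array([rng.normal(0, 0.3 * um), r * np.cos(phi), r * np.sin(phi)])
        make_kinetochore(center, None)

    # non-KMTs: span random intervals of the mother -> average-kinetochore axis
    if cfg.n_nonkmt > 0 and kinetochores:
        # same reference the analysis will use: average kinetochore position
        ak_est = np.mean(
            [np.median([tracks_by_id(tracks, tid).point_a for tid in k.kmt_track_ids], axis=0)
             for k in kinetochores],
            axis=0,
        )
    else:
        ak_est = np.zeros(3)
    for _ in range(cfg.n_nonkmt):
        pole = poles[int(rng.random() < 0.5)]
        axis = ak_est - pole.mother
        if np.linalg.norm(axis) < 1e-9:
            axis = np.array([np.sign(-pole.mother[0]) * half_sep, 0.0, 0.0])
        d_minus = float(_draw_minus_d(cfg, rng, 1)[0])
        d_plus = d_minus + float(rng.uniform(0.2, 0.8))
        minus = pole.mother + d_minus * axis
        minus = minus + rng.normal(0, cfg.end_jitter_nm) * _perpendicular(axis, rng)
        plus = pole.mother + d_plus * axis
        plus = plus + rng.normal(0, 2 * cfg.end_jitter_nm) * _perpendicular(axis, rng)
        chord = np.linalg.norm(plus - minus)
        bow = bow_frac * chord * _perpendicular(plus - minus, rng)
        pts = _bow_polyline(minus, plus, bow, cfg.n_polyline_points)
        tid = f"mt_{mt_counter:05d}"
        mt_counter += 1
        tracks.append(MicrotubuleTrack(tid, "non-KMT", None, pts))
        truth_rows.append(
            {"track_id": tid, "mt_class": "non-KMT", "fiber_id": "", "D_true": d_minus}
        )

    truth_df = pd.DataFrame(truth_rows)
    a, b = cfg.truth_logit_intercept, cfg.truth_logit_slope
    p_true = special.expit(a + b * truth_df["D_true"].to_numpy(float))
    truth_df["true_open"] = rng.random(len(truth_df)) < p_true

    section_info = None
    if cfg.n_sections is not None:
        measured = cfg.nominal_thickness_nm * cfg.n_sections * cfg.collapse_factor
        section_info = {
            "nominal_thickness_nm": cfg.nominal_thickness_nm,
            "n_sections": cfg.n_sections,
            "measured_total_nm": measured,
        }

    recon = SpindleReconstruction(
        condition=cfg.condition,
        cell_id=cfg.cell_id,
        tracks=tracks,
        poles=poles,
        kinetochores=kinetochores,
        observers=observers,
        section_info=section_info,
        metadata={"generator_seed": cfg.seed},
    )
    truth = GroundTruth(
        config=cfg,
        p_open_params=(a, b),
        observer_offsets=dict(cfg.observer_offsets),
        minus_end_D=truth_df,
        interkinetochore_um=np.asarray(ikd_um),
        kmts_per_fiber=kmt_counts,
    )
    return recon, truth


def tracks_by_id(tracks: list[MicrotubuleTrack], tid: str) -> MicrotubuleTrack:
    for t in tracks:
        if t.track_id == tid:
            return t
    raise KeyError(tid)


def generate_observations(
    recon: SpindleReconstruction,
    truth: GroundTruth,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Draw per-observer morphology labels and write them into *recon*.

    For each minus end and observer o the label is "undefined" with
    probability ``undefined_rate``, otherwise "open" with probability
    expit(logit p_open(D_true) + u_o).  KMT plus ends at kinetochores are
    always open.  Returns the observation records as a tidy DataFrame
    (columns track_id, mt_class, fiber_id, condition, polarity, observer_id,
    D, morphology).
    """
    cfg = config or truth.config
    if not cfg.observer_offsets:
        raise GeneratorError("observer list is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    a, b = truth.p_open_params
    d_by_track = dict(zip(truth.minus_end_D["track_id"], truth.minus_end_D["D_true"]))

    rows = []
    for t in recon.tracks:
        d_true = float(d_by_track[t.track_id])
        # minus end annotation: end_b for KMTs (end_a is at the kinetochore),
        # end_a for generated non-KMTs (built minus -> plus)
        minus_ann = t.end_b if t.mt_class == "KMT" else t.end_a
        for obs in sorted(cfg.observer_offsets):
            if rng.random() < cfg.undefined_rate:
                label = "undefined"
            else:
                p = special.expit(a + b * d_true + cfg.observer_offsets[obs])
                label = "open" if rng.random() < p else "closed"
            minus_ann.morphology_by_observer[obs] = label
            rows.append(
                {
                    "track_id": t.track_id,
                    "mt_class": t.mt_class,
                    "fiber_id": t.fiber_id or "",
                    "condition": recon.condition,
                    "polarity": "minus",
                    "observer_id": obs,
                    "D": d_true,
                    "morphology": label,
                }
            )
        if t.mt_class == "KMT":
            for obs in sorted(cfg.observer_offsets):
                t.end_a.morphology_by_observer[obs] = "open"
                rows.append(
                    {
                        "track_id": t.track_id,
                        "mt_class": t.mt_class,
                        "fiber_id": t.fiber_id or "",
                        "condition": recon.condition,
                        "polarity": "plus",
                        "observer_id": obs,
                        "D": 1.0,
                        "morphology": "open",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def scenario_presets() -> dict[str, GeneratorConfig]:
    """Named generator configurations.

    ``control-like``: ~226 k-fibers at 9.19 KMTs/fiber (≈ 2100 KMT minus
    ends), pole-region open proportion ≈ 53%, minus-end peak at D = 0.03.
    ``simcrs1-like``: ~106 k-fibers at 7.27 KMTs/fiber, region proportion
    ≈ 75%, peak shifted to D = 0.07, more non-KMTs sampled.  ``null``:
    identical to control-like but labeled as its own condition, for
    type-I-error checks.
    """
    control = GeneratorConfig(
        condition="control",
        n_fibers=226,
        kmt_rate=9.19,
        n_nonkmt=550,
        minus_peak_mu=0.03,
        truth_logit_intercept=0.17,
        truth_logit_slope=-0.5,
        n_sections=12,
    )
    simcrs1 = GeneratorConfig(
        condition="siMCRS1",
        n_fibers=106,
        kmt_rate=7.27,
        n_nonkmt=1550,
        minus_peak_mu=0.07,
        truth_logit_intercept=1.20,
        truth_logit_slope=-1.0,
        n_sections=12,
    )
    null = replace(control, condition="null")
    return {"control-like": control, "simcrs1-like": simcrs1, "null": null}
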