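"""End-to-end orchestration: load → Z-correct → geometry → bin → fit →
summarize → compare, with config validation and a report bundle on disk.

The pipeline runs the morphology model separately for each condition and MT
class (KMT / non-KMT), contrasts every non-reference condition against the
reference via posterior Δlog2(open/closed) draws, and adds the k-fiber
clustering LRT, the class × condition interaction test and the Poisson GLM
of KMTs per fiber when the data allow.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, aux_stats, geometry, graph_io, morphology_model as mm

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    conditions: dict[str, dict[str, str]]  # name -> {tracks, ends, landmarks}
    reference_condition: str | None = None
    apply_z_correction: bool = False
    n_bins: int = 16
    d_range: tuple[float, float] = (0.0, 1.0)
    degree: int = 3
    n_interior_knots: int = 5
    beta_prior_sd: float = 2.5
    sigma_u_prior_sd: float = 1.0
    n_walkers: int = 32
    n_adapt: int = 500
    n_steps: int = 2500
    n_burn: int = 250
    thin: int = 8
    seed: int = 20220815
    region: float = 0.2
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "d_range" in kwargs:
            kwargs["d_range"] = tuple(kwargs["d_range"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["d_range"] = list(self.d_range)
        return d


def validate_config(config: PipelineConfig | dict) -> list[str]:
    """Schema and range checks; empty list iff the config is runnable."""
    if isinstance(config, dict):
        try:
            config = PipelineConfig.from_dict(config)
        except (TypeError, ValueError) as e:
            return [f"config: {e}"]
    v = []
    if not config.conditions:
        v.append("conditions: at least one condition required")
    for name, paths in config.conditions.items():
        for key in ("tracks", "ends", "landmarks"):
            if key not in paths:
                v.append(f"conditions[{name}]: missing {key!r} path")
            elif not Path(paths[key]).exists():
                v.append(f"conditions[{name}]: no such file {paths[key]}")
    if config.n_bins < 1:
        v.append("n_bins: must be >= 1")
    if config.degree < 0:
        v.append("degree: must be >= 0")
    if config.n_interior_knots < 0:
        v.append("n_interior_knots: must be >= 0")
    if config.n_interior_knots + config.degree + 1 > config.n_bins:
        v.append("basis: more basis functions than bins")
    if not (0 < config.region <= 1):
        v.append("region: must be in (0, 1]")
    if config.d_range[0] >= config.d_range[1]:
        v.append("d_range: lower bound must be below upper bound")
    if min(config.n_walkers, config.n_steps) < 1 or config.n_burn >= config.n_steps:
        v.append("sampler: need n_walkers, n_steps >= 1 and n_burn < n_steps")
    if (
        config.reference_condition is not None
        and config.reference_condition not in config.conditions
    ):
        v.append(f"reference_condition: {config.reference_condition!r} not among conditions")
    return v


@dataclass
class ReportBundle:
    output_dir: Path
    ends_tables: dict[str, pd.DataFrame]
    region_summaries: dict[str, dict]
    comparisons: dict[str, dict]
    interaction: dict | None
    kfiber_lrt: dict | None
    kmt_glm: dict | None
    endpoint_z_qc: dict[str, dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _observations_from_ends_table(table: pd.DataFrame) -> pd.DataFrame:
    obs = table[(table["polarity"] == "minus") & (table["observer_id"] != "")]
    return obs[["track_id", "mt_class", "fiber_id", "condition", "observer_id", "D", "morphology"]]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; deterministic given ``config.seed``.

    Partial failures abort with the failing stage named.
    """
    violations = validate_config(config)
    if violations:
        raise PipelineError("validate_config", "; ".join(violations))

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    recons: dict[str, graph_io.SpindleReconstruction] = {}
    for name, paths in config.conditions.items():
        try:
            recon = graph_io.read_interchange(paths["tracks"], paths["ends"], paths["landmarks"])
        except Exception as e:
            raise PipelineError(f"load[{name}]", str(e)) from e
        problems = graph_io.validate(recon)
        if problems:
            raise PipelineError(f"load[{name}]", "; ".join(problems[:10]))
        if config.apply_z_correction:
            si = recon.section_info or {}
            try:
                recon = geometry.apply_z_correction(
                    recon,
                    si["nominal_thickness_nm"],
                    si["n_sections"],
                    si["measured_total_nm"],
                )
            except (KeyError, geometry.GeometryError) as e:
                raise PipelineError(f"z_correction[{name}]", str(e)) from e
        recons[name] = recon

    ends_tables: dict[str, pd.DataFrame] = {}
    all_obs = []
    for name, recon in recons.items():
        try:
            table = geometry.ends_table(recon)
        except geometry.GeometryError as e:
            raise PipelineError(f"geometry[{name}]", str(e)) from e
        table.to_csv(out_dir / f"ends_table_{name}.csv", index=False)
        fibers = geometry.kmts_per_fiber(recon)
        fibers.rename("n_kmts").rename_axis("fiber_id").reset_index().assign(
            condition=name
        ).to_csv(out_dir / f"fibers_{name}.csv", index=False)
        pair_rows = [
            {
                "kinetochore_id_1": a.kinetochore_id,
                "kinetochore_id_2": b.kinetochore_id,
                "distance_um": geometry.interkinetochore_distance((a, b), recon),
                "condition": name,
            }
            for a, b in geometry.sister_pairs(recon)
        ]
        pd.DataFrame(pair_rows).to_csv(out_dir / f"kinetochore_pairs_{name}.csv", index=False)
        minus_d = table.loc[table["polarity"] == "minus", ["track_id", "D"]].drop_duplicates(
            "track_id"
        )["D"].to_numpy(float)
        try:
            dens = geometry.minus_end_density(minus_d)
            pd.DataFrame({"D": dens.grid, "density": dens.density}).to_csv(
                out_dir / f"density_{name}.csv", index=False
            )
        except geometry.GeometryError:
            logger.info("condition %s: too few minus ends for a density curve", name)
        ends_tables[name] = table
        all_obs.append(_observations_from_ends_table(table))
    obs = pd.concat(all_obs, ignore_index=True)

    # stitching QC: endpoint density along Z should be roughly uniform
    z_qc: dict[str, dict] = {}
    for name, recon in recons.items():
        n_sections = (recon.section_info or {}).get("n_sections", 0)
        if n_sections and n_sections >= 2:
            zs = np.concatenate([[t.point_a[2], t.point_b[2]] for t in recon.tracks])
            edges = np.linspace(zs.min(), zs.max() + 1e-9, int(n_sections) + 1)
            qc = geometry.endpoint_z_uniformity(recon, edges)
            z_qc[name] = {
                "counts": [int(c) for c in qc.counts],
                "cv": qc.cv,
                "flagged": bool(qc.flagged),
            }

    basis = mm.build_spline_basis(
        config.n_bins, config.degree, config.n_interior_knots, config.d_range
    )
    priors = mm.Priors(config.beta_prior_sd, config.sigma_u_prior_sd)

    region_summaries: dict[str, dict] = {}
    posteriors: dict[tuple[str, str], tuple] = {}
    for i, name in enumerate(recons):
        for j, mt_class in enumerate(("KMT", "non-KMT")):
            sub = obs[(obs["condition"] == name) & (obs["mt_class"] == mt_class)]
            if sub.empty:
                continue
            key = f"{name}/{mt_class}"
            try:
                counts = mm.bin_morphology(sub, config.n_bins, config.d_range)
                logger.info(
                    "%s: binned %d ends (%d undefined, %d out of range excluded)",
                    key, int(counts.totals.sum()), counts.n_undefined, counts.n_out_of_range,
                )
                scfg = mm.SamplerConfig(
                    n_walkers=config.n_walkers,
                    n_adapt=config.n_adapt,
                    n_steps=config.n_steps,
                    n_burn=config.n_burn,
                    thin=config.thin,
                    seed=config.seed + 1000 * i + j,
                )
                post = mm.fit_end_morphology_model(counts, basis, priors, scfg)
                curve = mm.population_curve(post, basis, basis.midpoints)
                curve_df = pd.DataFrame({"D": curve.grid, "mean": curve.mean})
                for level, (lo, hi) in curve.bands.items():
                    curve_df[f"lo{level}"] = lo
                    curve_df[f"hi{level}"] = hi
                curve_df.to_csv(out_dir / f"curve_{name}_{mt_class}.csv", index=False)
                rs = mm.region_proportion(post, counts, basis, config.region)
                region_summaries[key] = {
                    "condition": name,
                    "mt_class": mt_class,
                    "region_upper_bound": rs.region_upper_bound,
                    "percent_open_mean": rs.percent_mean,
                    "percent_open_ci95": list(rs.percent_ci95),
                    "n_ends": rs.n_ends,
                    "seed": post.seed,
                    "rhat_max": post.rhat_max,
                }
                posteriors[(name, mt_class)] = (post, counts)
            except mm.ModelError as e:
                raise PipelineError(f"morphology[{key}]", str(e)) from e
    (out_dir / "region_summary.json").write_text(
        json.dumps(region_summaries, sort_keys=True, indent=2) + "\n"
    )

    reference = config.reference_condition or next(iter(recons))
    comparisons: dict[str, dict] = {}
    for name in recons:
        if name == reference:
            continue
        for mt_class in ("KMT", "non-KMT"):
            if (name, mt_class) in posteriors and (reference, mt_class) in posteriors:
                pa, ca = posteriors[(name, mt_class)]
                pb, cb = posteriors[(reference, mt_class)]
                cmp_ = mm.compare_conditions(pa, pb, ca, cb, basis, config.region)
                comparisons[f"{name}_vs_{reference}/{mt_class}"] = {
                    "delta_log2_open_closed_mean": cmp_.mean,
                    "ci95": list(cmp_.ci95),
                    "seed": pa.seed,
                }
    (out_dir / "comparison.json").write_text(
        json.dumps(comparisons, sort_keys=True, indent=2) + "\n"
    )

    kfiber_lrt = None
    kmt_obs = obs[(obs["condition"] == reference) & (obs["mt_class"] == "KMT")]
    if not kmt_obs.empty:
        try:
            stat, p = mm.kfiber_random_effect_lrt(kmt_obs)
            kfiber_lrt = {"condition": reference, "statistic": stat, "p_value": p}
        except mm.ModelError as e:
            logger.info("k-fiber LRT skipped: %s", e)

    interaction = None
    if len(recons) >= 2 and obs["mt_class"].nunique() == 2:
        other = next(n for n in recons if n != reference)
        pair_obs = obs[obs["condition"].isin([reference, other])]
        try:
            delta, p = mm.class_condition_interaction(pair_obs, config.region)
            interaction = {
                "conditions": [reference, other],
                "delta_log_odds": delta,
                "p_value": p,
            }
        except mm.ModelError as e:
            logger.info("interaction test skipped: %s", e)

    kmt_glm = None
    if len(recons) >= 2:
        frames = [
            geometry.kmts_per_fiber(r).rename("n").reset_index().assign(condition=n)
            for n, r in recons.items()
        ]
        fib = pd.concat(frames, ignore_index=True)
        if fib["condition"].nunique() >= 2 and len(fib) >= 2:
            try:
                fit = aux_stats.fit_poisson_counts(
                    fib["n"].to_numpy(), fib["condition"].to_numpy(), reference=reference
                )
                kmt_glm = fit.to_dict()
                del kmt_glm["deviance_trace"]
            except aux_stats.StatsError as e:
                logger.info("KMT-count GLM skipped: %s", e)

    config_dict = config.to_dict()
    provenance = {
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "spindlemorph_version": __version__,
        "inputs": {n: paths for n, paths in config.conditions.items()},
    }
    report = {
        "region_summaries": region_summaries,
        "comparisons": comparisons,
        "kfiber_lrt": kfiber_lrt,
        "interaction": interaction,
        "kmt_glm": kmt_glm,
        "endpoint_z_qc": z_qc,
        "provenance": provenance,
    }
    (out_dir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")

    return ReportBundle(
        output_dir=out_dir,
        ends_tables=ends_tables,
        region_summaries=region_summaries,
        comparisons=comparisons,
        interaction=interaction,
        kfiber_lrt=kfiber_lrt,
        kmt_glm=kmt_glm,
        endpoint_z_qc=z_qc,
        provenance=provenance,
    )


def simulate_to_dir(preset_name: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Generate a synthetic dataset + ground truth ready for the pipeline."""
    from dataclasses import replace

    from . import synthetic_spindle as ss

    presets = ss.scenario_presets()
    if preset_name not in presets:
        raise KeyError(
            f"unknown preset {preset_name!r}; available: {sorted(presets)}"
        )
    cfg = replace(presets[preset_name], seed=seed)
    recon, truth = ss.generate_spindle(cfg)
    ss.generate_observations(recon, truth, cfg)
    out_dir = Path(out_dir)
    paths = graph_io.write_interchange(recon, out_dir)
    truth_path = out_dir / "ground_truth.json"
    truth_payload = {
        "p_open_logit_intercept": truth.p_open_params[0],
        "p_open_logit_slope": truth.p_open_params[1],
        "observer_offsets": truth.observer_offsets,
        "undefined_rate": cfg.undefined_rate,
        "seed": cfg.seed,
        "interkinetochore_um": [float(x) for x in truth.interkinetochore_um],
        "kmts_per_fiber": truth.kmts_per_fiber,
    }
    truth_path.write_text(json.dumps(truth_payload, sort_keys=True, indent=2) + "\n")
    paths["ground_truth"] = truth_path
    return paths
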