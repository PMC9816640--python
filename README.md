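# spindlemorph

Quantitative analysis of microtubule (MT) minus-end morphology in
3D-reconstructed mitotic spindles.

Electron tomography of metaphase spindles yields spatial graphs: MT
polylines with annotated endpoints, centriole positions, and
kinetochore–microtubule associations. At single-MT resolution the
morphology of each minus end can be classified as **open** (flared or
sheet-like, suggesting a dynamic end) or **closed** (bearing an
electron-dense cap, suggesting a stabilized or γ-TuRC-capped end), with
ambiguous ends labeled *undefined*. The scientific question is how the
proportion of open minus ends varies with position in the spindle and
between experimental conditions (e.g. silencing of the minus-end regulator
MCRS1), while accounting for the fact that two human observers do not
classify identically.

`spindlemorph` provides, for researchers doing spindle ultrastructure
quantification:

- **graph_io** — a data model for spindle reconstructions, a reader for a
  subset of the Amira ASCII SpatialGraph format (with a configurable label
  map), a lossless CSV/JSON interchange format, and structural validation;
- **geometry** — Z-collapse correction, end polarity assignment, relative
  minus-end position *D* (0 at the mother centriole, 1 at the kinetochore),
  absolute pole distances, interkinetochore distances, KMTs per k-fiber,
  tortuosity, Gaussian-KDE minus-end density with peak detection, the
  pole-proximal interaction area, spindle angles, and endpoint-Z QC;
- **morphology_model** — the core inference (below), plus a likelihood-ratio
  test for clustering of morphologies within k-fibers and a binomial
  regression for the MT-class × condition interaction;
- **aux_stats** — Poisson GLM (log link, IRLS) for KMT counts, OLS angle
  models, pooled Student's t test, logarithmic tortuosity-vs-length fit;
- **synthetic_spindle** — a generator of synthetic spindles with known
  ground truth, used by every recovery and calibration test;
- **pipeline / CLI** — end-to-end orchestration with YAML configs.

## The model

Minus-end labels are binned into 16 intervals of the relative distance
*D* ∈ [0, 1]. With y<sub>bo</sub> open calls out of n<sub>bo</sub>
classified ends in bin *b* by observer *o*:

```
y[b,o] ~ Binomial(n[b,o], p[b,o])
logit p[b,o] = Σ_k B_k(mid_b) β_k + u_o
u_o ~ Normal(0, σ_u²)
β_k ~ Normal(0, 2.5),  σ_u ~ HalfNormal(1)
```

where B is a cubic b-spline basis over the bin midpoints (5 equally spaced
interior knots by default). The posterior is sampled with an
affine-invariant ensemble MCMC (`emcee`) over the spline coefficients, with
the observer offsets and their scale integrated out by quadrature; the
split-chain R-hat is reported and warned about above 1.01. Outputs are the
population-level curve p_open(D) with 95/80/50% credible bands, the
count-weighted open proportion in the pole region (D < 0.2 by default), and
condition contrasts expressed as Δlog2(open/closed) — 0 means equal open
and closed counts, +1 means twice as many open as closed.

## Worked example

```python
from spindlemorph import morphology_model as mm
from spindlemorph.synthetic_spindle import (
    scenario_presets, generate_spindle, generate_observations,
)

cfg = scenario_presets()["control-like"]      # ~226 k-fibers, 2 observers
recon, truth = generate_spindle(cfg)
obs = generate_observations(recon, truth, cfg)

kmt_minus = obs[(obs.polarity == "minus") & (obs.mt_class == "KMT")]
counts = mm.bin_morphology(kmt_minus, n_bins=16)
basis = mm.build_spline_basis(n_bins=16, degree=3, n_interior_knots=5)
post = mm.fit_end_morphology_model(counts, basis)
summary = mm.region_proportion(post, counts, basis, region=0.2)
print(f"open KMT minus ends at D < 0.2: {summary.percent_mean:.1f}% "
      f"(95% CI {summary.percent_ci95[0]:.1f}-{summary.percent_ci95[1]:.1f}%, "
      f"n = {summary.n_ends})")
```

prints

```
open KMT minus ends at D < 0.2: 52.1% (95% CI 29.3-73.6%, n = 2313)
```

i.e. about half of the pole-proximal KMT minus ends in the control-like
scenario are open — the generating truth curve puts the open proportion at
≈ 53% at the density peak — and the credible interval reflects both
binomial noise and the between-observer uncertainty. The same machinery via
the command line:

```sh
spindlemorph simulate --preset control-like --seed 11 --out data/control
spindlemorph simulate --preset simcrs1-like --seed 12 --out data/simcrs1
spindlemorph analyze --config config.yaml     # see docs/methods.md
```

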