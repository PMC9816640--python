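"""Spindle data model and I/O.

The central container is :class:`SpindleReconstruction`: microtubule tracks
(ordered 3D polylines in nm with per-end annotations), spindle poles
(mother/daughter centriole positions) and kinetochores (with their associated
KMT tracks and sister pairing).

Two on-disk representations are supported:

* a read-only subset of the Amira ASCII ``SpatialGraph`` format, the export
  format of the segmentation software used for tomographic reconstructions
  (``VertexCoordinates`` / ``EdgeConnectivity`` / ``NumEdgePoints`` /
  ``EdgePointCoordinates`` plus integer edge-label attributes mapped through a
  user-supplied label map);
* a lossless CSV/JSON interchange (``tracks.csv``, ``ends.csv``,
  ``landmarks.json``) used by the rest of the pipeline.

All coordinates are stored internally in nanometres.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MORPHOLOGIES = ("open", "closed", "undefined")
MT_CLASSES = ("KMT", "non-KMT")

TRACKS_COLUMNS = ["track_id", "mt_class", "fiber_id", "point_index", "x_nm", "y_nm", "z_nm"]
ENDS_COLUMNS = ["track_id", "end", "kinetochore_associated", "observer_id", "morphology"]


class GraphIOError(ValueError):
    """Malformed input file or schema violation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EndAnnotation:
    """Annotation of one microtubule end."""

    kinetochore_associated: bool = False
    morphology_by_observer: dict[str, str] = field(default_factory=dict)

    def copy(self) -> "EndAnnotation":
        return EndAnnotation(self.kinetochore_associated, dict(self.morphology_by_observer))


@dataclass
class MicrotubuleTrack:
    """One microtubule polyline with its two end annotations.

    ``points`` is an (n, 3) float array in nm, ordered along the polymer;
    ``end_a`` annotates ``points[0]`` and ``end_b`` annotates ``points[-1]``.
    """

    track_id: str
    mt_class: str  # "KMT" or "non-KMT"
    fiber_id: str | None
    points: np.ndarray
    end_a: EndAnnotation = field(default_factory=EndAnnotation)
    end_b: EndAnnotation = field(default_factory=EndAnnotation)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GraphIOError(f"track {self.track_id}: points must be (n, 3)")

    @property
    def point_a(self) -> np.ndarray:
        return self.points[0]

    @property
    def point_b(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class Pole:
    """A spindle pole: mother and daughter centriole positions (nm)."""

    pole_id: str
    mother: np.ndarray
    daughter: np.ndarray

    def __post_init__(self) -> None:
        self.mother = np.asarray(self.mother, dtype=float)
        self.daughter = np.asarray(self.daughter, dtype=float)


@dataclass
class Kinetochore:
    kinetochore_id: str
    sister_id: str | None
    kmt_track_ids: list[str] = field(default_factory=list)


@dataclass
class SpindleReconstruction:
    """A 3D-reconstructed (quarter or full) spindle as a spatial graph."""

    condition: str = "other"
    cell_id: str = ""
    tracks: list[MicrotubuleTrack] = field(default_factory=list)
    poles: list[Pole] = field(default_factory=list)
    kinetochores: list[Kinetochore] = field(default_factory=list)
    observers: list[str] = field(default_factory=list)
    section_info: dict | None = None
    metadata: dict = field(default_factory=dict)

    def track_by_id(self, track_id: str) -> MicrotubuleTrack:
        for t in self.tracks:
            if t.track_id == track_id:
                return t
        raise KeyError(track_id)

    def kinetochore_of_track(self, track_id: str) -> Kinetochore | None:
        for k in self.kinetochores:
            if track_id in k.kmt_track_ids:
                return k
        return None


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate(recon: SpindleReconstruction) -> list[str]:
    """Check every structural invariant; return a list of violations.

    Reports, never raises.  The empty list means the reconstruction is
    well formed.
    """
    v: list[str] = []
    seen_ids: set[str] = set()
    kmt_ids: set[str] = set()
    for t in recon.tracks:
        if t.track_id in seen_ids:
            v.append(f"track {t.track_id}: duplicate track_id")
        seen_ids.add(t.track_id)
        if len(t.points) < 2:
            v.append(f"track {t.track_id}: fewer than 2 points")
        if not np.all(np.isfinite(t.points)):
            v.append(f"track {t.track_id}: non-finite coordinates")
        elif len(t.points) >= 2 and np.any(np.all(np.diff(t.points, axis=0) == 0, axis=1)):
            v.append(f"track {t.track_id}: consecutive identical points")
        if t.mt_class not in MT_CLASSES:
            v.append(f"track {t.track_id}: unknown mt_class {t.mt_class!r}")
        if t.mt_class == "KMT":
            kmt_ids.add(t.track_id)
            if t.fiber_id is None:
                v.append(f"track {t.track_id}: KMT without fiber_id")
            if t.end_a.kinetochore_associated and t.end_b.kinetochore_associated:
                v.append(f"track {t.track_id}: both ends kinetochore-associated")
        for end_name, end in (("a", t.end_a), ("b", t.end_b)):
            for obs, morph in end.morphology_by_observer.items():
                if obs not in recon.observers:
                    v.append(f"track {t.track_id} end {end_name}: unknown observer {obs!r}")
                if morph not in MORPHOLOGIES:
                    v.append(f"track {t.track_id} end {end_name}: unknown morphology {morph!r}")

    if len(recon.poles) < 1:
        v.append("reconstruction: no poles")
    for p in recon.poles:
        if not (np.all(np.isfinite(p.mother)) and np.all(np.isfinite(p.daughter))):
            v.append(f"pole {p.pole_id}: non-finite centriole coordinates")
        elif np.array_equal(p.mother, p.daughter):
            v.append(f"pole {p.pole_id}: mother == daughter")

    kin_by_id = {k.kinetochore_id: k for k in recon.kinetochores}
    for k in recon.kinetochores:
        if k.sister_id is not None:
            sister = kin_by_id.get(k.sister_id)
            if sister is None:
                v.append(f"kinetochore {k.kinetochore_id}: dangling sister_id {k.sister_id!r}")
            elif sister.sister_id != k.kinetochore_id:
                v.append(f"kinetochore {k.kinetochore_id}: sister relation not symmetric")
        for tid in k.kmt_track_ids:
            if tid not in seen_ids:
                v.append(f"kinetochore {k.kinetochore_id}: dangling track id {tid!r}")
            elif tid not in kmt_ids:
                v.append(f"kinetochore {k.kinetochore_id}: track {tid} is not a KMT")
            else:
                t = recon.track_by_id(tid)
                if not (t.end_a.kinetochore_associated or t.end_b.kinetochore_associated):
                    v.append(
                        f"kinetochore {k.kinetochore_id}: track {tid} has no "
                        "kinetochore-associated end"
                    )
    return v


# ---------------------------------------------------------------------------
# Amira ASCII SpatialGraph (read-only subset)
# ---------------------------------------------------------------------------


@dataclass
class AmiraLabelMap:
    """Mapping from integer edge attributes to track semantics.

    ``mt_class_attribute`` names the integer EDGE attribute whose values in
    ``kmt_values`` mark a track as KMT; ``fiber_attribute`` names an integer
    EDGE attribute carrying a per-fiber id.  Unlabeled tracks default to
    non-KMT: KMT status requires positive kinetochore evidence.
    """

    mt_class_attribute: str | None = None
    kmt_values: frozenset[int] = frozenset({1})
    fiber_attribute: str | None = None
    coordinate_scale_nm: float = 1.0  # multiply file coordinates to get nm


_DEFINE_RE = re.compile(r"^(?:define\s+(\w+)\s+(\d+)|n(\w+)\s+(\d+))\s*$")
_DESCRIPTOR_RE = re.compile(
    r"^(VERTEX|EDGE|POINT)\s*\{\s*(int|float)(?:\[(\d+)\])?\s+(\w+)\s*\}\s*=?\s*@(\d+)"
)


def read_amira_spatial_graph(
    path: str | Path,
    label_map: AmiraLabelMap | None = None,
    condition: str = "other",
    cell_id: str = "",
) -> SpindleReconstruction:
    """Read the SpatialGraph subset of an AmiraMesh 3D ASCII file.

    Each EDGE becomes one :class:`MicrotubuleTrack` whose points are the
    edge's ordered ``EdgePointCoordinates`` run.  Integer edge attributes are
    mapped to mt_class / fiber ids through *label_map*.  Poles, kinetochores
    and end annotations are not part of this format subset; merge them from a
    landmarks file afterwards if available.
    """
    path = Path(path)
    if not path.exists():
        raise GraphIOError(f"no such file: {path}")
    label_map = label_map or AmiraLabelMap()
    text = path.read_text()
    lines = text.splitlines()
    if not lines or "AmiraMesh" not in lines[0] or "ASCII" not in lines[0]:
        raise GraphIOError(f"{path}: malformed header, expected '# AmiraMesh 3D ASCII'")

    counts: dict[str, int] = {}
    descriptors: dict[str, tuple[str, str, int]] = {}  # marker -> (section, name, width)
    for ln in lines:
        s = ln.strip()
        m = _DEFINE_RE.match(s)
        if m:
            name = m.group(1) or m.group(3)
            counts[name.upper()] = int(m.group(2) or m.group(4))
            continue
        m = _DESCRIPTOR_RE.match(s)
        if m:
            section, _dtype, width, name, marker = m.groups()
            descriptors[marker] = (section, name, int(width or 1))

    for required in ("VERTEX", "EDGE", "POINT"):
        if required not in counts:
            raise GraphIOError(f"{path}: missing 'define {required}' declaration")

    # numeric data blocks, keyed by @marker
    blocks: dict[str, list[float]] = {}
    current: str | None = None
    for ln in lines:
        s = ln.strip()
        if re.fullmatch(r"@(\d+)", s):
            current = s[1:]
            blocks[current] = []
            continue
        if current is not None:
            if not s or s.startswith("#"):
                continue
            try:
                blocks[current].extend(float(tok) for tok in s.split())
            except ValueError:
                current = None  # left the data section

    def get_block(name: str, section: str) -> np.ndarray:
        for marker, (sec, nm_, width) in descriptors.items():
            if nm_ == name and sec == section:
                if marker not in blocks:
                    raise GraphIOError(f"{path}: data block @{marker} ({name}) missing")
                arr = np.asarray(blocks[marker], dtype=float)
                expected = counts[section] * width
                if arr.size != expected:
                    raise GraphIOError(
                        f"{path}: {section} block {name} has {arr.size} values, "
                        f"expected {expected}"
                    )
                return arr.reshape(counts[section], width)
        raise GraphIOError(f"{path}: no {section} descriptor named {name}")

    get_block("VertexCoordinates", "VERTEX")  # presence + count check
    connectivity = get_block("EdgeConnectivity", "EDGE").astype(int)
    n_edge_points = get_block("NumEdgePoints", "EDGE").astype(int).ravel()
    edge_points = get_block("EdgePointCoordinates", "POINT")

    n_vertices = counts["VERTEX"]
    if np.any(connectivity < 0) or np.any(connectivity >= n_vertices):
        bad = int(np.argmax(np.any((connectivity < 0) | (connectivity >= n_vertices), axis=1)))
        raise GraphIOError(
            f"{path}: EdgeConnectivity edge {bad} references a vertex outside "
            f"0..{n_vertices - 1}"
        )
    if int(n_edge_points.sum()) != counts["POINT"]:
        raise GraphIOError(
            f"{path}: POINT count mismatch — NumEdgePoints sums to "
            f"{int(n_edge_points.sum())} but POINT declares {counts['POINT']}"
        )

    # optional integer edge attributes
    edge_attrs: dict[str, np.ndarray] = {}
    for marker, (sec, name, width) in descriptors.items():
        if sec == "EDGE" and name != "EdgeConnectivity" and name != "NumEdgePoints" and width == 1:
            if marker in blocks:
                edge_attrs[name] = np.asarray(blocks[marker], dtype=float).astype(int)

    scale = label_map.coordinate_scale_nm
    tracks: list[MicrotubuleTrack] = []
    offset = 0
    for i in range(counts["EDGE"]):
        npts = n_edge_points[i]
        pts = edge_points[offset : offset + npts] * scale
        offset += npts
        mt_class = "non-KMT"
        if label_map.mt_class_attribute and label_map.mt_class_attribute in edge_attrs:
            if int(edge_attrs[label_map.mt_class_attribute][i]) in label_map.kmt_values:
                mt_class = "KMT"
        fiber_id = None
        if label_map.fiber_attribute and label_map.fiber_attribute in edge_attrs:
            fiber_id = f"fiber_{int(edge_attrs[label_map.fiber_attribute][i])}"
        tracks.append(
            MicrotubuleTrack(track_id=f"mt_{i:05d}", mt_class=mt_class, fiber_id=fiber_id, points=pts)
        )

    return SpindleReconstruction(condition=condition, cell_id=cell_id, tracks=tracks)


# ---------------------------------------------------------------------------
# CSV/JSON interchange
# ---------------------------------------------------------------------------


def _fiber_str(fiber_id: str | None) -> str:
    return "" if fiber_id is None else fiber_id


def write_interchange(recon: SpindleReconstruction, out_dir: str | Path) -> dict[str, Path]:
    """Write ``tracks.csv``, ``ends.csv`` and ``landmarks.json`` to *out_dir*.

    The output is lossless and deterministic: rows are sorted by stable keys
    and JSON keys are sorted, so two writes of the same reconstruction are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    track_rows = []
    end_rows = []
    for t in sorted(recon.tracks, key=lambda t: t.track_id):
        for i, (x, y, z) in enumerate(t.points):
            track_rows.append((t.track_id, t.mt_class, _fiber_str(t.fiber_id), i, x, y, z))
        for end_name, end in (("a", t.end_a), ("b", t.end_b)):
            if end.kinetochore_associated or end.morphology_by_observer:
                if not end.morphology_by_observer:
                    end_rows.append((t.track_id, end_name, end.kinetochore_associated, "", ""))
                for obs in sorted(end.morphology_by_observer):
                    end_rows.append(
                        (t.track_id, end_name, end.kinetochore_associated, obs,
                         end.morphology_by_observer[obs])
                    )

    tracks_df = pd.DataFrame(track_rows, columns=TRACKS_COLUMNS)
    ends_df = pd.DataFrame(end_rows, columns=ENDS_COLUMNS)

    landmarks: dict = {
        "condition": recon.condition,
        "cell_id": recon.cell_id,
        "observers": list(recon.observers),
        "poles": [
            {
                "pole_id": p.pole_id,
                "mother": [float(c) for c in p.mother],
                "daughter": [float(c) for c in p.daughter],
            }
            for p in sorted(recon.poles, key=lambda p: p.pole_id)
        ],
        "kinetochores": [
            {
                "kinetochore_id": k.kinetochore_id,
                "sister_id": k.sister_id,
                "kmt_track_ids": sorted(k.kmt_track_ids),
            }
            for k in sorted(recon.kinetochores, key=lambda k: k.kinetochore_id)
        ],
    }
    if recon.section_info is not None:
        landmarks["section_info"] = recon.section_info
    if recon.metadata:
        landmarks["metadata"] = recon.metadata

    paths = {
        "tracks": out_dir / "tracks.csv",
        "ends": out_dir / "ends.csv",
        "landmarks": out_dir / "landmarks.json",
    }
    tracks_df.to_csv(paths["tracks"], index=False, lineterminator="\n")
    ends_df.to_csv(paths["ends"], index=False, lineterminator="\n")
    paths["landmarks"].write_text(json.dumps(landmarks, sort_keys=True, indent=2) + "\n")
    return paths


def read_interchange(
    tracks_csv: str | Path,
    ends_csv: str | Path,
    landmarks_json: str | Path,
) -> SpindleReconstruction:
    """Read the interchange triple back into a :class:`SpindleReconstruction`."""
    tracks_df = pd.read_csv(tracks_csv, dtype={"track_id": str, "fiber_id": str}, keep_default_na=False)
    ends_df = pd.read_csv(ends_csv, dtype=str, keep_default_na=False)
    landmarks = json.loads(Path(landmarks_json).read_text())

    for col in TRACKS_COLUMNS:
        if col not in tracks_df.columns:
            raise GraphIOError(f"tracks.csv: missing mandatory column {col!r}")
    extra = set(tracks_df.columns) - set(TRACKS_COLUMNS)
    if extra:
        logger.warning("tracks.csv: ignoring unknown columns %s", sorted(extra))
    for col in ENDS_COLUMNS:
        if col not in ends_df.columns:
            raise GraphIOError(f"ends.csv: missing mandatory column {col!r}")
    extra = set(ends_df.columns) - set(ENDS_COLUMNS)
    if extra:
        logger.warning("ends.csv: ignoring unknown columns %s", sorted(extra))

    tracks: list[MicrotubuleTrack] = []
    for tid, grp in tracks_df.groupby("track_id", sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        mt_class = grp["mt_class"].iloc[0]
        fiber = grp["fiber_id"].iloc[0] or None
        tracks.append(MicrotubuleTrack(str(tid), mt_class, fiber, pts))
    track_index = {t.track_id: t for t in tracks}

    for _, row in ends_df.iterrows():
        tid = row["track_id"]
        if tid not in track_index:
            raise GraphIOError(f"ends.csv: dangling track id {tid!r}")
        t = track_index[tid]
        end = t.end_a if row["end"] == "a" else t.end_b
        end.kinetochore_associated = str(row["kinetochore_associated"]).lower() in ("true", "1")
        if row["observer_id"]:
            end.morphology_by_observer[row["observer_id"]] = row["morphology"]

    for t in tracks:
        if t.mt_class == "KMT" and t.end_a.kinetochore_associated and t.end_b.kinetochore_associated:
            raise GraphIOError(f"ends.csv: KMT {t.track_id} has both ends kinetochore-associated")

    poles = [
        Pole(p["pole_id"], np.array(p["mother"], float), np.array(p["daughter"], float))
        for p in landmarks.get("poles", [])
    ]
    kins = []
    for k in landmarks.get("kinetochores", []):
        for tid in k["kmt_track_ids"]:
            if tid not in track_index:
                raise GraphIOError(f"landmarks.json: kinetochore {k['kinetochore_id']} "
                                   f"references missing track {tid!r}")
        kins.append(Kinetochore(k["kinetochore_id"], k.get("sister_id"), list(k["kmt_track_ids"])))

    return SpindleReconstruction(
        condition=landmarks.get("condition", "other"),
        cell_id=landmarks.get("cell_id", ""),
        tracks=tracks,
        poles=poles,
        kinetochores=kins,
        observers=list(landmarks.get("observers", [])),
        section_info=landmarks.get("section_info"),
        metadata=dict(landmarks.get("metadata", {})),
    )


def read_interchange_dir(directory: str | Path) -> SpindleReconstruction:
    """Convenience: read an interchange bundle written by :func:`write_interchange`."""
    d = Path(directory)
    return read_interchange(d / "tracks.csv", d / "ends.csv", d / "landmarks.json")
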