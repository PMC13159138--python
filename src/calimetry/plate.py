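"""Data model and I/O for multi-well calcium-imaging experiments.

An experiment on disk is a directory with an ``experiment.yaml`` layout
file and one subdirectory per well (named row-letter + zero-padded column,
e.g. ``B07``).  Two storage dialects are supported:

* ``tiff`` — each field of view is a multi-page TIFF ``fovNNN.tif``
  (axes T, Y, X) with an optional integer ``fovNNN_mask.tif`` label mask,
  an optional ``fovNNN_stim.csv`` stimulation log (columns
  ``onset_frame, duration_ms, power_pct[, irradiance_mw_cm2]``) and an
  optional binary ``fovNNN_stim_mask.tif``;
* ``zarr`` — a single ``plate.zarr`` group with one subgroup per well
  holding arrays ``fovNNN`` / ``fovNNN_mask`` / ``fovNNN_stim_mask`` and
  the stimulation log in the group attributes.

``experiment.yaml`` declares the dialect and acquisition metadata::

    format: tiff
    frame_rate_hz: 10.0
    pixel_size_um: 1.0      # optional

Plate maps annotate wells with a condition (genotype / treatment / dose)
from a YAML ``wells:`` section or a CSV with a ``well`` column; grouping by
plate map is a partition of the recordings, with unannotated wells under
the reserved ``"unassigned"`` group.  Frame indices are 0-based throughout
and time in seconds is ``frame / frame_rate_hz``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
import zarr

from .errors import ConfigError, FormatError, LayoutError
from .evoked import StimProtocol

__all__ = [
    "FovRecording",
    "Condition",
    "PlateMap",
    "load_experiment",
    "apply_plate_map",
    "export_feature_tables",
    "write_experiment",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"
WELL_RE = re.compile(r"^[A-P](0[1-9]|1[0-9]|2[0-4])$")
LAYOUT_FILE = "experiment.yaml"


@dataclass
class FovRecording:
    """One field of view: video, metadata and optional mask/stimulation."""

    well_id: str
    fov_index: int
    frame_rate_hz: float
    video: np.ndarray | None = None
    pixel_size_um: float | None = None
    stim: StimProtocol | None = None
    label_mask: np.ndarray | None = None
    _video_loader: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not WELL_RE.match(self.well_id):
            raise LayoutError(f"invalid well label {self.well_id!r}")
        if self.fov_index < 0:
            raise ValueError("fov_index must be >= 0")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.video is not None:
            self._validate_video(self.video)

    def _validate_video(self, video: np.ndarray) -> None:
        if video.ndim != 3 or video.shape[0] < 1:
            raise FormatError(
                f"{self.well_id}/fov{self.fov_index:03d}: video must be "
                f"T x Y x X with >= 1 frame, got shape {video.shape}"
            )
        if self.label_mask is not None and self.label_mask.shape != video.shape[1:]:
            raise FormatError(
                f"{self.well_id}/fov{self.fov_index:03d}: mask shape "
                f"{self.label_mask.shape} does not match video frame shape "
                f"{video.shape[1:]}"
            )

    def get_video(self) -> np.ndarray:
        """Load (lazily, once) and return the T x Y x X video."""
        if self.video is None:
            if self._video_loader is None:
                raise FormatError(
                    f"{self.well_id}/fov{self.fov_index:03d}: no video available"
                )
            self.video = np.asarray(self._video_loader())
            self._validate_video(self.video)
        return self.video

    @property
    def n_frames(self) -> int:
        return self.get_video().shape[0]


@dataclass(frozen=True)
class Condition:
    genotype: str
    treatment: str = ""
    dose: str | None = None

    @property
    def label(self) -> str:
        parts = [self.genotype]
        if self.treatment:
            parts.append(self.treatment)
        if self.dose:
            parts.append(str(self.dose))
        return "|".join(parts)


class _DupSafeLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys."""


def _construct_mapping(loader, node, deep=False):
    keys = [loader.construct_object(k, deep=deep) for k, _ in node.value]
    dup = {k for k in keys if keys.count(k) > 1}
    if dup:
        raise ConfigError(f"duplicate keys in mapping: {sorted(dup)}")
    return yaml.SafeLoader.construct_mapping(loader, node, deep)


_DupSafeLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping
)


class PlateMap:
    """Mapping well_id -> Condition."""

    def __init__(self, wells: dict[str, Condition]):
        for well in wells:
            if not WELL_RE.match(well):
                raise ConfigError(f"invalid well label in plate map: {well!r}")
        self.wells = dict(wells)

    @classmethod
    def from_file(cls, path: str | Path) -> "PlateMap":
        path = Path(path)
        if path.suffix.lower() == ".csv":
            df = pd.read_csv(path, dtype=str).fillna("")
            if "well" not in df.columns:
                raise ConfigError("plate-map CSV needs a 'well' column")
            if df["well"].duplicated().any():
                dups = df["well"][df["well"].duplicated()].tolist()
                raise ConfigError(f"well(s) listed more than once: {dups}")
            wells = {
                row["well"]: Condition(
                    genotype=row.get("genotype", ""),
                    treatment=row.get("treatment", ""),
                    dose=row.get("dose") or None,
                )
                for _, row in df.iterrows()
            }
            return cls(wells)
        data = yaml.load(path.read_text(), Loader=_DupSafeLoader) or {}
        section = data.get("wells", data)
        wells = {}
        for well, rec in section.items():
            rec = rec or {}
            if isinstance(rec, str):
                rec = {"genotype": rec}
            wells[well] = Condition(
                genotype=str(rec.get("genotype", "")),
                treatment=str(rec.get("treatment", "")),
                dose=(str(rec["dose"]) if rec.get("dose") not in (None, "") else None),
            )
        return cls(wells)

    def condition_label(self, well_id: str) -> str:
        cond = self.wells.get(well_id)
        return cond.label if cond is not None else UNASSIGNED

    def __len__(self) -> int:
        return len(self.wells)


def _read_stim_csv(path: Path, shape: tuple[int, int] | None,
                   stim_mask: np.ndarray | None) -> StimProtocol:
    df = pd.read_csv(path)
    irr = (
        df["irradiance_mw_cm2"].to_numpy()
        if "irradiance_mw_cm2" in df.columns
        else None
    )
    return StimProtocol(
        pulse_onset_frames=df["onset_frame"].to_numpy(),
        pulse_duration_ms=float(df["duration_ms"].iloc[0]) if len(df) else 0.0,
        led_power_pct=df["power_pct"].to_numpy(),
        irradiance_mw_cm2=irr,
        stim_mask=stim_mask,
    )


def load_experiment(root: str | Path, layout: dict | None = None) -> list[FovRecording]:
    """Discover and load every field of view of an experiment directory.

    ``layout`` overrides/extends the on-disk ``experiment.yaml``; videos are
    attached lazily (read on first access).  Returns recordings sorted by
    (well, fov index).
    """
    root = Path(root)
    cfg: dict = {}
    layout_path = root / LAYOUT_FILE
    if layout_path.exists():
        cfg.update(yaml.safe_load(layout_path.read_text()) or {})
    if layout:
        cfg.update(layout)
    if "frame_rate_hz" not in cfg:
        raise ConfigError(f"no frame_rate_hz in {LAYOUT_FILE} or layout override")
    dialect = cfg.get("format", "tiff")
    frame_rate = float(cfg["frame_rate_hz"])
    pixel_size = cfg.get("pixel_size_um")
    pixel_size = float(pixel_size) if pixel_size is not None else None

    if dialect == "tiff":
        recs = _load_tiff_experiment(root, frame_rate, pixel_size)
    elif dialect == "zarr":
        recs = _load_zarr_experiment(root, frame_rate, pixel_size)
    else:
        raise ConfigError(f"unknown storage format {dialect!r}")
    recs.sort(key=lambda r: (r.well_id, r.fov_index))
    return recs


def _load_tiff_experiment(root: Path, frame_rate: float,
                          pixel_size: float | None) -> list[FovRecording]:
    recs = []
    for well_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        name = well_dir.name
        if name.startswith(".") or name in ("truth", "results"):
            continue
        if not WELL_RE.match(name):
            raise LayoutError(f"unknown well label {name!r} in {root}")
        for tif in sorted(well_dir.glob("fov*.tif")):
            m = re.match(r"^fov(\d+)$", tif.stem)
            if not m:
                continue
            fov = int(m.group(1))
            mask_path = well_dir / f"fov{fov:03d}_mask.tif"
            mask = tifffile.imread(mask_path) if mask_path.exists() else None
            stim_mask_path = well_dir / f"fov{fov:03d}_stim_mask.tif"
            stim_mask = (
                tifffile.imread(stim_mask_path).astype(bool)
                if stim_mask_path.exists()
                else None
            )
            stim_path = well_dir / f"fov{fov:03d}_stim.csv"
            stim = (
                _read_stim_csv(stim_path, None, stim_mask)
                if stim_path.exists()
                else None
            )
            try:
                rec = FovRecording(
                    well_id=name,
                    fov_index=fov,
                    frame_rate_hz=frame_rate,
                    pixel_size_um=pixel_size,
                    stim=stim,
                    label_mask=mask,
                    _video_loader=lambda p=tif: tifffile.imread(p),
                )
            except FormatError as err:
                raise FormatError(f"{name}/fov{fov:03d}: {err}") from err
            recs.append(rec)
    return recs


def _load_zarr_experiment(root: Path, frame_rate: float,
                          pixel_size: float | None) -> list[FovRecording]:
    store = root / "plate.zarr"
    if not store.exists():
        raise FormatError(f"no plate.zarr group under {root}")
    group = zarr.open_group(str(store), mode="r")
    recs = []
    for name in sorted(group.group_keys()):
        if not WELL_RE.match(name):
            raise LayoutError(f"unknown well label {name!r} in plate.zarr")
        wg = group[name]
        for key in sorted(wg.array_keys()):
            m = re.match(r"^fov(\d+)$", key)
            if not m:
                continue
            fov = int(m.group(1))
            mask = (
                np.asarray(wg[f"fov{fov:03d}_mask"])
                if f"fov{fov:03d}_mask" in wg
                else None
            )
            stim_mask = (
                np.asarray(wg[f"fov{fov:03d}_stim_mask"]).astype(bool)
                if f"fov{fov:03d}_stim_mask" in wg
                else None
            )
            stim = None
            stim_attrs = dict(wg.attrs).get(f"fov{fov:03d}_stim")
            if stim_attrs is not None:
                stim = StimProtocol(
                    pulse_onset_frames=np.asarray(stim_attrs["onset_frames"]),
                    pulse_duration_ms=float(stim_attrs["duration_ms"]),
                    led_power_pct=np.asarray(stim_attrs["power_pct"]),
                    irradiance_mw_cm2=(
                        np.asarray(stim_attrs["irradiance_mw_cm2"])
                        if stim_attrs.get("irradiance_mw_cm2") is not None
                        else None
                    ),
                    stim_mask=stim_mask,
                )
            recs.append(
                FovRecording(
                    well_id=name,
                    fov_index=fov,
                    frame_rate_hz=frame_rate,
                    pixel_size_um=pixel_size,
                    stim=stim,
                    label_mask=mask,
                    _video_loader=lambda g=wg, k=key: np.asarray(g[k]),
                )
            )
    return recs


def apply_plate_map(
    recordings: list[FovRecording], plate_map: PlateMap
) -> dict[str, list[FovRecording]]:
    """Group recordings by condition label; a partition of the input."""
    groups: dict[str, list[FovRecording]] = {}
    for rec in recordings:
        label = plate_map.condition_label(rec.well_id)
        groups.setdefault(label, []).append(rec)
    return groups


def export_feature_tables(features: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write one long-format CSV per feature column plus a combined CSV.

    ``features`` must carry ``well``, ``fov``, ``roi`` and ``condition``
    columns; every other numeric/boolean column is treated as a feature.
    Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    key_cols = ["well", "fov", "roi", "condition"]
    for col in key_cols:
        if col not in features.columns:
            raise ValueError(f"features table lacks required column {col!r}")
    if features[["well", "fov", "roi"]].duplicated().any():
        raise ValueError("duplicate (well, fov, roi) keys in feature table")
    feature_cols = [c for c in features.columns if c not in key_cols]
    written = []
    for col in feature_cols:
        path = out_dir / f"{col}.csv"
        features[key_cols + [col]].rename(columns={col: "value"}).to_csv(
            path, index=False
        )
        written.append(path)
    combined = out_dir / "features_combined.csv"
    features.to_csv(combined, index=False)
    written.append(combined)
    return written


def write_experiment(
    root: str | Path,
    recordings: list[FovRecording],
    dialect: str = "tiff",
) -> Path:
    """Write recordings to disk in the layout that load_experiment reads."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if not recordings:
        raise ValueError("nothing to write")
    frame_rate = recordings[0].frame_rate_hz
    cfg = {"format": dialect, "frame_rate_hz": float(frame_rate)}
    if recordings[0].pixel_size_um is not None:
        cfg["pixel_size_um"] = float(recordings[0].pixel_size_um)
    (root / LAYOUT_FILE).write_text(yaml.safe_dump(cfg, sort_keys=False))

    if dialect == "tiff":
        for rec in recordings:
            well_dir = root / rec.well_id
            well_dir.mkdir(exist_ok=True)
            base = f"fov{rec.fov_index:03d}"
            tifffile.imwrite(well_dir / f"{base}.tif", rec.get_video())
            if rec.label_mask is not None:
                tifffile.imwrite(
                    well_dir / f"{base}_mask.tif",
                    rec.label_mask.astype(np.uint16),
                )
            if rec.stim is not None:
                _write_stim(well_dir, base, rec.stim)
    elif dialect == "zarr":
        group = zarr.open_group(str(root / "plate.zarr"), mode="w")
        for rec in recordings:
            wg = (
                group[rec.well_id]
                if rec.well_id in group
                else group.create_group(rec.well_id)
            )
            base = f"fov{rec.fov_index:03d}"
            video = rec.get_video()
            arr = wg.create_array(base, shape=video.shape, dtype=video.dtype)
            arr[:] = video
            if rec.label_mask is not None:
                mask = rec.label_mask.astype(np.uint16)
                marr = wg.create_array(f"{base}_mask", shape=mask.shape,
                                       dtype=mask.dtype)
                marr[:] = mask
            if rec.stim is not None:
                st = rec.stim
                wg.attrs[f"{base}_stim"] = {
                    "onset_frames": st.pulse_onset_frames.tolist(),
                    "duration_ms": st.pulse_duration_ms,
                    "power_pct": st.led_power_pct.tolist(),
                    "irradiance_mw_cm2": (
                        st.irradiance_mw_cm2.tolist()
                        if st.irradiance_mw_cm2 is not None
                        else None
                    ),
                }
                if st.stim_mask is not None:
                    sm = st.stim_mask.astype(np.uint8)
                    sarr = wg.create_array(f"{base}_stim_mask", shape=sm.shape,
                                           dtype=sm.dtype)
                    sarr[:] = sm
    else:
        raise ConfigError(f"unknown storage format {dialect!r}")
    return root


def _write_stim(well_dir: Path, base: str, stim: StimProtocol) -> None:
    data = {
        "onset_frame": stim.pulse_onset_frames,
        "duration_ms": np.full(stim.n_pulses, stim.pulse_duration_ms),
        "power_pct": stim.led_power_pct,
    }
    if stim.irradiance_mw_cm2 is not None:
        data["irradiance_mw_cm2"] = stim.irradiance_mw_cm2
    pd.DataFrame(data).to_csv(well_dir / f"{base}_stim.csv", index=False)
    if stim.stim_mask is not None:
        tifffile.imwrite(
            well_dir / f"{base}_stim_mask.tif",
            stim.stim_mask.astype(np.uint8),
        )
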