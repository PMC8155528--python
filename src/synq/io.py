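"""Calibrated image stacks, result tables, projections and shared services.

Every analysis in this package operates on an :class:`ImageStack`, an N-D
fluorescence image normalized to the axis order ``(T, Z, C, Y, X)`` with
physical calibration attached (pixel size in μm, Z step in μm, frame interval
in s).  Stacks are loaded from TIFF / ImageJ-TIFF files, with calibration read
from metadata, from a sidecar YAML, or from explicit overrides.

Geometric conventions used throughout the package:

* pixel indices are 0-based; a pixel's physical position is
  ``(index + 0.5) * pixel_size_um`` (pixel-center convention);
* ``y`` increases downward (row direction), ``x`` to the right (columns);
* points are ``(x_um, y_um)`` pairs in μm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("synq")

__all__ = [
    "ImageStack",
    "ResultTable",
    "load_stack",
    "save_stack",
    "sum_projection",
    "save_table",
    "load_table",
    "make_rng",
]

#: axis order used internally everywhere
AXES = "TZCYX"

#: metric names the ResultTable vocabulary accepts
METRIC_VOCABULARY = frozenset(
    {
        "polarity_index",
        "bead_recruitment_pct",
        "centrosome_density_index",
        "center_recruitment",
        "z_peak_fraction",
        "antigen_extraction_pct",
        "centrosome_nucleus_distance_um",
        "spreading_area_um2",
        "aspect_ratio",
        "spreading_velocity_um2_min",
        "retrograde_flow_um_s",
        "frap_plateau",
        "frap_k_per_s",
        "frap_half_life_s",
        "pearson_r",
        "pearson_r_rotated",
        "n_tracks",
        "track_duration_s",
        "track_displacement_um",
        "diffusion_um2_s",
        "quartile_mfi",
    }
)


class CalibrationError(ValueError):
    """Raised when a stack lacks required physical calibration."""


@dataclass(frozen=True)
class ImageStack:
    """A calibrated fluorescence image with axes ``(T, Z, C, Y, X)``.

    Parameters
    ----------
    pixels:
        Non-negative float array.  Arrays with 2–5 dimensions are accepted
        together with an ``axes`` string and normalized to 5-D.
    pixel_size_um:
        Lateral sampling in μm per pixel, isotropic in Y/X.
    z_step_um:
        Axial sampling in μm per plane; required when Z > 1.
    frame_interval_s:
        Seconds between frames; required when T > 1.
    channel_names:
        One label per channel.
    """

    pixels: np.ndarray
    pixel_size_um: float
    z_step_um: float | None = None
    frame_interval_s: float | None = None
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 5:
            raise ValueError(
                f"pixels must be 5-D (T,Z,C,Y,X); got {px.ndim}-D — "
                "use from_array() to normalize other layouts"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must all be finite")
        if px.size and px.min() < 0:
            raise ValueError("pixel intensities must be >= 0")
        object.__setattr__(self, "pixels", px)
        if not self.pixel_size_um or self.pixel_size_um <= 0:
            raise CalibrationError("pixel_size_um must be > 0")
        if self.n_frames > 1 and (self.frame_interval_s is None or self.frame_interval_s <= 0):
            raise CalibrationError("frame_interval_s must be > 0 for time series")
        if self.n_planes > 1 and (self.z_step_um is None or self.z_step_um <= 0):
            raise CalibrationError("z_step_um must be > 0 for Z-stacks")
        names = tuple(self.channel_names) if self.channel_names else tuple(
            f"ch{i}" for i in range(self.n_channels)
        )
        if len(names) != self.n_channels:
            raise ValueError(
                f"channel_names has {len(names)} entries for {self.n_channels} channels"
            )
        object.__setattr__(self, "channel_names", names)

    # -- shape accessors ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[3], self.pixels.shape[4]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def plane(self, t: int = 0, z: int = 0, c: int = 0) -> np.ndarray:
        """One 2-D (Y, X) image."""
        return self.pixels[t, z, c]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise IndexError(f"unknown channel {channel!r}; have {self.channel_names}")
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} out of range (C={self.n_channels})")
        return channel

    def with_pixels(self, pixels: np.ndarray) -> "ImageStack":
        return replace(self, pixels=pixels)

    @classmethod
    def from_array(
        cls,
        array: np.ndarray,
        axes: str,
        *,
        pixel_size_um: float,
        z_step_um: float | None = None,
        frame_interval_s: float | None = None,
        channel_names=(),
    ) -> "ImageStack":
        """Build a stack from an array in any axis dialect of ``TZCYX``.

        ``axes`` names the dimensions of ``array`` (e.g. ``"TCZYX"``,
        ``"ZYX"``, ``"YX"``); missing axes become singletons.  Normalization
        is idempotent: an already-``TZCYX`` array passes through unchanged.
        """
        array = np.asarray(array)
        axes = axes.upper()
        if array.ndim != len(axes):
            raise ValueError(f"array is {array.ndim}-D but axes={axes!r}")
        if len(set(axes)) != len(axes) or any(a not in AXES for a in axes):
            raise ValueError(f"axes must be a subset of {AXES!r} without repeats; got {axes!r}")
        if "Y" not in axes or "X" not in axes:
            raise ValueError("axes must include Y and X")
        # insert singleton axes, then transpose into canonical order
        full = array
        have = axes
        for a in AXES:
            if a not in have:
                full = np.expand_dims(full, axis=0)
                have = a + have
        order = [have.index(a) for a in AXES]
        full = np.transpose(full, order)
        return cls(
            pixels=full,
            pixel_size_um=pixel_size_um,
            z_step_um=z_step_um,
            frame_interval_s=frame_interval_s,
            channel_names=channel_names,
        )


def _guess_axes(shape: tuple[int, ...], axes_hint: str | None) -> str:
    """Map common TIFF layouts onto axis names; require an override otherwise."""
    if axes_hint:
        return axes_hint.upper()
    ndim = len(shape)
    if ndim == 2:
        return "YX"
    if ndim == 3:
        # a small leading dimension is far more plausibly C than Z/T, but the
        # choice is genuinely ambiguous — demand an explicit override
        raise ValueError(
            f"ambiguous 3-D layout {shape}: pass axes='ZYX', 'CYX' or 'TYX' explicitly"
        )
    raise ValueError(f"cannot infer axes for {ndim}-D data; pass axes explicitly")


def load_stack(
    path: str | Path,
    *,
    axes: str | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_names=(),
) -> ImageStack:
    """Load a TIFF (or ImageJ/OME TIFF) into a canonical :class:`ImageStack`.

    Calibration is resolved in priority order: explicit keyword overrides,
    sidecar YAML (``<path>.yaml`` with keys ``pixel_size_um`` etc.), then TIFF
    metadata.  A missing pixel size after all three is a
    :class:`CalibrationError` — silent default calibration would corrupt every
    μm-denominated metric downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        array = series.asarray()
        meta_axes = series.axes.replace("S", "C").replace("Q", "")
        meta: dict = {}
        if tf.imagej_metadata:
            meta.update(tf.imagej_metadata)
        # pixel size from resolution tags (pixels per unit)
        page = tf.pages[0]
        res_px_size = None
        try:
            xres = page.tags["XResolution"].value
            unit = page.tags.get("ResolutionUnit")
            unit_name = getattr(unit.value, "name", "NONE") if unit is not None else "NONE"
            ij_unit = meta.get("unit", "")
            if xres and xres[0]:
                if unit_name == "CENTIMETER":
                    res_px_size = xres[1] / xres[0] * 1e4
                elif unit_name == "INCH":
                    res_px_size = xres[1] / xres[0] * 25400.0
                elif ij_unit in ("um", "micron", "µm", "\\u00b5m"):
                    # unitless resolution tag, but ImageJ metadata declares μm
                    res_px_size = xres[1] / xres[0]
        except KeyError:
            pass

    sidecar = path.with_suffix(path.suffix + ".yaml")
    side: dict = {}
    if sidecar.exists():
        side = yaml.safe_load(sidecar.read_text()) or {}

    def pick(override, key, meta_value):
        if override is not None:
            return override
        if key in side:
            return side[key]
        return meta_value

    px = pick(pixel_size_um, "pixel_size_um", res_px_size)
    if px is None or px <= 0:
        raise CalibrationError(
            f"{path.name}: no pixel size in metadata or sidecar; pass pixel_size_um"
        )
    zs = pick(z_step_um, "z_step_um", meta.get("spacing"))
    fi = pick(frame_interval_s, "frame_interval_s", meta.get("finterval"))
    names = channel_names or tuple(side.get("channel_names", ()))

    if axes is None and meta_axes and set(meta_axes) <= set(AXES) and len(meta_axes) == array.ndim:
        axes = meta_axes
    axes = _guess_axes(array.shape, axes)
    stack = ImageStack.from_array(
        array,
        axes,
        pixel_size_um=float(px),
        z_step_um=None if zs is None else float(zs),
        frame_interval_s=None if fi is None else float(fi),
        channel_names=names,
    )
    logger.info(
        "loaded %s: T=%d Z=%d C=%d YX=%s, %.4g um/px",
        path.name, stack.n_frames, stack.n_planes, stack.n_channels,
        stack.shape_yx, stack.pixel_size_um,
    )
    return stack


def save_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an ImageJ-flavoured TIFF preserving calibration and axes."""
    path = Path(path)
    metadata = {"axes": AXES, "unit": "um"}
    if stack.z_step_um is not None:
        metadata["spacing"] = stack.z_step_um
    if stack.frame_interval_s is not None:
        metadata["finterval"] = stack.frame_interval_s
    res = 1.0 / stack.pixel_size_um
    tifffile.imwrite(
        str(path),
        stack.pixels.astype(np.float32),
        imagej=True,
        resolution=(res, res),
        metadata=metadata,
    )
    # channel names and exact calibration go in a sidecar; ImageJ metadata
    # has no standard slot for float64-precision values
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "pixel_size_um": float(stack.pixel_size_um),
                "z_step_um": None if stack.z_step_um is None else float(stack.z_step_um),
                "frame_interval_s": (
                    None if stack.frame_interval_s is None else float(stack.frame_interval_s)
                ),
                "channel_names": list(stack.channel_names),
            }
        )
    )


def sum_projection(stack: ImageStack, channel: int | str, frame: int = 0) -> np.ndarray:
    """Sum-of-planes Z projection of one channel at one frame.

    Collapses the Z axis by per-pixel summation, the projection used for
    quantifying fluorescence retained on antigen-coated beads; total intensity
    is conserved exactly.
    """
    c = stack.channel_index(channel)
    if not 0 <= frame < stack.n_frames:
        raise IndexError(f"frame {frame} out of range (T={stack.n_frames})")
    return stack.pixels[frame, :, c].sum(axis=0)


# ---------------------------------------------------------------------------
# result tables


@dataclass
class ResultTable:
    """Long-format measurement table: one row per (cell, frame, metric).

    ``metric_name`` is restricted to the registered vocabulary so that
    downstream pooling cannot silently mix typo'd metrics.
    """

    rows: list = field(default_factory=list)

    def add(self, cell_id: str, frame: int, metric_name: str, value: float, units: str = ""):
        if metric_name not in METRIC_VOCABULARY:
            raise ValueError(f"unregistered metric {metric_name!r}")
        value = float(value)
        if not np.isfinite(value):
            raise ValueError(f"non-finite value for {metric_name}: {value}")
        key = (cell_id, int(frame), metric_name)
        if any((r[0], r[1], r[2]) == key for r in self.rows):
            raise ValueError(f"duplicate measurement for {key}")
        self.rows.append((cell_id, int(frame), metric_name, value, units))
        logger.info("%s frame %d: %s = %.6g %s", cell_id, frame, metric_name, value, units)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["cell_id", "frame", "metric_name", "value", "units"]
        )

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, ResultTable) and self.rows == other.rows


def save_table(table: ResultTable, path: str | Path) -> None:
    """Write a ResultTable as CSV (lossless round trip via :func:`load_table`)."""
    df = table.to_frame()
    if len(df) and not np.isfinite(df["value"]).all():
        raise ValueError("table contains non-finite values")
    df.to_csv(path, index=False)


def load_table(path: str | Path) -> ResultTable:
    df = pd.read_csv(path, keep_default_na=False)
    t = ResultTable()
    for r in df.itertuples(index=False):
        t.add(r.cell_id, int(r.frame), r.metric_name, float(r.value), str(r.units))
    return t


def make_rng(seed) -> np.random.Generator:
    """The package-wide RNG service: every stochastic routine takes a seed or
    Generator and passes it through here, so a single integer reproduces a
    whole pipeline bit-identically."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
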