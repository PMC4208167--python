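"""Strip-image densitometry: from pixels to band grayscale signals.

A lateral-flow strip is imaged with the flow axis along image rows (sample
pad at low row indices by default).  The reading pipeline is

    to_grayscale -> longitudinal_profile -> detect_bands -> LineSignal

Bands (test and control lines) are dips in the per-row mean grayscale;
background is the two-pass median of the off-band profile.  A strip is
valid only when a control band is called; the test band's signal is
reported either as its raw mean grayscale (dark line -> low value) or as
the background-corrected ``net_signal = background - mean_gray`` which
increases with analyte concentration (default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import InputError

__all__ = [
    "StripConfig",
    "LineProfile",
    "BandCall",
    "LineSignal",
    "read_strip_image",
    "to_grayscale",
    "longitudinal_profile",
    "detect_bands",
    "extract_line_signal",
]

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R BT.601


@dataclass(frozen=True)
class StripConfig:
    """Geometry and reading options for a strip image.

    lane : (row0, row1, col0, col1) half-open bounds of the membrane window,
        or None for the whole image.
    orientation : "control-bottom" places the absorbent pad (and hence the
        control line) at high row indices; "control-top" flips it.
    min_depth : minimum dip (grayscale units) below background to call a band.
    polarity : "net" reports background - mean_gray for the test band
        (increases with concentration); "raw" reports the band mean grayscale.
    """

    lane: tuple[int, int, int, int] | None = None
    orientation: str = "control-bottom"
    min_depth: float = 5.0
    polarity: str = "net"

    def __post_init__(self):
        if self.orientation not in ("control-bottom", "control-top"):
            raise InputError(f"unknown orientation {self.orientation!r}")
        if self.polarity not in ("net", "raw"):
            raise InputError(f"unknown polarity {self.polarity!r}")
        if self.min_depth <= 0:
            raise InputError("min_depth must be positive")


@dataclass(frozen=True)
class LineProfile:
    """Per-row mean grayscale along the flow axis of one lane."""

    values: np.ndarray
    axis_origin: int = 0  # image row of profile index 0


@dataclass(frozen=True)
class BandCall:
    """One called band with its local-background-corrected signal."""

    role: str  # "control" | "test" | "band"
    center: int  # image row at the middle of the called extent
    extent: tuple[int, int]  # half-open row range
    mean_gray: float
    background: float

    @property
    def net_signal(self) -> float:
        return self.background - self.mean_gray


@dataclass(frozen=True)
class LineSignal:
    """Reading of one strip: control and test band calls plus the reported
    grayscale used downstream for calibration."""

    control: BandCall | None
    test: BandCall | None
    valid: bool
    measured_grayscale: float | None


def read_strip_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF strip image as a numpy array."""
    try:
        img = iio.imread(Path(path))
    except OSError as exc:
        raise InputError(f"cannot read strip image {path}: {exc}") from exc
    return np.asarray(img)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion rounded half-up; gray input passes through."""
    img = np.asarray(image)
    if img.size == 0:
        raise InputError("empty image")
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        luma = img[..., :3].astype(float) @ _LUMA
        return np.floor(luma + 0.5).astype(np.uint8)
    raise InputError(f"unsupported image shape {img.shape}")


def longitudinal_profile(
    image: np.ndarray, lane: tuple[int, int, int, int] | None = None
) -> LineProfile:
    """Mean grayscale of each lane row (the flow-axis intensity profile)."""
    gray = to_grayscale(image)
    h, w = gray.shape
    if lane is None:
        lane = (0, h, 0, w)
    r0, r1, c0, c1 = lane
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise InputError(f"lane {lane} outside image bounds {(h, w)}")
    values = gray[r0:r1, c0:c1].astype(float).mean(axis=1)
    return LineProfile(values=values, axis_origin=r0)


def _band_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def detect_bands(
    profile: LineProfile,
    expected: int = 2,
    min_depth: float = 5.0,
    orientation: str = "control-bottom",
) -> list[BandCall]:
    """Call up to ``expected`` bands as dips >= min_depth below background.

    Background is estimated iteratively: median of all rows, then median of
    the rows not already flagged as band rows (two passes, so a dark band
    cannot drag the estimate down).  The ``expected`` deepest dips are kept
    and returned ordered along the flow axis; the band nearest the absorbent
    pad is the control line.  Zero bands is a legal outcome (invalid strip).
    """
    vals = np.asarray(profile.values, dtype=float)
    if vals.size < 5:
        raise InputError("profile too short to call bands (need >= 5 rows)")
    background = float(np.median(vals))
    for _ in range(2):
        off_band = vals[vals >= background - min_depth]
        if off_band.size == 0:
            break
        background = float(np.median(off_band))
    mask = vals < background - min_depth
    candidates = []
    for start, stop in _band_runs(mask):
        seg = vals[start:stop]
        depth = background - seg.min()
        candidates.append((depth, start, stop))
    candidates.sort(key=lambda t: -t[0])
    kept = sorted(candidates[: max(expected, 0)], key=lambda t: t[1])

    bands = []
    for depth, start, stop in kept:
        # midpoint of the called extent: robust to noise on flat-bottomed bands
        center = (start + stop) // 2
        bands.append(
            BandCall(
                role="band",
                center=profile.axis_origin + center,
                extent=(profile.axis_origin + start, profile.axis_origin + stop),
                mean_gray=float(vals[start:stop].mean()),
                background=background,
            )
        )
    if not bands:
        return bands

    # role assignment: control sits nearest the absorbent-pad end
    control_idx = len(bands) - 1 if orientation == "control-bottom" else 0
    test_idx = None
    if len(bands) >= 2:
        test_idx = control_idx - 1 if orientation == "control-bottom" else 1
    out = []
    for i, band in enumerate(bands):
        role = "control" if i == control_idx else "test" if i == test_idx else "band"
        out.append(
            BandCall(role, band.center, band.extent, band.mean_gray, band.background)
        )
    return out


def extract_line_signal(image: np.ndarray, config: StripConfig = StripConfig()) -> LineSignal:
    """Full reading of one strip image.

    Composes grayscale conversion, lane profiling and band calling; the
    strip is valid only if a control band is present.  The reported
    ``measured_grayscale`` follows ``config.polarity`` and refers to the
    test band; it is None when the test band is absent (e.g. a blank) or the
    strip is invalid.
    """
    profile = longitudinal_profile(image, config.lane)
    bands = detect_bands(
        profile, expected=2, min_depth=config.min_depth, orientation=config.orientation
    )
    control = next((b for b in bands if b.role == "control"), None)
    test = next((b for b in bands if b.role == "test"), None)
    valid = control is not None
    measured = None
    if valid and test is not None:
        measured = test.net_signal if config.polarity == "net" else test.mean_gray
    return LineSignal(control=control, test=test, valid=valid, measured_grayscale=measured)
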