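"""Seed-controlled synthetic strips and simulated screening experiments.

The generator emulates what the reading pipeline sees on a real hCG
lateral-flow strip: a nitrocellulose membrane window imaged with the flow
axis along rows, a fixed control line, and a test line whose darkness grows
linearly with analyte concentration over 0-50 mIU/mL (sandwich assay,
clamped above 50).  A ten-parameter camera model (backlight compensation,
brightness, contrast, exposure, gain, gamma, hue, saturation, sharpness,
white balance) distorts the rendered scene in a fixed, documented order.

For robust-design studies, :func:`simulate_l12` produces the paired
reference/measured grayscale signals of a full orthogonal-array experiment
with exactly known ground-truth factor effects on the run S/N (dB scale),
so recovery of influential parameters can be asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .densitometry import longitudinal_profile, to_grayscale
from .design import FactorAssignment, OrthogonalArray
from .exceptions import InputError
from .taguchi import RunResponse, run_response

__all__ = [
    "CameraParams",
    "StripSpec",
    "EffectModel",
    "reference_targets",
    "render_strip",
    "render_reference_patch",
    "measure_patch",
    "simulate_l12",
    "simulate_calibration_points",
]

STANDARD_GRAYSCALES = (247.0, 249.0, 251.0, 253.0, 255.0)


@dataclass(frozen=True)
class CameraParams:
    """Acquisition parameters of the simulated camera (neutral defaults).

    Neutral means the rendered scene passes through unchanged: offsets 0,
    gains 1, gamma 1, sharpness 0, saturation 100, white balance "Auto",
    backlight compensation off.
    """

    backlight_compensation: bool = False
    brightness: float = 0.0
    contrast: float = 1.0
    exposure: float = 1.0
    gain: float = 1.0
    gamma: float = 1.0
    hue: float = 0.0  # degrees of chroma rotation
    saturation: float = 100.0  # percent
    sharpness: float = 0.0  # unsharp-mask strength
    white_balance: float | str = "Auto"  # "Auto" or colour temperature (K)

    def __post_init__(self):
        if self.gamma <= 0:
            raise InputError("gamma must be positive")
        if self.saturation < 0:
            raise InputError("saturation must be non-negative")

    @classmethod
    def neutral(cls) -> "CameraParams":
        return cls()


@dataclass(frozen=True)
class StripSpec:
    """Geometry and optical truth of one synthetic strip.

    The test-line dip is ``test_depth_at_50 * min(concentration/50, 1)``
    grayscale units: linear in concentration over the assay's working range
    and absent at concentration zero.
    """

    concentration: float = 25.0  # mIU/mL
    height: int = 120
    width: int = 40
    membrane_gray: float = 220.0
    control_depth: float = 80.0
    test_depth_at_50: float = 60.0
    band_centers: tuple[int, int] = (45, 85)  # (test, control) rows
    band_width: int = 8
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.concentration < 0:
            raise InputError("concentration must be non-negative")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        if not (0 < self.band_width <= self.height // 4):
            raise InputError("band_width must be positive and fit the strip")
        t, c = self.band_centers
        if not (0 <= t < self.height and 0 <= c < self.height):
            raise InputError("band centers outside the strip")

    @property
    def test_depth(self) -> float:
        return self.test_depth_at_50 * min(self.concentration / 50.0, 1.0)


def reference_targets() -> tuple[float, ...]:
    """The five standard grayscales used as the dynamic signal levels."""
    return STANDARD_GRAYSCALES


# ---------------------------------------------------------------------------
# camera pixel pipeline


def _apply_camera(rgb: np.ndarray, params: CameraParams, rng: np.random.Generator,
                  noise_sd: float) -> np.ndarray:
    """Apply the camera transforms in fixed order on a float RGB array."""
    x = rgb.astype(float)
    x = x * params.exposure
    if params.gain != 1.0:
        # amplification scales signal and injects amplified read noise
        x = x * params.gain
        extra = noise_sd * abs(params.gain - 1.0)
        if extra > 0:
            x = x + rng.normal(0.0, extra, size=x.shape)
    x = x + params.brightness
    x = 128.0 + params.contrast * (x - 128.0)
    if params.gamma != 1.0:
        x = 255.0 * np.clip(x / 255.0, 0.0, 1.0) ** (1.0 / params.gamma)
    if params.white_balance != "Auto":
        temp = float(params.white_balance)
        x[..., 0] *= (6500.0 / temp) ** 0.2
        x[..., 2] *= (temp / 6500.0) ** 0.2
    if params.hue != 0.0 or params.saturation != 100.0:
        # luma-preserving chroma edit in YIQ space: hue rotates the (I, Q)
        # plane, saturation scales it; achromatic pixels are untouched
        to_yiq = np.array(
            [[0.299, 0.587, 0.114], [0.596, -0.274, -0.322], [0.211, -0.523, 0.312]]
        )
        yiq = x @ to_yiq.T
        theta = math.radians(params.hue)
        s = params.saturation / 100.0
        i0, q0 = yiq[..., 1].copy(), yiq[..., 2].copy()
        yiq[..., 1] = s * (math.cos(theta) * i0 - math.sin(theta) * q0)
        yiq[..., 2] = s * (math.sin(theta) * i0 + math.cos(theta) * q0)
        x = yiq @ np.linalg.inv(to_yiq).T
    if params.sharpness != 0.0:
        blurred = ndimage.uniform_filter(x, size=(3, 3, 1), mode="nearest")
        x = x + params.sharpness * (x - blurred)
    if params.backlight_compensation:
        # highlight compression: values above the knee are halved toward it
        knee = 225.0
        x = np.where(x > knee, knee + 0.5 * (x - knee), x)
    return x


def _finalize(x: np.ndarray, rgb: bool) -> np.ndarray:
    x = np.clip(x, 0.0, 255.0)
    img = np.floor(x + 0.5).astype(np.uint8)
    if rgb:
        return img
    return to_grayscale(img)


def render_strip(
    spec: StripSpec,
    params: CameraParams = CameraParams(),
    seed: int = 0,
    rgb: bool = False,
) -> np.ndarray:
    """Render one strip image (uint8 gray by default, RGB on request).

    The scene is membrane background plus Gaussian pixel noise with the
    control band darkened by ``control_depth`` and the test band by the
    concentration-scaled test depth; the camera pipeline is then applied in
    the fixed order exposure -> gain -> brightness -> contrast -> gamma ->
    white balance -> hue/saturation -> sharpness -> backlight compensation.
    Bit-identical for fixed (spec, params, seed).
    """
    rng = np.random.default_rng(seed)
    scene = np.full((spec.height, spec.width), spec.membrane_gray, dtype=float)
    if spec.noise_sd > 0:
        scene += rng.normal(0.0, spec.noise_sd, size=scene.shape)
    half = spec.band_width // 2
    t_center, c_center = spec.band_centers
    scene[c_center - half : c_center - half + spec.band_width, :] -= spec.control_depth
    if spec.test_depth > 0:
        scene[t_center - half : t_center - half + spec.band_width, :] -= spec.test_depth
    x = np.repeat(scene[..., None], 3, axis=-1)  # achromatic scene
    x = _apply_camera(x, params, rng, spec.noise_sd)
    return _finalize(x, rgb)


def render_reference_patch(
    target_gray: float,
    params: CameraParams = CameraParams(),
    seed: int = 0,
    size: tuple[int, int] = (24, 24),
    noise_sd: float = 0.5,
    rgb: bool = False,
) -> np.ndarray:
    """Render a flat reference patch at a given scene grayscale.

    These emulate the printed standard-grayscale patches (247-255) placed in
    the test-line window while tuning the acquisition parameters.
    """
    rng = np.random.default_rng(seed)
    scene = np.full(size, float(target_gray))
    if noise_sd > 0:
        scene += rng.normal(0.0, noise_sd, size=size)
    x = np.repeat(scene[..., None], 3, axis=-1)
    x = _apply_camera(x, params, rng, noise_sd)
    return _finalize(x, rgb)


def measure_patch(patch: np.ndarray) -> float:
    """Mean grayscale of a reference patch via the densitometry profile."""
    return float(longitudinal_profile(patch).values.mean())


# ---------------------------------------------------------------------------
# ground-truth effect model for simulated screening experiments


@dataclass(frozen=True)
class EffectModel:
    """Ground-truth factor effects on the run S/N (dB scale).

    ``effects[factor_id]`` is the change in run S/N when that factor moves
    from level 1 to level 2 (so it equals the response-table effect in
    expectation).  ``interactions[(a, b)]`` adds a product term on the
    +/-1/2 contrast coding.  Influential factors are those with
    ``|effect| >= 3`` dB; background factors should stay within 0.5 dB.
    Defaults mirror the observed camera study: backlight compensation (A)
    +3.15 dB, gamma (F) -7.36 dB, sharpness (I) +3.87 dB, base 40 dB,
    run-to-run noise 0.5 dB.
    """

    effects: dict[str, float] = field(
        default_factory=lambda: {"A": 3.15, "F": -7.36, "I": 3.87}
    )
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    base_sn: float = 40.0
    run_noise_db: float = 0.5

    def influential(self) -> list[str]:
        return [f for f, e in self.effects.items() if abs(e) >= 3.0]

    def validate(self) -> None:
        weak = {f: e for f, e in self.effects.items() if 0.5 < abs(e) < 3.0}
        if weak:
            raise InputError(
                f"effects must be influential (>=3 dB) or background (<=0.5 dB): {weak}"
            )

    def true_run_sn(
        self, design: OrthogonalArray, assignment: list[FactorAssignment]
    ) -> np.ndarray:
        """Noise-free run S/N implied by the model on a given design."""
        col = {f.factor_id: f.column for f in assignment}
        x = {f: np.where(design.column(c) == 2, 0.5, -0.5) for f, c in col.items()}
        sn = np.full(design.n_runs, self.base_sn)
        for f, e in self.effects.items():
            if f in x:
                sn = sn + e * x[f]
        for (fa, fb), c in self.interactions.items():
            if fa in x and fb in x:
                sn = sn + c * x[fa] * x[fb]
        return sn


def simulate_l12(
    design: OrthogonalArray,
    assignment: list[FactorAssignment],
    effects: EffectModel = EffectModel(),
    replicates: int = 1,
    seed: int = 0,
    patch_size: tuple[int, int] = (24, 24),
    patch_noise_sd: float = 0.5,
    baseline_exposure: float = 0.9,
) -> list[RunResponse]:
    """Simulate a full screening experiment with known factor effects.

    For each run the five standard-grayscale patches are rendered and
    measured through the densitometry pipeline; the measured signals carry
    residuals whose scale encodes that run's ground-truth S/N,
    ``sd = 10^(-S/N / 20)`` on the unit-slope normalized scale, with the
    residual vector built orthogonal to the reference signals so the fitted
    slope and spread recover the injected values.  Patches are rendered
    under a fixed sub-unity ``baseline_exposure`` so the brightest standard
    keeps headroom below the 8-bit ceiling; this scales beta and Sd jointly
    and therefore leaves every run's S/N untouched.  ``effects.true_run_sn``
    returns the exact noise-free ground truth for assertions.
    """
    if replicates < 1:
        raise InputError("replicates must be at least 1")
    cols = [f.column for f in assignment]
    if len(set(cols)) != len(cols) or (cols and max(cols) >= design.n_columns):
        raise InputError("assignment inconsistent with the design")
    rng = np.random.default_rng(seed)
    M = np.asarray(STANDARD_GRAYSCALES)
    M_norm = M / 255.0
    truth = effects.true_run_sn(design, assignment)
    responses = []
    for r in range(design.n_runs):
        sn_run = truth[r] + (
            rng.normal(0.0, effects.run_noise_db) if effects.run_noise_db > 0 else 0.0
        )
        measured = np.zeros_like(M)
        for _ in range(replicates):
            if math.isinf(sn_run):
                y_norm = M_norm.copy()
            else:
                sd_run = 10.0 ** (-sn_run / 20.0)
                z = rng.normal(size=M.size)
                e = z - (z @ M_norm) / (M_norm @ M_norm) * M_norm
                e *= sd_run / math.sqrt((e @ e) / (M.size - 1))
                y_norm = M_norm + e
            camera = CameraParams(exposure=baseline_exposure)
            for i, target in enumerate(y_norm * 255.0):
                patch = render_reference_patch(
                    target,
                    camera,
                    seed=int(rng.integers(2**31)),
                    size=patch_size,
                    noise_sd=patch_noise_sd,
                )
                measured[i] += measure_patch(patch)
        measured /= replicates
        responses.append(run_response(r + 1, M, measured, scale=255.0))
    return responses


# ---------------------------------------------------------------------------
# calibration-study simulation


def simulate_calibration_points(
    levels=(6.25, 12.5, 25.0, 37.5, 50.0),
    replicates: int = 3,
    seed: int = 0,
    spec: StripSpec = StripSpec(),
    params: CameraParams = CameraParams(),
    config=None,
):
    """Render replicate strips per concentration level and read them.

    Returns a pandas DataFrame with columns concentration, signal,
    replicate_id (the calibration-CSV layout), using the densitometry
    pipeline with the given reading config (default: whole-image lane,
    net-signal polarity).
    """
    import pandas as pd

    from .densitometry import StripConfig, extract_line_signal

    if config is None:
        config = StripConfig()
    if replicates < 1:
        raise InputError("replicates must be at least 1")
    seeds = np.random.SeedSequence(seed).generate_state(len(levels) * replicates)
    rows = []
    k = 0
    for conc in levels:
        for rep in range(1, replicates + 1):
            strip_spec = replace(spec, concentration=float(conc))
            img = render_strip(strip_spec, params, seed=int(seeds[k] % 2**31))
            k += 1
            reading = extract_line_signal(img, config)
            if not reading.valid or reading.measured_grayscale is None:
                continue
            rows.append(
                {
                    "concentration": float(conc),
                    "signal": reading.measured_grayscale,
                    "replicate_id": rep,
                }
            )
    return pd.DataFrame(rows)
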