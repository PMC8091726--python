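"""Synthetic imaging scenes with known ground truth.

The generators emulate the structure the plane-threshold analysis
assumes: a mouse-body intensity plateau sitting above a lower
imaging-bed background, smooth unimodal (Gaussian) tumour blobs on top
of the plateau, additive detector noise, integer quantization and
bit-depth clipping.  On top of single scenes they build the study's
composite designs — tenfold dilution plates, phantom-mouse
repositioning series and exponential growth timecourses — always
emitting the generating truth (blob integrals, plateau levels, true
amplitude CV, analytic detection crossings) so that downstream recovery
tests never depend on the pipeline they are checking.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError
from .image_io import RawImage
from .series_stats import DilutionSeries

__all__ = [
    "SceneParams",
    "GrowthParams",
    "SceneTruth",
    "gen_mouse_image",
    "gen_dilution_plate",
    "gen_phantom_series",
    "gen_growth_timecourse",
]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic mouse (or phantom) image.

    Levels are raw detector counts.  ``body_ellipse`` is
    (center_row, center_col, semi_row, semi_col); ``None`` means the
    body plateau fills the whole frame, emulating an image already
    cropped to the tumour neighbourhood.  ``tumours`` holds
    (center_row, center_col, sigma_px, amplitude_counts) blobs.
    """

    shape: tuple[int, int] = (96, 96)
    bed_level: float = 200.0
    body_level: float = 3000.0
    body_ellipse: tuple[float, float, float, float] | None = (48.0, 48.0, 42.0, 38.0)
    tumours: tuple[tuple[float, float, float, float], ...] = (
        (48.0, 48.0, 6.0, 20000.0),
    )
    noise_sd: float = 30.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        ceiling = (1 << self.bit_depth) - 1
        if not 0 <= self.bed_level <= ceiling or not 0 <= self.body_level <= ceiling:
            raise DomainError("plateau levels must lie within the bit-depth range")
        if self.body_level <= self.bed_level:
            raise DomainError("body plateau must sit above the bed background")
        if self.noise_sd < 0:
            raise DomainError("noise sd must be non-negative")
        for r, c, sigma, amp in self.tumours:
            if sigma <= 0:
                raise DomainError("blob sigma must be positive")
            if amp < 0:
                raise DomainError("blob amplitude must be non-negative")


@dataclass(frozen=True)
class GrowthParams:
    """Exponential tumour growth schedule over imaging days.

    Amplitude at day d is ``initial_amplitude * exp(rate * (d - days[0]))``.
    ``jitter_px`` shifts the blob centre per day (uniform in
    [-jitter_px, +jitter_px] per axis); ``jitter_fraction`` perturbs the
    amplitude multiplicatively — both emulate repositioning between
    imaging sessions.
    """

    initial_amplitude: float = 5000.0
    rate: float = math.log(2.0) / 3.5
    days: tuple[int, ...] = (14, 17, 21, 24)
    jitter_px: float = 0.0
    jitter_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.rate):
            raise DomainError("growth rate must be finite")
        if any(a >= b for a, b in zip(self.days, self.days[1:])):
            raise DomainError("imaging days must be strictly increasing")


@dataclass(frozen=True)
class SceneTruth:
    """Generating truth for one scene."""

    bed_level: float
    body_level: float
    blob_integrals: tuple[float, ...]  # discrete sums of each blob over the grid
    amplitudes: tuple[float, ...]
    peak_exceeds_ceiling: bool
    body_mask: np.ndarray = field(repr=False, compare=False)


def _body_mask(params: SceneParams) -> np.ndarray:
    if params.body_ellipse is None:
        return np.ones(params.shape, dtype=bool)
    cr, cc, sr, sc = params.body_ellipse
    rows, cols = np.indices(params.shape)
    return ((rows - cr) / sr) ** 2 + ((cols - cc) / sc) ** 2 <= 1.0


def gen_mouse_image(
    params: SceneParams, rng: np.random.Generator | None = None
) -> tuple[RawImage, SceneTruth]:
    """Render one scene and return it with its generating truth.

    The noiseless field is bed level outside the body ellipse, body
    level inside, plus isotropic Gaussian blobs; seeded Gaussian noise
    is added, then values are rounded and clipped to
    ``[0, 2**bit_depth - 1]``.  Blob integrals in the truth record are
    the *discrete* noiseless sums over the grid (before clipping), i.e.
    exactly what a perfect plane measurement at the body plateau would
    recover.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    body = _body_mask(params)
    field_ = np.where(body, params.body_level, params.bed_level).astype(np.float64)
    rows, cols = np.indices(params.shape)
    integrals, amplitudes = [], []
    for r0, c0, sigma, amp in params.tumours:
        blob = amp * np.exp(
            -((rows - r0) ** 2 + (cols - c0) ** 2) / (2.0 * sigma**2)
        )
        field_ += blob
        integrals.append(float(blob.sum()))
        amplitudes.append(float(amp))
    ceiling = (1 << params.bit_depth) - 1
    peak_exceeds = bool(field_.max() > ceiling)
    if params.noise_sd > 0:
        field_ = field_ + rng.normal(0.0, params.noise_sd, size=params.shape)
    pixels = np.clip(np.rint(field_), 0, ceiling).astype(
        np.uint16 if params.bit_depth <= 16 else np.uint32
    )
    image = RawImage(pixels, bit_depth=params.bit_depth, platform="SYN", units="counts")
    truth = SceneTruth(
        bed_level=params.bed_level,
        body_level=params.body_level,
        blob_integrals=tuple(integrals),
        amplitudes=tuple(amplitudes),
        peak_exceeds_ceiling=peak_exceeds,
        body_mask=body,
    )
    return image, truth


def gen_dilution_plate(
    top_signal: float,
    n_dilutions: int = 6,
    step: float = 10.0,
    replicates: int = 3,
    background: float = 100.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    k: float = 3.0,
    n_background: int = 6,
) -> tuple[DilutionSeries, dict]:
    """Simulate a serial-dilution well plate.

    Well signal at dilution i (factor ``step**-i``) is
    ``background + top_signal * step**-i`` plus Gaussian noise;
    ``replicates`` wells per dilution plus ``n_background`` blank
    wells (more blanks than signal triplicates: a stable background sd
    is what the k-sigma detection rule leans on, and a plate has blank
    wells to spare).  The truth dict carries the noiseless means and
    the analytic detection crossing: the smallest ladder factor whose
    true net signal exceeds ``k * noise_sd`` (None when even the top
    dilution is below it).
    """
    if top_signal <= background:
        raise DomainError("top signal must exceed background")
    if n_dilutions < 2 or step <= 1 or replicates < 1:
        raise DomainError("need >= 2 dilutions, step > 1, >= 1 replicate")
    rng = np.random.default_rng(seed)
    factors = tuple(step**-i for i in range(n_dilutions))
    true_means = tuple(background + (top_signal - background) * f for f in factors)
    signals = tuple(
        tuple(rng.normal(m, noise_sd, size=replicates).tolist()) for m in true_means
    )
    bg_wells = tuple(rng.normal(background, noise_sd, size=n_background).tolist())
    detectable = [
        f
        for f, m in zip(factors, true_means)
        if m - background > k * noise_sd
    ]
    truth = {
        "true_means": true_means,
        "background": background,
        "noise_sd": noise_sd,
        "analytic_lod": min(detectable) if detectable else None,
        "k": k,
    }
    return (
        DilutionSeries(
            dilution_factors=factors,
            replicate_signals=signals,
            background_wells=bg_wells,
        ),
        truth,
    )


def gen_phantom_series(
    base_signal: float = 20000.0,
    jitter_fraction: float = 0.2,
    n_repeats: int = 20,
    seed: int = 0,
    scene: SceneParams | None = None,
    position_jitter_px: float = 5.0,
) -> tuple[list[RawImage], dict]:
    """Repeated imaging of a phantom emitter under repositioning.

    Each repeat re-renders a single-blob scene whose amplitude is
    multiplied by ``1 + jitter_fraction * u`` (u uniform on [-1, 1])
    and whose centre shifts by up to ``jitter_fraction *
    position_jitter_px`` pixels per axis — the larger the repositioning
    jitter, the larger both effects.  The truth dict records the
    realized amplitudes and their CV (sample sd / mean, percent), the
    quantity a repeatable pipeline should recover.
    """
    if not 0.0 <= jitter_fraction < 1.0:
        raise DomainError("jitter fraction must be in [0, 1)")
    if scene is None:
        scene = SceneParams(
            body_ellipse=None,  # phantom frame cropped to the emitter region
            tumours=((48.0, 48.0, 6.0, base_signal),),
            noise_sd=0.0,
        )
    rng = np.random.default_rng(seed)
    r0, c0, sigma, _ = scene.tumours[0]
    images, amplitudes = [], []
    for _ in range(n_repeats):
        amp = base_signal * (1.0 + jitter_fraction * rng.uniform(-1.0, 1.0))
        dr, dc = rng.uniform(
            -jitter_fraction * position_jitter_px,
            jitter_fraction * position_jitter_px,
            size=2,
        )
        params = replace(scene, tumours=((r0 + dr, c0 + dc, sigma, amp),))
        image, _truth = gen_mouse_image(params, rng=rng)
        images.append(image)
        amplitudes.append(amp)
    amps = np.asarray(amplitudes)
    true_cv = (
        100.0 * float(np.std(amps, ddof=1)) / float(amps.mean())
        if n_repeats > 1
        else 0.0
    )
    truth = {"amplitudes": amplitudes, "true_cv_pct": true_cv}
    return images, truth


def gen_growth_timecourse(
    scene: SceneParams | None = None,
    growth: GrowthParams | None = None,
    seed: int = 0,
) -> list[tuple[int, RawImage, float]]:
    """Longitudinal scenes with exponentially growing blob amplitude.

    Returns (day, image, true_amplitude) triples.  With jitter and
    noise both zero the true fold change between days d1 and d2 is
    exactly ``exp(rate * (d2 - d1))``.  Saturation can be emulated by
    choosing amplitudes that push the peak past the bit-depth ceiling
    (clipping is always applied during rendering).
    """
    if growth is None:
        growth = GrowthParams()
    if scene is None:
        scene = SceneParams(body_ellipse=None, noise_sd=0.0)
    rng = np.random.default_rng(seed)
    r0, c0, sigma, _ = scene.tumours[0]
    out = []
    d0 = growth.days[0]
    for day in growth.days:
        amp = growth.initial_amplitude * math.exp(growth.rate * (day - d0))
        if growth.jitter_fraction > 0:
            amp *= 1.0 + growth.jitter_fraction * rng.uniform(-1.0, 1.0)
        dr = dc = 0.0
        if growth.jitter_px > 0:
            dr, dc = rng.uniform(-growth.jitter_px, growth.jitter_px, size=2)
        params = replace(scene, tumours=((r0 + dr, c0 + dc, sigma, amp),))
        image, _ = gen_mouse_image(params, rng=rng)
        out.append((day, image, amp))
    return out
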