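"""Synthetic meniscus stress-MRI cohort generator with known ground truth.

The generator emulates an ex-vivo loading experiment on lateral meniscus
body samples: each sample is a 2-D wedge-shaped cross-section imaged at
three loading positions (delta0 unloaded, delta1 = 2 bar / 37.1 N,
delta2 = 4 bar / 69.1 N).  Loading flattens the wedge — mask areas shrink
by configurable compression factors — and shifts the zonal relaxation
times according to degeneration-dependent response patterns:

* T1 decreases everywhere under loading, more at the base;
* T1rho increases at the apex in intact/mildly degenerative samples and
  decreases (apex and base) in moderately-to-severely degenerative ones;
* T2 decreases at the apex in degenerative samples.

Zone/grade/load central values are calibrated to published cohort medians
for this experiment type; per-sample offsets, per-load jitter, and Rician
acquisition noise (the modulus of a complex Gaussian perturbation, i.e.
what a magnitude image actually shows) are layered on top.  Within a zone
the true relaxation time is homogeneous, so ROI medians of an ideal
pipeline equal the stored truth exactly.

Every sample also gets an unconfined-compression stress-strain curve drawn
from the exponential hyperelastic model (sigma = c*(exp(b*eps)-1)) with
grade-wise Elastic-Modulus statistics, and a Pauli subscore tuple whose sum
lands in the grade's bin.  One latent per-sample degeneration factor
couples the qMRI offsets (positively) and the Elastic Modulus
(negatively), reproducing the inverse qMRI-biomechanics correlations seen
in real cohorts.

All randomness flows through one seeded generator: identical seeds give
bit-identical cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .biomechanics import StressStrainCurve
from .relaxometry import SignalStack, inversion_recovery_signal, mono_exp_signal
from .zones import partition_thirds

__all__ = [
    "PhantomSpec",
    "SampleTruth",
    "SyntheticSample",
    "Cohort",
    "generate_cohort",
    "generate_wedge_mask",
    "generate_stress_strain",
    "rician",
    "DEFAULT_ZONAL_TRUTH",
    "ACQUISITION",
]

LOADS = ("delta0", "delta1", "delta2")
CONTRASTS = ("T1", "T1rho", "T2")
ZONES = ("I", "II", "III")
GRADE_GROUPS = ("I", "II", ">=III")

#: acquisition grids: (variable values in ms, repetition time in ms)
ACQUISITION = {
    "T1": {"times": (150.0, 300.0, 500.0, 800.0, 1000.0, 1500.0), "tr": 3000.0},
    "T1rho": {"times": (0.0, 10.0, 20.0, 30.0, 40.0), "tr": 30.0},
    "T2": {"times": tuple(8.4 * n for n in range(1, 7)), "tr": 1500.0},
}

#: per grade-group -> contrast -> zone -> (delta0, delta1, delta2) central
#: values in ms, calibrated to published cohort medians.
DEFAULT_ZONAL_TRUTH: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "I": {
        "T1": {"I": (780, 713, 702), "II": (593, 522, 465), "III": (661, 513, 499)},
        "T1rho": {"I": (43.6, 58.6, 55.0), "II": (34.8, 44.9, 44.7), "III": (48.2, 46.1, 43.9)},
        "T2": {"I": (23.3, 23.0, 22.8), "II": (20.2, 20.3, 20.2), "III": (26.2, 23.6, 22.6)},
    },
    "II": {
        "T1": {"I": (887, 877, 837), "II": (624, 532, 482), "III": (676, 528, 511)},
        "T1rho": {"I": (63.3, 59.7, 58.3), "II": (42.2, 44.2, 42.9), "III": (45.1, 47.9, 48.0)},
        "T2": {"I": (30.1, 29.8, 26.0), "II": (25.3, 23.8, 25.0), "III": (26.8, 26.4, 27.0)},
    },
    ">=III": {
        "T1": {"I": (914, 860, 782), "II": (694, 569, 489), "III": (628, 505, 468)},
        "T1rho": {"I": (65.5, 56.9, 51.3), "II": (49.7, 45.5, 43.4), "III": (49.7, 41.9, 41.0)},
        "T2": {"I": (31.0, 32.1, 28.6), "II": (23.7, 21.4, 19.7), "III": (23.5, 23.6, 22.0)},
    },
}

#: grade-wise Elastic Modulus targets [MPa]: group -> (EM20 mean, EM80 mean)
DEFAULT_EM_MEANS = {
    "I": (15.5, 351.4),
    "II": (17.8, 343.4),
    ">=III": (16.2, 353.5),
}

#: Pauli sum-score sampling per group: (mean, sd, clip_lo, clip_hi)
DEFAULT_PAULI_SUMS = {
    "I": (3.4, 0.9, 0, 4),
    "II": (8.0, 0.9, 5, 9),
    ">=III": (12.3, 1.5, 10, 16),
}


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate a 45-sample cohort split 14/16/15 across Pauli grade
    groups, a 64 x 64 grid at 0.25 mm/pixel (~800 wedge pixels unloaded),
    mask-area compression to 89.6 % and 75.4 % under the two loads, and
    Rician noise of 2 signal units at amplitude 100 (SNR 50).
    """

    n_samples: int = 45
    image_shape: tuple[int, int] = (64, 64)
    pixel_size: float = 0.25  # mm
    wedge_width: float = 8.4  # mm, mediolateral (cohort mean)
    wedge_height: float = 11.45  # mm, base height (cohort mean)
    wedge_width_sd: float = 1.0  # mm, between-sample variability
    wedge_height_sd: float = 2.0  # mm
    grade_fractions: tuple[float, float, float] = (14 / 45, 16 / 45, 15 / 45)
    compression_factors: tuple[float, float, float] = (1.0, 0.896, 0.754)
    noise_sigma: float = 2.0  # Rician scale, signal units
    amplitude: float = 100.0  # signal units
    apex_side: str = "right"
    zonal_truth: dict = field(default_factory=lambda: DEFAULT_ZONAL_TRUTH)
    between_sample_sd: dict = field(
        default_factory=lambda: {"T1": 70.0, "T1rho": 8.0, "T2": 3.0}
    )
    load_jitter_sd: dict = field(
        default_factory=lambda: {"T1": 7.0, "T1rho": 1.5, "T2": 0.8}
    )
    degeneration_coupling: float = 0.75
    em_means: dict = field(default_factory=lambda: DEFAULT_EM_MEANS)
    em_log_sd: tuple[float, float] = (0.58, 0.20)
    strain_step: float = 0.01
    stress_noise_fraction: float = 0.02
    pauli_sum_stats: dict = field(default_factory=lambda: DEFAULT_PAULI_SUMS)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.wedge_width <= 0 or self.wedge_height <= 0:
            raise ValueError("wedge_width and wedge_height must be positive")
        if self.wedge_width_sd < 0 or self.wedge_height_sd < 0:
            raise ValueError("wedge_width_sd and wedge_height_sd must be non-negative")
        if abs(sum(self.grade_fractions) - 1.0) > 1e-6:
            raise ValueError(
                f"grade_fractions must sum to 1, got {sum(self.grade_fractions)}"
            )
        cf = self.compression_factors
        if cf[0] != 1.0:
            raise ValueError("compression_factors must start at 1.0 (delta0)")
        # strictly decreasing below 1.0; repeats of exactly 1.0 are allowed
        # for uncompressed diagnostic runs
        if any(f <= 0 for f in cf) or any(
            (b > a) or (b == a and b < 1.0) for a, b in zip(cf, cf[1:])
        ):
            raise ValueError(
                "compression_factors must be strictly decreasing and positive"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        for group in GRADE_GROUPS:
            for contrast in CONTRASTS:
                for zone in ZONES:
                    vals = self.zonal_truth[group][contrast][zone]
                    if any(v <= 0 for v in vals):
                        raise ValueError(
                            f"zonal_truth[{group}][{contrast}][{zone}] must be positive"
                        )

    def replace(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


@dataclass
class SampleTruth:
    """Ground truth stored alongside a synthetic sample for recovery scoring."""

    grade_group: str
    pauli: tuple[int, int, int, int]
    pauli_sum: int
    latent_degeneration: float
    zonal_values: dict  # load -> contrast -> zone -> ms
    b: float
    c: float
    em_20: float
    em_80: float


@dataclass
class SyntheticSample:
    sample_id: str
    masks: dict  # load -> 2-D bool array
    stacks: dict  # load -> contrast -> SignalStack
    curve: StressStrainCurve
    truth: SampleTruth


@dataclass
class Cohort:
    spec: PhantomSpec
    samples: list[SyntheticSample]

    def by_group(self) -> dict[str, list[SyntheticSample]]:
        out: dict[str, list[SyntheticSample]] = {g: [] for g in GRADE_GROUPS}
        for s in self.samples:
            out[s.truth.grade_group].append(s)
        return out


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rician-corrupted magnitude signal: |S + n_re + i n_im|, n ~ N(0, sigma)."""
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    re = signal + sigma * rng.standard_normal(signal.shape)
    im = sigma * rng.standard_normal(signal.shape)
    return np.hypot(re, im)


def _allocate_counts(weights: np.ndarray, total: int, minimum: int = 0) -> np.ndarray:
    """Largest-remainder rounding of ``weights`` (summing ~total) to integers."""
    base = np.floor(weights).astype(int)
    base = np.maximum(base, minimum)
    diff = total - int(base.sum())
    if diff > 0:
        order = np.argsort(-(weights - np.floor(weights)), kind="stable")
        for i in range(diff):
            base[order[i % order.size]] += 1
    elif diff < 0:
        order = np.argsort(weights - np.floor(weights), kind="stable")
        removed = 0
        idx = 0
        while removed < -diff:
            j = order[idx % order.size]
            if base[j] > minimum:
                base[j] -= 1
                removed += 1
            idx += 1
            if idx > 10 * order.size:  # cannot honour the minimum everywhere
                raise ValueError("cannot allocate counts under the minimum constraint")
    return base


def generate_wedge_mask(
    width_mm: float,
    height_mm: float,
    pixel_size: float,
    compression_factor: float = 1.0,
    image_shape: tuple[int, int] = (64, 64),
    apex_side: str = "right",
) -> np.ndarray:
    """Binary wedge (triangular) cross-section mask, optionally compressed.

    The wedge tapers linearly from the base height to the apex tip.  A
    compression factor f in (0, 1] flattens the wedge: the pixel count is
    exactly ``round(f * n0)`` (largest-remainder allocation of per-column
    heights, every column keeping >= 1 pixel so the mediolateral width is
    preserved), emulating loading-induced loss of cross-sectional area at
    preserved width.

    Raises
    ------
    ValueError
        For non-positive dimensions, a factor outside (0, 1], or a wedge
        shorter than 3 pixels.
    """
    if width_mm <= 0 or height_mm <= 0 or pixel_size <= 0:
        raise ValueError("wedge dimensions and pixel size must be positive")
    if not (0 < compression_factor <= 1):
        raise ValueError("compression_factor must be in (0, 1]")
    if apex_side not in ("left", "right"):
        raise ValueError("apex_side must be 'left' or 'right'")
    nrows, ncols_img = image_shape
    ncols = int(round(width_mm / pixel_size))
    height_px = height_mm / pixel_size
    if ncols > ncols_img or height_px > nrows:
        raise ValueError("wedge does not fit in image_shape")
    if ncols < 3:
        raise ValueError("wedge narrower than 3 pixels")

    # unloaded column heights: linear taper, base (j=0) tallest
    j = np.arange(ncols)
    h_cont = height_px * (ncols - j) / ncols
    h0 = np.maximum(np.round(h_cont).astype(int), 1)
    n0 = int(h0.sum())

    if compression_factor < 1.0:
        target = int(round(compression_factor * n0))
        heights = _allocate_counts(compression_factor * h0.astype(float), target, minimum=1)
    else:
        heights = h0
    if heights.max() < 3:
        raise ValueError("compressed wedge would be less than 3 pixels tall")

    if apex_side == "left":
        heights = heights[::-1]
    col_offset = (ncols_img - ncols) // 2
    mask = np.zeros(image_shape, dtype=bool)
    rows = np.arange(nrows)[:, None]
    # fill from the bottom row upwards
    mask[:, col_offset : col_offset + ncols] = rows >= (nrows - heights[None, :])
    return mask


def generate_stress_strain(
    b: float,
    c: float,
    strain_grid: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> StressStrainCurve:
    """Stress-strain curve from sigma(eps) = c*(exp(b*eps) - 1) + Gaussian noise."""
    if b <= 0 or c <= 0:
        raise ValueError("b and c must be positive")
    eps = np.asarray(strain_grid, dtype=float)
    if np.any(eps < 0) or np.any(eps > 1):
        raise ValueError("strain_grid must lie in [0, 1]")
    sigma = c * (np.exp(b * eps) - 1.0)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        sigma = sigma + noise_sd * rng.standard_normal(eps.shape)
    return StressStrainCurve(eps, sigma, sample_id)


def _draw_pauli(group: str, stats: dict, rng: np.random.Generator):
    mean, sd, lo, hi = stats[group]
    total = int(np.clip(round(rng.normal(mean, sd)), lo, hi))
    # decompose into (surface<=9, cellularity<=3, collagen<=3, staining<=3)
    rem = total
    surface = int(rng.integers(max(0, rem - 9), min(9, rem) + 1))
    rem -= surface
    cellularity = int(rng.integers(max(0, rem - 6), min(3, rem) + 1))
    rem -= cellularity
    collagen = int(rng.integers(max(0, rem - 3), min(3, rem) + 1))
    staining = rem - collagen
    return (surface, cellularity, collagen, staining), total


def _group_sizes(fractions, n: int) -> list[int]:
    return list(_allocate_counts(np.asarray(fractions) * n, n))


def generate_cohort(spec: PhantomSpec) -> Cohort:
    """Generate a full in-silico cohort from a validated :class:`PhantomSpec`.

    Deterministic given ``spec.seed``.  Each sample carries masks and
    multi-contrast signal stacks per loading position, a stress-strain
    curve, Pauli subscores, and the complete ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = _group_sizes(spec.grade_fractions, spec.n_samples)
    group_of = [g for g, n in zip(GRADE_GROUPS, sizes) for _ in range(n)]

    strain_grid = np.arange(0.0, 1.0 + spec.strain_step / 2, spec.strain_step)
    w = spec.degeneration_coupling
    w_orth = float(np.sqrt(1.0 - w * w))
    s20, s80 = spec.em_log_sd

    samples: list[SyntheticSample] = []
    for i, group in enumerate(group_of):
        sample_id = f"S{i + 1:02d}"
        z = float(rng.standard_normal())

        # per-sample geometry: samples are cut to standard length but keep
        # their natural (variable) width and height
        max_w = (spec.image_shape[1] - 2) * spec.pixel_size
        max_h = (spec.image_shape[0] - 2) * spec.pixel_size
        width = float(
            np.clip(
                rng.normal(spec.wedge_width, spec.wedge_width_sd),
                4 * spec.pixel_size,
                max_w,
            )
        )
        height = float(
            np.clip(
                rng.normal(spec.wedge_height, spec.wedge_height_sd),
                5 * spec.pixel_size,
                max_h,
            )
        )

        offsets = {
            contrast: spec.between_sample_sd[contrast]
            * (w * z + w_orth * float(rng.standard_normal()))
            for contrast in CONTRASTS
        }
        zonal_values: dict = {}
        for li, load in enumerate(LOADS):
            zonal_values[load] = {}
            for contrast in CONTRASTS:
                zonal_values[load][contrast] = {}
                for zone in ZONES:
                    center = spec.zonal_truth[group][contrast][zone][li]
                    value = (
                        center
                        + offsets[contrast]
                        + spec.load_jitter_sd[contrast] * float(rng.standard_normal())
                    )
                    zonal_values[load][contrast][zone] = float(max(value, 1.0))

        masks: dict = {}
        stacks: dict = {}
        for li, load in enumerate(LOADS):
            mask = generate_wedge_mask(
                width,
                height,
                spec.pixel_size,
                spec.compression_factors[li],
                spec.image_shape,
                spec.apex_side,
            )
            masks[load] = mask
            partition = partition_thirds(mask, spec.apex_side)
            stacks[load] = {}
            for contrast in CONTRASTS:
                truth_map = np.ones(spec.image_shape)  # dummy positive background
                for zone in ZONES:
                    truth_map[partition.zone_mask(zone)] = zonal_values[load][contrast][zone]
                times = np.asarray(ACQUISITION[contrast]["times"])
                if contrast == "T1":
                    signal = inversion_recovery_signal(
                        spec.amplitude, truth_map[..., None], times[None, None, :]
                    )
                else:
                    signal = mono_exp_signal(
                        spec.amplitude, truth_map[..., None], times[None, None, :]
                    )
                signal = np.where(mask[..., None], signal, 0.0)
                data = rician(signal, spec.noise_sigma, rng)
                data = np.where(mask[..., None], data, 0.0)
                stacks[load][contrast] = SignalStack(
                    data=data,
                    times=times,
                    contrast=contrast,
                    tr=ACQUISITION[contrast]["tr"],
                )

        # biomechanics: grade-wise EM targets with inverse degeneration coupling
        em20_mean, em80_mean = spec.em_means[group]
        le20 = (
            np.log(em20_mean)
            - 0.5 * s20 * s20
            + s20 * (-w * z + w_orth * float(rng.standard_normal()))
        )
        le80 = (
            np.log(em80_mean)
            - 0.5 * s80 * s80
            + s80 * (-w * z + w_orth * float(rng.standard_normal()))
        )
        em20, em80 = float(np.exp(le20)), float(np.exp(le80))
        b = float(np.log(em80 / em20) / 0.6)
        c = float(em20 / (b * np.exp(0.2 * b)))
        noise_sd = spec.stress_noise_fraction * c * (np.exp(b) - 1.0)
        curve = generate_stress_strain(b, c, strain_grid, noise_sd, rng, sample_id)

        pauli, pauli_sum = _draw_pauli(group, spec.pauli_sum_stats, rng)

        truth = SampleTruth(
            grade_group=group,
            pauli=pauli,
            pauli_sum=pauli_sum,
            latent_degeneration=z,
            zonal_values=zonal_values,
            b=b,
            c=c,
            em_20=em20,
            em_80=em80,
        )
        samples.append(SyntheticSample(sample_id, masks, stacks, curve, truth))

    return Cohort(spec=spec, samples=samples)
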