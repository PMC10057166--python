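"""Synthetic fluorescence data with known ground truth.

Generates plant-shaped foreground masks, Fo/Fm image pairs by inverting the
Fv/Fm definition (Fo = Fm * (1 - Fv/Fm)) with additive Gaussian noise and
quantization, excitation-emission matrices as separable Gaussian bumps, and
full multi-group multi-day experiments with linearly declining group trends
and SPAD readings linearly coupled to the true Fv/Fm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import ellipse as _draw_ellipse

from .emex_analysis import EMISSION_AXIS, EXCITATION_AXIS, EmexMatrix
from .errors import ParameterizationError, SaturationError
from .imaging_core import BinaryMask, ImagePair, RawImage

__all__ = [
    "GroupTrend",
    "GeneratorConfig",
    "ExperimentBundle",
    "default_group_trends",
    "gen_plant_mask",
    "gen_image_pair",
    "gen_emex",
    "gen_experiment",
    "spad_noise_for_target_r",
    "config_to_dict",
    "config_from_dict",
]

# Group period-mean Fv/Fm defaults taken from the reference experiment's
# printed values (control / drought / heat / combination).
DEFAULT_PERIOD_MEANS = {
    "control": 0.802,
    "drought": 0.780,
    "heat": 0.768,
    "combination": 0.749,
}
DEFAULT_DAYS = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass(frozen=True)
class GroupTrend:
    """Linear decline of a treatment group's mean Fv/Fm over the trial.

    The period average of a linear trend sampled at evenly spaced days is
    (fvfm_day1 + fvfm_day15) / 2, so defaults are chosen symmetric about the
    target period means.
    """

    name: str
    fvfm_day1: float
    fvfm_day15: float
    between_plant_sd: float = 0.015
    within_plant_spatial_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.fvfm_day15 <= self.fvfm_day1 < 1.0:
            raise ParameterizationError(
                f"group {self.name!r}: need 0 < fvfm_day15 <= fvfm_day1 < 1, "
                f"got day1={self.fvfm_day1}, day15={self.fvfm_day15}"
            )
        if self.between_plant_sd < 0 or self.within_plant_spatial_sd < 0:
            raise ParameterizationError(f"group {self.name!r}: SDs must be >= 0")

    @property
    def period_mean(self) -> float:
        return (self.fvfm_day1 + self.fvfm_day15) / 2.0

    def mean_at(self, day: float, day_first: float, day_last: float) -> float:
        t = (day - day_first) / (day_last - day_first)
        return self.fvfm_day1 + t * (self.fvfm_day15 - self.fvfm_day1)


def default_group_trends() -> tuple[GroupTrend, ...]:
    """Four treatment groups whose period averages hit the default means.

    The control trend spans 0.810 -> 0.794 so it stays at or above the 0.79
    health limit throughout; the stressed groups sit below 0.79 from day 1.
    """
    spreads = {"control": 0.008, "drought": 0.01, "heat": 0.01, "combination": 0.01}
    return tuple(
        GroupTrend(
            name=name,
            fvfm_day1=mean + spreads[name],
            fvfm_day15=mean - spreads[name],
        )
        for name, mean in DEFAULT_PERIOD_MEANS.items()
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to synthesize a full experiment."""

    image_shape: tuple[int, int] = (612, 512)  # quarter-scale sensor stand-in
    bit_depth: int = 16
    groups: tuple[GroupTrend, ...] = field(default_factory=default_group_trends)
    n_plants_per_group: int = 30
    days: tuple[int, ...] = DEFAULT_DAYS
    noise_sd: float = 50.0
    fm_level: float = 20000.0
    n_leaflets: int = 6
    spad_slope: float = 100.0
    spad_intercept: float = -36.0
    spad_noise_sd: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ParameterizationError(f"image_shape must be positive, got {self.image_shape}")
        if self.bit_depth not in (8, 16):
            raise ParameterizationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.n_plants_per_group < 2:
            raise ParameterizationError("n_plants_per_group must be >= 2 for SE/ANOVA")
        days = tuple(self.days)
        if len(days) < 1 or any(b <= a for a, b in zip(days, days[1:])):
            raise ParameterizationError("days must be strictly increasing")
        if len(self.groups) < 1:
            raise ParameterizationError("need at least one group trend")
        if self.fm_level >= 2 ** self.bit_depth:
            raise SaturationError(
                f"fm_level {self.fm_level} saturates {self.bit_depth}-bit sensor"
            )
        if self.noise_sd < 0 or self.spad_noise_sd < 0:
            raise ParameterizationError("noise SDs must be >= 0")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "image_shape", (int(rows), int(cols)))


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    # Deterministic, order-independent stream per (group, plant, day, purpose).
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def gen_plant_mask(
    shape: tuple[int, int], n_leaflets: int = 6, seed: int = 0
) -> BinaryMask:
    """A rosette of overlapping filled ellipses around the image center.

    Deterministic for a fixed seed; the foreground fraction is kept within
    [0.05, 0.60] by rescaling the leaflets if the first draw falls outside.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if n_leaflets < 1:
        raise ParameterizationError(f"n_leaflets must be >= 1, got {n_leaflets}")
    if min(rows, cols) < 16:
        raise ParameterizationError(f"shape {shape} too small to place a leaflet")
    rng = _child_rng(seed, 0xA5)
    radius = min(rows, cols) / 2.0
    lengths = rng.uniform(0.55, 0.80, n_leaflets) * radius
    widths = rng.uniform(0.35, 0.55, n_leaflets) * lengths
    angles = (
        2.0 * np.pi * np.arange(n_leaflets) / n_leaflets
        + rng.uniform(-0.25, 0.25, n_leaflets)
    )
    center = (rows / 2.0, cols / 2.0)

    scale = 1.0
    for _ in range(8):
        mask = np.zeros((rows, cols), dtype=bool)
        for ln, wd, ang in zip(lengths * scale, widths * scale, angles):
            r0 = center[0] + 0.5 * ln * np.sin(ang)
            c0 = center[1] + 0.5 * ln * np.cos(ang)
            rr, cc = _draw_ellipse(
                r0, c0, max(ln / 2.0, 1.0), max(wd / 2.0, 1.0),
                shape=(rows, cols), rotation=ang,
            )
            mask[rr, cc] = True
        frac = mask.mean()
        if frac < 0.05:
            scale *= 1.35
        elif frac > 0.60:
            scale *= 0.80
        else:
            return BinaryMask(pixels=mask, method="synthetic")
    raise ParameterizationError(
        f"could not fit {n_leaflets} leaflet(s) into shape {shape} "
        f"with foreground fraction in [0.05, 0.60]"
    )


def gen_image_pair(
    mask: BinaryMask,
    target_fvfm: Union[float, np.ndarray],
    fm_level: float,
    config: GeneratorConfig,
    seed: int = 0,
    plant_id: Optional[str] = None,
    group: Optional[str] = None,
    day: Optional[int] = None,
) -> ImagePair:
    """Invert the Fv/Fm definition: foreground Fm ~= fm_level and
    Fo = Fm * (1 - target), then additive Gaussian noise, clipping at 0 and
    saturation, and integer quantization. Background is near-zero + noise.
    """
    bit_depth = config.bit_depth
    max_val = (1 << bit_depth) - 1
    if fm_level >= (1 << bit_depth):
        raise SaturationError(f"fm_level {fm_level} saturates {bit_depth}-bit range")
    fg = mask.pixels
    shape = fg.shape
    target = np.broadcast_to(np.asarray(target_fvfm, dtype=np.float64), shape)
    tf = target[fg]
    if tf.size and (tf.min() < 0.0 or tf.max() >= 1.0):
        raise ParameterizationError("target_fvfm must satisfy 0 <= value < 1 on foreground")

    fm_clean = np.where(fg, float(fm_level), 0.0)
    fo_clean = fm_clean * (1.0 - target)  # Fo <= Fm guaranteed pre-noise

    rng = _child_rng(seed, 0x1F)
    dtype = np.uint8 if bit_depth == 8 else np.uint16

    def quantize(clean: np.ndarray) -> np.ndarray:
        noisy = clean if config.noise_sd == 0 else clean + rng.normal(0.0, config.noise_sd, shape)
        return np.clip(np.rint(noisy), 0, max_val).astype(dtype)

    fo_px = quantize(fo_clean)
    fm_px = quantize(fm_clean)
    return ImagePair(
        fo=RawImage(fo_px, bit_depth=bit_depth, channel="Fo"),
        fm=RawImage(fm_px, bit_depth=bit_depth, channel="Fm"),
        plant_id=plant_id,
        group=group,
        day=day,
    )


def gen_emex(
    peak_ex: float,
    peak_em: float,
    width_ex: float = 20.0,
    width_em: float = 10.0,
    amplitude: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    day: Optional[int] = None,
    sample_id: Optional[str] = None,
) -> EmexMatrix:
    """Separable Gaussian bump on the standard 201 x 201 EMEX grid
    (excitation 350-550 nm, emission 600-800 nm, 1 nm steps) plus optional
    Gaussian noise, clipped at zero."""
    if not (EXCITATION_AXIS[0] <= peak_ex <= EXCITATION_AXIS[-1]):
        raise ParameterizationError(f"peak_ex {peak_ex} outside [350, 550] nm")
    if not (EMISSION_AXIS[0] <= peak_em <= EMISSION_AXIS[-1]):
        raise ParameterizationError(f"peak_em {peak_em} outside [600, 800] nm")
    if width_ex <= 0 or width_em <= 0:
        raise ParameterizationError("widths must be positive")
    gx = np.exp(-0.5 * ((EXCITATION_AXIS - peak_ex) / width_ex) ** 2)
    gy = np.exp(-0.5 * ((EMISSION_AXIS - peak_em) / width_em) ** 2)
    intensity = amplitude * np.outer(gx, gy)
    if noise_sd > 0:
        rng = _child_rng(seed, 0xE3)
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
    return EmexMatrix(
        excitation=EXCITATION_AXIS.copy(),
        emission=EMISSION_AXIS.copy(),
        intensity=np.clip(intensity, 0.0, None),
        day=day,
        sample_id=sample_id,
    )


@dataclass(frozen=True)
class ExperimentBundle:
    """Ground truth plus a lazy image stream for a synthetic experiment.

    ``truth`` has one row per plant-day: plant_id, group, day, true_fvfm
    (the foreground mean the images were built from) and spad. Images are
    materialized on demand so a full experiment never has to fit in memory.
    """

    config: GeneratorConfig
    truth: pd.DataFrame

    def iter_image_pairs(self) -> Iterator[ImagePair]:
        cfg = self.config
        by_plant = self.truth.groupby("plant_id", sort=False)
        for plant_id, rows in by_plant:
            gi = int(rows["group_index"].iloc[0])
            pi = int(rows["plant_index"].iloc[0])
            trend = cfg.groups[gi]
            mask = gen_plant_mask(cfg.image_shape, cfg.n_leaflets, seed=_mask_seed(cfg.seed, gi, pi))
            for row in rows.itertuples():
                di = int(row.day_index)
                rng = _child_rng(cfg.seed, gi, pi, di, 3)
                fld = row.true_fvfm + (
                    rng.normal(0.0, trend.within_plant_spatial_sd, cfg.image_shape)
                    if trend.within_plant_spatial_sd > 0
                    else 0.0
                )
                fld = np.clip(fld, 0.0, 0.9995)
                yield gen_image_pair(
                    mask,
                    fld,
                    cfg.fm_level,
                    cfg,
                    seed=_pair_seed(cfg.seed, gi, pi, di),
                    plant_id=plant_id,
                    group=trend.name,
                    day=int(row.day),
                )

    def write(self, out_dir: Union[str, Path]) -> Path:
        """Write TIFF pairs, metadata.csv, truth.csv, and config.yaml."""
        out = Path(out_dir)
        images = out / "images"
        images.mkdir(parents=True, exist_ok=True)
        meta_rows = []
        for pair in self.iter_image_pairs():
            fo_name = f"{pair.plant_id}_{pair.day}_Fo.tif"
            fm_name = f"{pair.plant_id}_{pair.day}_Fm.tif"
            tifffile.imwrite(images / fo_name, pair.fo.pixels)
            tifffile.imwrite(images / fm_name, pair.fm.pixels)
            meta_rows.append(
                {
                    "plant_id": pair.plant_id,
                    "group": pair.group,
                    "day": pair.day,
                    "fo_path": f"images/{fo_name}",
                    "fm_path": f"images/{fm_name}",
                }
            )
        meta = pd.DataFrame(meta_rows).merge(
            self.truth[["plant_id", "day", "spad"]], on=["plant_id", "day"]
        )
        meta.to_csv(out / "metadata.csv", index=False)
        self.truth.drop(columns=["group_index", "plant_index", "day_index"]).to_csv(
            out / "truth.csv", index=False
        )
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config_to_dict(self.config), fh, sort_keys=False)
        return out


def _mask_seed(seed: int, gi: int, pi: int) -> int:
    return int(np.random.SeedSequence([seed, gi, pi, 2]).generate_state(1)[0])


def _pair_seed(seed: int, gi: int, pi: int, di: int) -> int:
    return int(np.random.SeedSequence([seed, gi, pi, di, 4]).generate_state(1)[0])


def gen_experiment(config: GeneratorConfig) -> ExperimentBundle:
    """Build the ground-truth table for groups x plants x days.

    Each plant gets a persistent Gaussian offset around its group trend; the
    plant-day true Fv/Fm is the trend value at that day plus the offset, and
    SPAD = spad_slope * true + spad_intercept + noise. Fully reproducible
    from ``config.seed`` (images included, via :meth:`ExperimentBundle.iter_image_pairs`).
    """
    days = config.days
    d0, d1 = float(days[0]), float(days[-1])
    rows = []
    for gi, trend in enumerate(config.groups):
        for pi in range(config.n_plants_per_group):
            offset = float(
                _child_rng(config.seed, gi, pi, 0).normal(0.0, trend.between_plant_sd)
            ) if trend.between_plant_sd > 0 else 0.0
            plant_id = f"{trend.name}_{pi + 1:03d}"
            for di, day in enumerate(days):
                base = trend.mean_at(day, d0, d1) if len(days) > 1 else trend.fvfm_day1
                true = float(np.clip(base + offset, 1e-3, 0.999))
                spad_noise = (
                    float(_child_rng(config.seed, gi, pi, di, 1).normal(0.0, config.spad_noise_sd))
                    if config.spad_noise_sd > 0
                    else 0.0
                )
                spad = config.spad_slope * true + config.spad_intercept + spad_noise
                rows.append(
                    {
                        "plant_id": plant_id,
                        "group": trend.name,
                        "day": int(day),
                        "true_fvfm": true,
                        "spad": spad,
                        "group_index": gi,
                        "plant_index": pi,
                        "day_index": di,
                    }
                )
    return ExperimentBundle(config=config, truth=pd.DataFrame(rows))


def spad_noise_for_target_r(config: GeneratorConfig, rho: float) -> float:
    """SPAD noise SD giving population correlation ``rho`` between the true
    Fv/Fm and SPAD, based on the spread of true Fv/Fm this config generates."""
    if not 0.0 < rho < 1.0:
        raise ParameterizationError(f"rho must be in (0, 1), got {rho}")
    probe = dataclasses.replace(config, spad_noise_sd=0.0)
    sd_x = float(gen_experiment(probe).truth["true_fvfm"].std(ddof=1))
    if sd_x == 0.0:
        raise ParameterizationError("config generates zero Fv/Fm variance; cannot calibrate")
    return abs(config.spad_slope) * sd_x * float(np.sqrt(1.0 / rho**2 - 1.0))


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["image_shape"] = list(config.image_shape)
    d["days"] = list(config.days)
    d["groups"] = [dataclasses.asdict(g) for g in config.groups]
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "groups" in d:
        d["groups"] = tuple(GroupTrend(**g) for g in d["groups"])
    if "image_shape" in d:
        d["image_shape"] = tuple(d["image_shape"])
    if "days" in d:
        d["days"] = tuple(d["days"])
    return GeneratorConfig(**d)
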