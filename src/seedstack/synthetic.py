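"""Synthetic multimodal seed datasets.

Generates the two tables the classification pipeline consumes — a Raman
spectrum table and an image-feature table — with a known, recoverable
class structure:

* spectra are a baseline plus class-dependent Gaussian bands plus iid
  Gaussian noise, on a fixed wavenumber grid (default 400–1800 cm⁻¹ at
  2 cm⁻¹, 700 channels);
* image features (43 named columns: 18 geometric, 7 texture, 18 color)
  are drawn from class-specific multivariate normals sharing one
  covariance matrix.

Every generator is a pure function of a :class:`SyntheticSpec` and its
seed, so outputs are bit-reproducible. The spec records which spectral
channels actually carry class signal (``informative_channels``) so that
feature-selection recovery can be scored against ground truth.

These are stand-ins: no public dataset of this kind exists, and nothing
here models instrument physics (fluorescence background drift, cosmic
spikes) or pixel-level image extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectrumTable",
    "ImageFeatureTable",
    "SyntheticSpec",
    "IMAGE_FEATURE_NAMES",
    "IMAGE_FEATURE_BLOCKS",
    "default_spec",
    "recovery_spec",
    "generate_spectra",
    "generate_image_features",
    "generate_multimodal",
    "write_dataset",
    "read_spectra_csv",
    "read_image_csv",
]


# --------------------------------------------------------------------------- #
# grid and tables
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class WavenumberGrid:
    """Half-open Raman-shift grid [start, stop) in cm⁻¹.

    The default 400–1800 cm⁻¹ at 2 cm⁻¹ steps yields exactly 700 channels
    (the half-open convention resolves the off-by-one an inclusive grid
    would give).
    """

    start: float = 400.0
    stop: float = 1800.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        if self.stop <= self.start:
            raise ValueError("grid stop must exceed start")

    @property
    def n_channels(self) -> int:
        return int(round((self.stop - self.start) / self.step))

    def wavenumbers(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_channels)

    def column_names(self) -> list[str]:
        return [f"wn_{int(round(w)):04d}" for w in self.wavenumbers()]


@dataclass
class SpectrumTable:
    """Sample × wavenumber intensity matrix with labels."""

    intensities: np.ndarray
    grid: WavenumberGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (samples × channels)")
        if self.intensities.shape[1] != self.grid.n_channels:
            raise ValueError(
                f"channel count {self.intensities.shape[1]} does not match "
                f"grid ({self.grid.n_channels} channels)"
            )
        if len(self.labels) != self.intensities.shape[0]:
            raise ValueError("labels length must equal sample count")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.grid.column_names())
        df.insert(0, "label", self.labels)
        return df


@dataclass
class ImageFeatureTable:
    """Sample × named-image-feature matrix with labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values must be n_samples × len(feature_names)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal sample count")
        if not np.isfinite(self.values).all():
            raise ValueError("image features contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        return df


# --------------------------------------------------------------------------- #
# the 43 image feature names (18 geometric, 7 texture, 18 color)
# --------------------------------------------------------------------------- #

_GEOMETRIC = [
    "perimeter",
    "area",
    "long axis length",
    "short axis length",
    "aspect ratio",
    "eccentricity",
    "equivalent diameter",
    "convex area",
    "solidity",
    "extent",
    "rectangularity",
    "circularity",
    "compactness",
    "roundness",
    "perimeter-area ratio",
    "axis ratio",
    "bounding box width",
    "bounding box height",
]
_TEXTURE = [
    "energy",
    "entropy",
    "contrast",
    "grey scale variance product function",
    "correlation",
    "homogeneity",
    "vollath function",
]
_COLOR = [
    "R-mean in RGB space",
    "G-mean in RGB space",
    "B-mean in RGB space",
    "R-variance in RGB space",
    "G-variance in RGB space",
    "B-variance in RGB space",
    "H-mean in HSV space",
    "S-mean in HSV space",
    "V-mean in HSV space",
    "H-variance in HSV space",
    "S-variance in HSV space",
    "V-variance in HSV space",
    "L-mean in LAB space",
    "A-mean in LAB space",
    "B-mean in LAB space",
    "L-variance in LAB space",
    "A-variance in LAB space",
    "B-variance in LAB space",
]

IMAGE_FEATURE_NAMES: list[str] = _GEOMETRIC + _TEXTURE + _COLOR
IMAGE_FEATURE_BLOCKS: dict[str, list[str]] = {
    "geometric": _GEOMETRIC,
    "texture": _TEXTURE,
    "color": _COLOR,
}


# --------------------------------------------------------------------------- #
# spec
# --------------------------------------------------------------------------- #

@dataclass
class SyntheticSpec:
    """Full description of one synthetic multimodal dataset.

    ``peak_centers/heights/widths`` are per-class lists (one list of bands
    per class; widths are Gaussian standard deviations in cm⁻¹).
    ``baseline`` is either a constant intensity or polynomial coefficients
    (lowest order first) over the normalized axis u ∈ [0, 1].
    """

    n_classes: int
    n_per_class: int
    peak_centers: list[list[float]]
    peak_heights: list[list[float]]
    peak_widths: list[list[float]]
    baseline: float | list[float] = 0.0
    noise_sd: float = 0.0
    image_class_means: np.ndarray | None = None
    image_cov: np.ndarray | None = None
    image_feature_names: list[str] = field(
        default_factory=lambda: list(IMAGE_FEATURE_NAMES)
    )
    class_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        for name in ("peak_centers", "peak_heights", "peak_widths"):
            val = getattr(self, name)
            if len(val) != self.n_classes:
                raise ValueError(f"{name} must have one list per class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.class_names is None:
            # A, B, C, ... as in variety coding
            self.class_names = [chr(ord("A") + c) for c in range(self.n_classes)]
        if self.image_class_means is not None:
            self.image_class_means = np.asarray(self.image_class_means, dtype=float)
            if self.image_class_means.shape != (
                self.n_classes,
                len(self.image_feature_names),
            ):
                raise ValueError(
                    "image_class_means must be n_classes × n_image_features"
                )
        if self.image_cov is not None:
            self.image_cov = np.asarray(self.image_cov, dtype=float)
            _check_psd(self.image_cov, len(self.image_feature_names))

    # ------------------------------------------------------------------ #

    def labels(self) -> np.ndarray:
        return np.repeat(np.asarray(self.class_names, dtype=object), self.n_per_class)

    def class_mean_spectra(self, grid: WavenumberGrid) -> np.ndarray:
        """Noiseless per-class mean spectra (n_classes × n_channels)."""
        w = grid.wavenumbers()
        base = _baseline_values(self.baseline, grid)
        means = np.tile(base, (self.n_classes, 1))
        for c in range(self.n_classes):
            for center, height, width in zip(
                self.peak_centers[c], self.peak_heights[c], self.peak_widths[c]
            ):
                if center < grid.start or center > w[-1]:
                    raise ValueError(
                        f"peak center {center} cm⁻¹ lies outside the grid "
                        f"[{grid.start}, {w[-1]}]"
                    )
                means[c] += height * np.exp(-0.5 * ((w - center) / width) ** 2)
        return means

    def informative_channels(
        self, grid: WavenumberGrid, rel_tol: float = 0.01
    ) -> np.ndarray:
        """Channel indices whose noiseless class means actually differ.

        A channel is informative when its between-class spread exceeds
        ``rel_tol`` times the largest spread anywhere on the grid.
        """
        means = self.class_mean_spectra(grid)
        spread = means.max(axis=0) - means.min(axis=0)
        if spread.max() <= 0:
            return np.empty(0, dtype=int)
        return np.flatnonzero(spread > rel_tol * spread.max())

    def to_json_dict(self, grid: WavenumberGrid) -> dict:
        return {
            "seed": int(self.seed),
            "n_classes": int(self.n_classes),
            "n_per_class": int(self.n_per_class),
            "class_names": list(self.class_names),
            "grid": {
                "start": grid.start,
                "stop": grid.stop,
                "step": grid.step,
                "n_channels": grid.n_channels,
            },
            "peak_centers": [list(map(float, p)) for p in self.peak_centers],
            "peak_heights": [list(map(float, p)) for p in self.peak_heights],
            "peak_widths": [list(map(float, p)) for p in self.peak_widths],
            "baseline": self.baseline
            if isinstance(self.baseline, (int, float))
            else list(map(float, self.baseline)),
            "noise_sd": float(self.noise_sd),
            "informative_channel_ids": self.informative_channels(grid).tolist(),
        }


def _check_psd(cov: np.ndarray, n: int) -> None:
    if cov.shape != (n, n):
        raise ValueError(f"covariance must be {n}×{n}, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance matrix is not symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals.max())):
        raise ValueError(
            f"covariance matrix is not positive semidefinite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )


def _baseline_values(baseline, grid: WavenumberGrid) -> np.ndarray:
    if isinstance(baseline, (int, float)):
        return np.full(grid.n_channels, float(baseline))
    coeffs = np.asarray(baseline, dtype=float)
    u = np.linspace(0.0, 1.0, grid.n_channels)
    return np.polynomial.polynomial.polyval(u, coeffs)


# --------------------------------------------------------------------------- #
# default study conditions: 7 varieties × 100 seeds
# --------------------------------------------------------------------------- #

# Shared Raman band set (cm⁻¹): starch skeletal/C-O-C modes (478, 864, 940,
# 1080, 1340), phenylalanine ring breathing (1002), amide III (1265),
# CH₂ deformation (1460), amide I region (1605), lipid C=O ester (1745).
_DEFAULT_CENTERS = [478, 520, 640, 864, 940, 1002, 1080, 1265, 1340, 1460, 1605, 1745]
_DEFAULT_HEIGHTS = [80, 30, 25, 45, 50, 35, 60, 30, 40, 55, 35, 20]
_DEFAULT_WIDTHS = [6, 4.5, 5, 6, 6, 3.5, 7, 6, 6, 6, 8, 4.5]

# Fixed per-class band-height modulation pattern; varieties differ in relative
# band intensities (composition), not band positions.
_SIGNATURE_SEED = 20260108


def default_spec(
    seed: int = 0,
    n_classes: int = 7,
    n_per_class: int = 100,
    class_separation: float = 0.065,
    noise_sd: float = 5.0,
    image_separation: float = 0.03,
    image_cv: float = 0.12,
) -> SyntheticSpec:
    """Default synthetic study conditions: 7 balanced varieties of 100 seeds.

    ``class_separation`` scales the per-class relative modulation of band
    heights; ``image_separation`` does the same for image-feature means;
    ``image_cv`` is the per-feature coefficient of variation. Defaults are
    calibrated so the varieties are separable but not trivially so.
    """
    sig_rng = np.random.default_rng(_SIGNATURE_SEED)
    n_bands = len(_DEFAULT_CENTERS)
    band_mod = sig_rng.standard_normal((n_classes, n_bands))
    base_h = np.asarray(_DEFAULT_HEIGHTS, dtype=float)
    heights = [
        (base_h * (1.0 + class_separation * band_mod[c])).tolist()
        for c in range(n_classes)
    ]

    n_feat = len(IMAGE_FEATURE_NAMES)
    base_means = _default_image_base_means()
    feat_mod = sig_rng.standard_normal((n_classes, n_feat))
    image_means = base_means * (1.0 + image_separation * feat_mod)
    image_cov = _default_image_cov(base_means, image_cv)

    return SyntheticSpec(
        n_classes=n_classes,
        n_per_class=n_per_class,
        peak_centers=[list(_DEFAULT_CENTERS)] * n_classes,
        peak_heights=heights,
        peak_widths=[list(_DEFAULT_WIDTHS)] * n_classes,
        baseline=[40.0, -15.0, 6.0],  # gentle sloping background
        noise_sd=noise_sd,
        image_class_means=image_means,
        image_cov=image_cov,
        seed=seed,
    )


def recovery_spec(
    seed: int = 0,
    n_classes: int = 3,
    n_per_class: int = 70,
    n_channels: int = 200,
    n_informative: int = 5,
    peak_height: float = 10.0,
    height_modulation: float = 0.3,
    noise_sd: float = 0.5,
) -> tuple[SyntheticSpec, WavenumberGrid]:
    """Spectra-only spec for feature-selection recovery experiments.

    Exactly ``n_informative`` channels carry class signal: sub-channel-width
    bands (sd = 0.3 grid steps, so neighbouring channels see < 0.4% of the
    band) at evenly spaced on-grid centers, with per-class heights
    ``peak_height · (1 ± height_modulation)``. Each channel's class-height
    pattern is a randomly permuted linear contrast, so every informative
    channel separates at least two classes by the full modulation span while
    the contrast *direction* varies between channels. Patterns are drawn from
    the seed, so repeated seeds give independent instances.
    ``spec.informative_channels(grid)`` returns exactly those channel ids.
    """
    grid = WavenumberGrid(400.0, 400.0 + 2.0 * n_channels, 2.0)
    w = grid.wavenumbers()
    channel_ids = np.linspace(0, n_channels - 1, n_informative + 2)[1:-1].round().astype(int)
    centers = w[channel_ids]
    rng = np.random.default_rng(seed + 7_000_000)
    contrast = np.linspace(-1.0, 1.0, n_classes)
    pattern = np.column_stack(
        [rng.permutation(contrast) for _ in range(n_informative)]
    )
    heights = [
        (peak_height * (1.0 + height_modulation * pattern[c])).tolist()
        for c in range(n_classes)
    ]
    spec = SyntheticSpec(
        n_classes=n_classes,
        n_per_class=n_per_class,
        peak_centers=[centers.tolist()] * n_classes,
        peak_heights=heights,
        peak_widths=[[0.3 * grid.step] * n_informative] * n_classes,
        baseline=1.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    return spec, grid


def _default_image_base_means() -> np.ndarray:
    """Plausible magnitudes for a ~4 mm seed imaged at fixed scale."""
    geometric = [13.5, 14.0, 4.8, 3.7, 1.30, 0.63, 4.2, 14.6, 0.96, 0.76,
                 0.79, 0.80, 1.25, 0.78, 0.96, 0.77, 4.9, 3.9]
    texture = [0.22, 4.6, 35.0, 120.0, 0.85, 0.55, 18.0]
    color = [96.0, 135.0, 70.0, 210.0, 260.0, 140.0,   # RGB mean/var
             0.32, 0.48, 0.55, 0.004, 0.009, 0.012,    # HSV mean/var
             52.0, -14.0, 30.0, 38.0, 9.0, 14.0]       # LAB mean/var
    return np.asarray(geometric + texture + color, dtype=float)


def _default_image_cov(base_means: np.ndarray, cv: float) -> np.ndarray:
    """Within-block correlation 0.3, per-feature sd = cv·|mean| (floored)."""
    sd = np.maximum(cv * np.abs(base_means), 1e-3)
    n = len(base_means)
    corr = np.eye(n)
    start = 0
    for block in IMAGE_FEATURE_BLOCKS.values():
        stop = start + len(block)
        corr[start:stop, start:stop] = 0.3
        start = stop
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sd, sd)


# --------------------------------------------------------------------------- #
# generators
# --------------------------------------------------------------------------- #

def _modality_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def generate_spectra(
    spec: SyntheticSpec, grid: WavenumberGrid | None = None
) -> SpectrumTable:
    """Draw the spectrum table: class mean + iid N(0, noise_sd²) per channel."""
    grid = grid or WavenumberGrid()
    rng, _ = _modality_rngs(spec.seed)
    means = spec.class_mean_spectra(grid)
    rows = np.repeat(means, spec.n_per_class, axis=0)
    if spec.noise_sd > 0:
        rows = rows + rng.normal(0.0, spec.noise_sd, size=rows.shape)
    return SpectrumTable(rows, grid, spec.labels())


def generate_image_features(spec: SyntheticSpec) -> ImageFeatureTable:
    """Draw the image-feature table from class-specific multivariate normals."""
    if spec.image_class_means is None or spec.image_cov is None:
        raise ValueError("spec must define image_class_means and image_cov")
    _, rng = _modality_rngs(spec.seed)
    blocks = [
        rng.multivariate_normal(
            spec.image_class_means[c], spec.image_cov,
            size=spec.n_per_class, method="svd",
        )
        for c in range(spec.n_classes)
    ]
    return ImageFeatureTable(
        np.vstack(blocks), list(spec.image_feature_names), spec.labels()
    )


def generate_multimodal(
    spec: SyntheticSpec, grid: WavenumberGrid | None = None
) -> tuple[SpectrumTable, ImageFeatureTable]:
    """Both tables with identical sample order and labels."""
    grid = grid or WavenumberGrid()
    spectra = generate_spectra(spec, grid)
    images = generate_image_features(spec)
    return spectra, images


# --------------------------------------------------------------------------- #
# I/O
# --------------------------------------------------------------------------- #

def write_dataset(
    out_dir: str | Path,
    spectra: SpectrumTable,
    images: ImageFeatureTable,
    spec: SyntheticSpec | None = None,
) -> dict[str, Path]:
    """Write spectra.csv, image_features.csv and (optionally) spec.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": out / "spectra.csv",
        "images": out / "image_features.csv",
    }
    spectra.to_dataframe().to_csv(paths["spectra"], index=False)
    images.to_dataframe().to_csv(paths["images"], index=False)
    if spec is not None:
        paths["spec"] = out / "spec.json"
        paths["spec"].write_text(json.dumps(spec.to_json_dict(spectra.grid), indent=1))
    return paths


def read_spectra_csv(path: str | Path, grid: WavenumberGrid | None = None) -> SpectrumTable:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy()
    wn_cols = [c for c in df.columns if c.startswith("wn_")]
    if grid is None:
        wns = np.array([float(c[3:]) for c in wn_cols])
        step = float(np.median(np.diff(wns))) if len(wns) > 1 else 2.0
        grid = WavenumberGrid(wns[0], wns[-1] + step, step)
    return SpectrumTable(df[wn_cols].to_numpy(float), grid, labels)


def read_image_csv(path: str | Path) -> ImageFeatureTable:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy()
    return ImageFeatureTable(df.to_numpy(float), list(df.columns), labels)
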