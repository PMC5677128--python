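"""Predator-vision conspicuousness analysis of hyperspectral scenes.

Given a radiance cube (H x W x B bands, default 16 bands spanning
360-660 nm) with a butterfly mask against a textured background, computes:

* luminance (per-pixel sum over bands) and the percent luminance change of
  butterfly pixels against the mean background luminance;
* a granularity spectrum — image power partitioned over seven equal-width
  radial spatial-frequency bands — and the Kullback-Leibler divergence
  between butterfly and background spectra;
* per-pixel chromatic just-noticeable differences (JND) under the
  receptor-noise-limited model of color discrimination, for any number of
  receptor classes (dichromat through tetrachromat), against the average
  background spectrum.  Contrasts are logarithmic quantum-catch ratios, so
  chromatic JND is exactly invariant under global illumination scaling.

Receptor sensitivities, cone abundances and the Weber fraction are inputs;
the bundled trichromat/tetrachromat models use synthetic Gaussian pigment
templates as placeholders for measured curves.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "HyperspectralCube",
    "ReceptorModel",
    "GranularitySpectrum",
    "JNDResult",
    "luminance_map",
    "percent_luminance_change",
    "granularity_spectrum",
    "kl_divergence",
    "quantum_catches",
    "jnd_map",
    "jnd_summary",
    "write_cube",
    "read_cube",
    "write_mask",
    "read_mask",
]


@dataclass
class HyperspectralCube:
    """Radiance image: (H, W, B) array plus band-center wavelengths in nm."""

    radiance: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.radiance.ndim != 3:
            raise ValueError("radiance must be (H, W, B)")
        if self.radiance.shape[2] != self.wavelengths.size:
            raise ValueError("band count must match wavelengths")
        if self.wavelengths.size < 2:
            raise ValueError("need at least two bands")
        if not (np.diff(self.wavelengths) > 0).all():
            raise ValueError("wavelengths must be strictly increasing")
        if (self.radiance < 0).any():
            raise ValueError("radiance must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.radiance.shape


def _check_mask(mask: np.ndarray, cube: HyperspectralCube) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape must match the image")
    if not mask.any() or mask.all():
        raise ValueError("both butterfly and background regions must be non-empty")
    return mask


@dataclass
class ReceptorModel:
    """A receptor-noise-limited observer.

    sensitivities : (n_classes, B) spectral sensitivities at the cube's bands
    abundances : relative cone abundances eta per class
    weber_fraction : Weber fraction nu of the reference (most abundant) class
    reference_class : index of the reference class (default: most abundant)

    Per-class noise is e_i = nu * sqrt(eta_ref / eta_i).
    """

    sensitivities: np.ndarray
    abundances: np.ndarray
    weber_fraction: float = 0.05
    reference_class: int | None = None

    def __post_init__(self) -> None:
        self.sensitivities = np.atleast_2d(np.asarray(self.sensitivities, float))
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.sensitivities.shape[0] != self.abundances.size:
            raise ValueError("one abundance per receptor class required")
        if (self.sensitivities < 0).any() or not (
            self.sensitivities.sum(axis=1) > 0
        ).all():
            raise ValueError("sensitivities must be non-negative with positive sums")
        if (self.abundances <= 0).any():
            raise ValueError("abundances must be positive")
        if self.weber_fraction <= 0:
            raise ValueError("weber_fraction must be positive")
        if self.reference_class is None:
            self.reference_class = int(np.argmax(self.abundances))

    @property
    def n_classes(self) -> int:
        return self.sensitivities.shape[0]

    @property
    def noise(self) -> np.ndarray:
        eta_ref = self.abundances[self.reference_class]
        return self.weber_fraction * np.sqrt(eta_ref / self.abundances)

    @classmethod
    def gaussian_templates(
        cls,
        wavelengths: Sequence[float],
        peaks: Sequence[float],
        abundances: Sequence[float],
        sigma: float = 40.0,
        weber_fraction: float = 0.05,
    ) -> "ReceptorModel":
        """Synthetic Gaussian pigment templates (placeholder sensitivities)."""
        wl = np.asarray(wavelengths, dtype=float)
        sens = np.exp(-0.5 * ((wl[None, :] - np.asarray(peaks)[:, None]) / sigma) ** 2)
        return cls(sens, np.asarray(abundances, float), weber_fraction)

    @classmethod
    def trichromat(cls, wavelengths: Sequence[float]) -> "ReceptorModel":
        """Synthetic trichromat (human-like S/M/L peaks 420/534/564 nm)."""
        return cls.gaussian_templates(wavelengths, (420, 534, 564), (1, 2, 4))

    @classmethod
    def tetrachromat(cls, wavelengths: Sequence[float]) -> "ReceptorModel":
        """Synthetic tetrachromat (songbird-like UV/S/M/L 370/445/508/565 nm)."""
        return cls.gaussian_templates(
            wavelengths, (370, 445, 508, 565), (1, 2, 2, 4)
        )

    def to_json(self, path: str | Path, wavelengths: Sequence[float]) -> None:
        payload = {
            "wavelengths_nm": list(map(float, wavelengths)),
            "sensitivities": self.sensitivities.tolist(),
            "abundances": self.abundances.tolist(),
            "weber_fraction": self.weber_fraction,
            "reference_class": int(self.reference_class),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReceptorModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["sensitivities"]),
            np.asarray(payload["abundances"]),
            payload["weber_fraction"],
            payload.get("reference_class"),
        )


def luminance_map(cube: HyperspectralCube) -> np.ndarray:
    """Per-pixel luminance: the sum of radiance across bands."""
    return cube.radiance.sum(axis=2)


def percent_luminance_change(
    cube: HyperspectralCube, mask: np.ndarray
) -> tuple[float, float]:
    """Mean and SD of per-pixel percent luminance change vs the background.

    Each butterfly pixel contributes 100 * (L - mean background L) / (mean
    background L).
    """
    mask = _check_mask(mask, cube)
    lum = luminance_map(cube)
    bg_mean = lum[~mask].mean()
    if bg_mean <= 0:
        raise ValueError("background luminance must be positive")
    change = 100.0 * (lum[mask] - bg_mean) / bg_mean
    return float(change.mean()), float(change.std())


@dataclass(frozen=True)
class GranularitySpectrum:
    """Power fractions over radial spatial-frequency bands (sum to 1)."""

    energies: np.ndarray
    band_edges: np.ndarray  # n_bands + 1 edges in cycles/pixel
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "energies", np.asarray(self.energies, float))
        object.__setattr__(self, "band_edges", np.asarray(self.band_edges, float))
        if (self.energies < 0).any():
            raise ValueError("band energies must be non-negative")
        if abs(self.energies.sum() - 1.0) > 1e-9:
            raise ValueError("band energies must sum to 1")


def granularity_spectrum(
    image: np.ndarray, mask: np.ndarray, n_bands: int = 7
) -> GranularitySpectrum:
    """Spatial-frequency power spectrum of a masked region in ``n_bands`` bands.

    The region is mean-subtracted, its complement zero-filled, and 2-D
    Fourier power is binned into equal-width radial-frequency annuli from
    the full-image scale up to the Nyquist frequency.  A constant region is
    degenerate: by convention its spectrum is uniform, with a flag set.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape or image.ndim != 2:
        raise ValueError("image and mask must be matching 2-D arrays")
    n_pix = int(mask.sum())
    if n_pix < 2:
        raise ValueError("region must contain at least two pixels")
    region = np.zeros_like(image)
    region[mask] = image[mask] - image[mask].mean()

    h, w = image.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.sqrt(fy**2 + fx**2)
    power = np.abs(np.fft.fft2(region)) ** 2

    f_low = 1.0 / max(h, w)  # full-image scale
    edges = np.linspace(f_low, 0.5, n_bands + 1)
    energies = np.zeros(n_bands)
    # residual power below the lowest band edge joins the lowest band
    band_index = np.clip(
        np.searchsorted(edges, radius, side="right") - 1, 0, n_bands - 1
    )
    total = power.sum() - power[0, 0]  # drop the (zero) DC term explicitly
    if total <= 0:
        return GranularitySpectrum(
            np.full(n_bands, 1.0 / n_bands), edges, degenerate=True
        )
    flat_power = power.copy()
    flat_power[0, 0] = 0.0
    np.add.at(energies, band_index.ravel(), flat_power.ravel())
    return GranularitySpectrum(energies / total, edges)


def kl_divergence(
    p: GranularitySpectrum, q: GranularitySpectrum, eps: float = 1e-9
) -> float:
    """KL(p || q) between two granularity spectra with additive smoothing."""
    if p.energies.size != q.energies.size or not np.allclose(
        p.band_edges, q.band_edges
    ):
        raise ValueError("spectra must share the same band structure")
    a = p.energies + eps
    b = q.energies + eps
    a = a / a.sum()
    b = b / b.sum()
    return float(np.sum(a * np.log(a / b)))


def quantum_catches(
    spectrum: np.ndarray, receptors: ReceptorModel, wavelengths: np.ndarray
) -> np.ndarray:
    """Receptor quantum catches Q_i = sum_b radiance_b * S_i(b) * dlambda_b."""
    spectrum = np.asarray(spectrum, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if spectrum.shape[-1] != receptors.sensitivities.shape[1]:
        raise ValueError("spectrum band count must match receptor sampling")
    dl = np.gradient(wl)
    return spectrum @ (receptors.sensitivities * dl).T


def _rnl_distance(df: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """Receptor-noise-limited chromatic distance for n >= 2 receptor classes.

    df : (..., n) log-contrast vectors; noise : (n,) per-class noise.
    For each receptor pair the squared contrast difference is weighted by
    the squared product of the noises of all *other* classes; the
    denominator is the sum over (n-1)-subsets of squared noise products.
    For n = 2 this reduces to |df1 - df2| / sqrt(e1^2 + e2^2).
    """
    n = noise.size
    num = np.zeros(df.shape[:-1])
    for i, j in itertools.combinations(range(n), 2):
        others = [k for k in range(n) if k not in (i, j)]
        weight = np.prod(noise[others]) ** 2 if others else 1.0
        num = num + weight * (df[..., i] - df[..., j]) ** 2
    den = 0.0
    for subset in itertools.combinations(range(n), n - 1):
        den += np.prod(noise[list(subset)]) ** 2
    return np.sqrt(num / den)


@dataclass
class JNDResult:
    """Per-pixel chromatic JND over the butterfly mask."""

    jnd: np.ndarray  # (H, W), NaN outside the mask and at excluded pixels
    mask: np.ndarray
    mean: float
    sd: float
    n_excluded: int


def jnd_map(
    cube: HyperspectralCube, mask: np.ndarray, receptors: ReceptorModel
) -> JNDResult:
    """Chromatic JND of each butterfly pixel against the average background.

    The reference is the mean background radiance spectrum; per-pixel
    contrasts are Delta f_i = ln(Q_i(pixel) / Q_i(reference)).  Pixels with
    a non-positive quantum catch in any class are excluded and counted.
    """
    mask = _check_mask(mask, cube)
    reference = cube.radiance[~mask].mean(axis=0)
    q_ref = quantum_catches(reference, receptors, cube.wavelengths)
    if (q_ref <= 0).any():
        raise ValueError("background reference has a non-positive quantum catch")
    pix = cube.radiance[mask]
    q_pix = quantum_catches(pix, receptors, cube.wavelengths)
    valid = (q_pix > 0).all(axis=1)
    df = np.log(q_pix[valid] / q_ref)
    values = _rnl_distance(df, receptors.noise)
    out = np.full(cube.shape[:2], np.nan)
    flat = np.full(pix.shape[0], np.nan)
    flat[valid] = values
    out[mask] = flat
    return JNDResult(
        jnd=out,
        mask=mask,
        mean=float(values.mean()) if values.size else math.nan,
        sd=float(values.std()) if values.size else math.nan,
        n_excluded=int((~valid).sum()),
    )


def jnd_summary(
    result: JNDResult, n_bins: int = 30, log_floor: float = 1e-3
) -> dict:
    """Mean, SD, and a normalized histogram of JND on a log axis."""
    values = result.jnd[np.isfinite(result.jnd)]
    if values.size == 0:
        raise ValueError("no valid JND pixels")
    clipped = np.maximum(values, log_floor)
    edges = np.geomspace(clipped.min(), max(clipped.max(), log_floor * 1.01), n_bins + 1)
    hist, edges = np.histogram(clipped, bins=edges)
    density = hist / hist.sum()
    return {
        "mean": float(values.mean()),
        "sd": float(values.std()),
        "n": int(values.size),
        "bin_edges": edges,
        "density": density,
    }


# ---------------------------------------------------------------------------
# simple band-stack cube I/O (flat float32 binary + JSON sidecar)


def write_cube(cube: HyperspectralCube, path: str | Path) -> None:
    path = Path(path)
    cube.radiance.astype("<f4").tofile(path)
    sidecar = {
        "shape": list(cube.shape),
        "dtype": "<f4",
        "order": "HWB",
        "wavelengths_nm": cube.wavelengths.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_cube(path: str | Path) -> HyperspectralCube:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=sidecar["dtype"]).reshape(sidecar["shape"])
    return HyperspectralCube(data.astype(float), np.asarray(sidecar["wavelengths_nm"]))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")


def read_mask(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).astype(bool)
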