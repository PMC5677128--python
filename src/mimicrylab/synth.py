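"""Synthetic-data generators with known ground truth.

Every downstream analysis in the package can run on data built here: a
random stop-free ancestral coding sequence, a phased haplotype panel with
two diverged (inversion-like) haplogroups and planted group-specific SNPs,
and a hyperspectral scene with a textured background and a masked butterfly
of programmed reflectance.  Each generator is a pure function of its spec
plus seed, and returns a truth record sufficient to compute exact expected
analysis output in noiseless settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codon import CODON_AA, CODON_STRINGS, CodonSequence
from .haplotypes import MISSING, HaplotypeMatrix, write_phased_vcf
from .vision import HyperspectralCube, ReceptorModel, write_cube, write_mask

__all__ = [
    "PanelSpec",
    "PanelTruth",
    "SceneSpec",
    "SceneTruth",
    "generate_gmrca",
    "generate_haplotype_panel",
    "generate_scene",
    "write_fixtures",
]

_SENSE_CODONS = [c for c, aa in zip(CODON_STRINGS, CODON_AA) if aa != "*"]


def generate_gmrca(
    n_codons: int, rng: np.random.Generator, start_with_atg: bool = False
) -> CodonSequence:
    """Uniform random stop-free coding sequence of ``n_codons`` codons."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    codons = [_SENSE_CODONS[i] for i in idx]
    if start_with_atg:
        codons[0] = "ATG"
    return CodonSequence("".join(codons))


@dataclass(frozen=True)
class PanelSpec:
    """Phased haplotype panel with planted group-specific SNPs.

    n_target, n_reference : haplotypes per group (even, two per sample)
    n_sites : total SNP sites
    n_planted : sites fixed for a private allele in the target group
    divergence : per-site probability of an inversion-like fixed difference
        between the two haplogroups
    background_freq : (low, high) range of the shared-polymorphism
        alternative-allele frequency per site
    missing_rate : per-call missing probability (planted sites exempt, so
        the planted truth satisfies the group-specific predicate exactly)
    """

    n_target: int = 6
    n_reference: int = 4
    n_sites: int = 1000
    n_planted: int = 110
    divergence: float = 0.05
    background_freq: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    target_group: str = "theseus"
    reference_group: str = "polytes"
    contig: str = "dsx_inversion"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_planted > self.n_sites:
            raise ValueError("cannot plant more sites than exist")
        if self.n_target % 2 or self.n_reference % 2:
            raise ValueError("haplotypes per group must be even (diploid samples)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class PanelTruth:
    planted_positions: tuple[int, ...]
    divergent_positions: tuple[int, ...]
    spec: PanelSpec


def generate_haplotype_panel(spec: PanelSpec) -> tuple[HaplotypeMatrix, PanelTruth]:
    """Build the panel; target-group rows come first, then reference rows."""
    rng = np.random.default_rng(spec.seed)
    n_hap = spec.n_target + spec.n_reference
    positions = np.sort(
        rng.choice(np.arange(1, spec.n_sites * 10 + 1), spec.n_sites, replace=False)
    )
    alleles = np.zeros((n_hap, spec.n_sites), dtype=np.int16)
    t_rows = np.arange(spec.n_target)
    r_rows = np.arange(spec.n_target, n_hap)

    site_kind = np.zeros(spec.n_sites, dtype=np.int8)  # 0 bg, 1 planted, 2 divergent
    planted_idx = rng.choice(spec.n_sites, spec.n_planted, replace=False)
    site_kind[planted_idx] = 1
    divergent = (rng.random(spec.n_sites) < spec.divergence) & (site_kind == 0)
    site_kind[divergent] = 2

    lo, hi = spec.background_freq
    bg_freq = rng.uniform(lo, hi, size=spec.n_sites)
    for j in range(spec.n_sites):
        if site_kind[j] == 1:
            alleles[t_rows, j] = 1
        elif site_kind[j] == 2:
            # inversion-like fixed difference between haplogroups
            alleles[t_rows, j] = 1
            alleles[r_rows, j] = 0
        else:
            carrier = rng.random(n_hap) < bg_freq[j]
            alleles[carrier, j] = 1
    if spec.missing_rate > 0:
        miss = rng.random(alleles.shape) < spec.missing_rate
        miss[:, site_kind == 1] = False
        alleles[miss] = MISSING

    samples = [f"{spec.target_group}{i + 1}" for i in range(spec.n_target // 2)] + [
        f"{spec.reference_group}{i + 1}" for i in range(spec.n_reference // 2)
    ]
    hap_ids = [f"{s}_h{i}" for s in samples for i in (1, 2)]
    groups = [spec.target_group] * spec.n_target + [
        spec.reference_group
    ] * spec.n_reference
    labels = pd.DataFrame(
        {"sample": [s for s in samples for _ in (1, 2)], "group": groups},
        index=hap_ids,
    )
    matrix = HaplotypeMatrix(
        contig=spec.contig,
        positions=positions,
        alleles=alleles,
        labels=labels,
        site_alleles=[("A", "T")] * spec.n_sites,
    )
    truth = PanelTruth(
        planted_positions=tuple(int(p) for p in np.sort(positions[planted_idx])),
        divergent_positions=tuple(int(p) for p in positions[site_kind == 2]),
        spec=spec,
    )
    return matrix, truth


@dataclass(frozen=True)
class SceneSpec:
    """Hyperspectral scene: textured green background plus a butterfly patch.

    The background per-pixel spectrum is a Gaussian "leaf green" profile
    modulated by an isotropic 1/f spatial texture field of relative
    amplitude ``texture_amplitude``.  The butterfly is an axis-aligned
    ellipse; its reflectance is ``butterfly_spectrum`` when given, else the
    background profile scaled by ``butterfly_scale``.  ``illumination``
    scales the whole cube.
    """

    height: int = 64
    width: int = 64
    n_bands: int = 16
    wavelength_range: tuple[float, float] = (360.0, 660.0)
    background_peak: float = 550.0
    background_width: float = 60.0
    background_level: float = 1.0
    texture_amplitude: float = 0.2
    butterfly_spectrum: tuple[float, ...] | None = None
    butterfly_scale: float = 1.0
    ellipse_axes: tuple[float, float] = (0.25, 0.35)  # fractions of H, W
    illumination: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.height < 4 or self.width < 4:
            raise ValueError("scene must be at least 4x4")
        if self.n_bands < 2:
            raise ValueError("need at least two bands")
        if self.butterfly_spectrum is not None and len(
            self.butterfly_spectrum
        ) != self.n_bands:
            raise ValueError("butterfly_spectrum length must equal n_bands")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)

    @property
    def background_profile(self) -> np.ndarray:
        wl = self.wavelengths
        return self.background_level * np.exp(
            -0.5 * ((wl - self.background_peak) / self.background_width) ** 2
        )


@dataclass(frozen=True)
class SceneTruth:
    percent_luminance_change: float
    butterfly_spectrum: tuple[float, ...]
    background_profile: tuple[float, ...]
    spec: SceneSpec


def _one_over_f_field(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Isotropic 1/f-amplitude noise field, zero mean, unit SD."""
    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.sqrt(fy**2 + fx**2)
    radius[0, 0] = np.inf  # kill DC
    spectrum = np.fft.fft2(white) / radius
    spectrum[0, 0] = 0.0
    f = np.real(np.fft.ifft2(spectrum))
    return (f - f.mean()) / f.std()


def generate_scene(
    spec: SceneSpec,
) -> tuple[HyperspectralCube, np.ndarray, SceneTruth]:
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ry, rx = spec.ellipse_axes[0] * h, spec.ellipse_axes[1] * w
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    profile = spec.background_profile
    if spec.butterfly_spectrum is not None:
        bfly = np.asarray(spec.butterfly_spectrum, dtype=float)
    else:
        bfly = profile * spec.butterfly_scale

    if spec.texture_amplitude > 0:
        field_arr = 1.0 + spec.texture_amplitude * _one_over_f_field(h, w, rng)
        field_arr = np.clip(field_arr, 0.05, None)
    else:
        field_arr = np.ones((h, w))
    radiance = field_arr[:, :, None] * profile[None, None, :]
    radiance[mask] = bfly[None, :]
    radiance *= spec.illumination
    cube = HyperspectralCube(radiance, spec.wavelengths)
    truth = SceneTruth(
        percent_luminance_change=float(
            100.0 * (bfly.sum() - profile.sum()) / profile.sum()
        ),
        butterfly_spectrum=tuple(float(v) for v in bfly),
        background_profile=tuple(float(v) for v in profile),
        spec=spec,
    )
    return cube, mask, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a small deterministic fixture set and return its manifest.

    Files: ancestral FASTA, phased VCF + label TSV, hyperspectral cube
    (band-stack binary + JSON sidecar), mask matrix, receptor-model JSON,
    and ``manifest.json`` listing every file with its SHA-256 digest plus
    the generator truths.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gmrca = generate_gmrca(60, rng)
    fasta = out / "gmrca.fasta"
    SeqIO.write(
        [SeqRecord(Seq(gmrca.sequence), id="GMRCA", description="")], fasta, "fasta"
    )

    panel_spec = PanelSpec(
        n_target=6, n_reference=4, n_sites=200, n_planted=25, seed=seed
    )
    matrix, panel_truth = generate_haplotype_panel(panel_spec)
    vcf_path = out / "panel.vcf"
    write_phased_vcf(matrix, vcf_path)
    labels_path = out / "panel_labels.tsv"
    matrix.labels.to_csv(labels_path, sep="\t", index_label="haplotype")

    scene_spec = SceneSpec(height=32, width=32, butterfly_scale=1.5, seed=seed)
    cube, mask, scene_truth = generate_scene(scene_spec)
    cube_path = out / "scene.cube"
    write_cube(cube, cube_path)
    mask_path = out / "scene_mask.txt"
    write_mask(mask, mask_path)

    receptors = ReceptorModel.tetrachromat(cube.wavelengths)
    receptor_path = out / "tetrachromat.json"
    receptors.to_json(receptor_path, cube.wavelengths)

    files = [
        fasta,
        vcf_path,
        labels_path,
        cube_path,
        cube_path.with_suffix(cube_path.suffix + ".json"),
        mask_path,
        receptor_path,
    ]
    manifest = {
        "seed": seed,
        "files": {f.name: _sha256(f) for f in files},
        "truths": {
            "gmrca_n_codons": gmrca.n_codons,
            "panel_planted_positions": list(panel_truth.planted_positions),
            "panel_divergent_positions": list(panel_truth.divergent_positions),
            "scene_percent_luminance_change": scene_truth.percent_luminance_change,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
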