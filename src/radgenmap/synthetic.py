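"""Synthetic radiogenomic study cohort with known ground truth.

The generator emulates the structure of a three-grade-group prostate-cancer
cohort: per patient one T2WI and one ADC region of interest, a table of
copy-number segments for a nine-gene panel, an array QC call score, and the
Gleason grade group (1/2/3).  Every latent quantity used during generation is
retained in a per-patient ``truth`` record so each downstream stage has a
recoverable target.

Image model
-----------
An ROI is a stationary Gaussian random field: white noise smoothed with a
Gaussian kernel (standard deviation = ``correlation_length`` pixels),
standardised, mixed with white measurement noise of standard deviation
``noise_sd``, and passed through ``tanh(contrast_scale * z)``.  The tanh gain
is the texture knob: a larger ``contrast_scale`` spreads the intensity
histogram toward the tails, which monotonically raises the co-occurrence
Contrast and the Sum-of-Squares Variance of the quantised ROI.  Pixel values
are finally discretised to the 16-bit integer grid so raster fixtures
round-trip losslessly.  The mask is a centred disc covering ~64% of pixels.

Planted radiogenomic links
--------------------------
A planted link (gene, feature, target_r) ties a patient-level latent driver
``t ~ N(0,1)`` to both sides of the map.  On the imaging side the driver
scales the tanh gain of the named feature's modality by ``exp(b * t)``.  On
the genomic side the gene's gain/loss state is a noisy trichotomised copy of
the driver: ``u = rho * t + sqrt(1 - rho^2) * e`` with state +1 / 0 / -1 for
``u`` above / between / below the symmetric equal-thirds cutpoints.  For that
scheme ``corr(state, t) = 2 * phi(c) / sqrt(2 * Phi(-c)) * rho ~= 0.89 rho``,
so ``rho`` is set in closed form to make the population driver-state
correlation exactly ``target_r`` (attainable for |target_r| <= ~0.89).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage, stats

from ._util import sha256_file
from .genomics import CnvSegment, GenePanel, default_panel, write_panel, write_segments
from .texture import MODALITIES, RoiImage

__all__ = [
    "ConfigurationError",
    "TextureParams",
    "PlantedLink",
    "CohortConfig",
    "SyntheticPatient",
    "generate_roi_image",
    "generate_cnv_segments",
    "generate_cohort",
    "write_fixtures",
    "read_fixtures",
    "MAX_PLANTED_R",
]

# equal-thirds cutpoint for the trichotomised gene state and the resulting
# driver-state correlation per unit latent correlation
_CUT = float(stats.norm.ppf(2.0 / 3.0))
_TRICHOTOMY_FACTOR = float(2.0 * stats.norm.pdf(_CUT) / np.sqrt(2.0 * stats.norm.cdf(-_CUT)))
MAX_PLANTED_R = _TRICHOTOMY_FACTOR  # ~0.890


class ConfigurationError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class TextureParams:
    """Per-group random-field parameters.

    correlation_length : Gaussian smoothing kernel sd, in pixels.
    contrast_scale     : tanh gain; larger means coarser, higher-contrast
                         texture (dimensionless, > 0).
    noise_sd           : white measurement-noise sd relative to the unit-
                         variance smooth field.
    """

    correlation_length: float = 4.0
    contrast_scale: float = 1.0
    noise_sd: float = 0.3


@dataclass(frozen=True)
class PlantedLink:
    """Ground-truth association between a gene and a texture feature."""

    gene: str
    feature: str  # modality-suffixed, e.g. "SumSquaresVariance_T2WI"
    target_r: float

    @property
    def modality(self) -> str:
        suffix = self.feature.rsplit("_", 1)[-1]
        if suffix not in MODALITIES:
            raise ConfigurationError(
                f"planted_links: feature {self.feature!r} lacks a modality suffix"
            )
        return suffix


DEFAULT_TEXTURE_PARAMS: dict[int, TextureParams] = {
    1: TextureParams(4.0, 0.7, 0.3),
    2: TextureParams(4.0, 1.1, 0.3),
    3: TextureParams(4.0, 1.6, 0.3),
}

DEFAULT_PLANTED_LINKS: tuple[PlantedLink, ...] = (
    PlantedLink("P4HA1", "SumSquaresVariance_T2WI", 0.7),
)

#: Loss of the NKX3-1 locus is enriched in higher-grade disease, so the
#: genomic block carries grade signal independent of the imaging block.
DEFAULT_GRADE_GENE_EFFECTS: dict[str, dict[int, tuple[float, float]]] = {
    "NKX3-1": {1: (0.10, 0.10), 2: (0.45, 0.05), 3: (0.65, 0.05)},
}


@dataclass
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults emulate a small grade-stratified radiogenomics study design
    (3 balanced grade groups, two modalities per patient, a >=80% QC filter
    that occasionally fires) with group texture contrasts strong enough that
    feature screening has real signal at moderate n.
    """

    n_per_group: int = 30
    image_size: int = 64
    texture_params: Mapping[int, TextureParams] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURE_PARAMS)
    )
    planted_links: Sequence[PlantedLink] = DEFAULT_PLANTED_LINKS
    qc_mean: float = 92.0
    qc_sd: float = 8.0
    seed: int = 0
    # probability of a background (non-planted) loss and gain per gene
    background_alteration_prob: float = 0.15
    # gene -> {group: (p_loss, p_gain)} grade-dependent alteration probabilities
    grade_gene_effects: Mapping[str, Mapping[int, tuple[float, float]]] | None = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRADE_GENE_EFFECTS.items()}
    )
    # log-scale gain of the latent driver on the modulated contrast_scale
    driver_log_gain: float = 0.55
    decoys_per_sample: int = 3

    def __post_init__(self) -> None:
        links = []
        for link in self.planted_links:
            if isinstance(link, PlantedLink):
                links.append(link)
            else:
                links.append(PlantedLink(*link))
        self.planted_links = tuple(links)

    def validate(self, panel: GenePanel) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError(f"n_per_group: must be >= 2, got {self.n_per_group}")
        if self.image_size < 16:
            raise ConfigurationError(f"image_size: must be >= 16, got {self.image_size}")
        if set(self.texture_params) != {1, 2, 3}:
            raise ConfigurationError("texture_params: must map grade groups 1, 2, 3")
        for grp, par in self.texture_params.items():
            if par.correlation_length >= self.image_size:
                raise ConfigurationError(
                    f"texture_params[{grp}].correlation_length: must be < image_size"
                )
            if par.contrast_scale <= 0:
                raise ConfigurationError(
                    f"texture_params[{grp}].contrast_scale: must be > 0"
                )
            if par.noise_sd < 0:
                raise ConfigurationError(f"texture_params[{grp}].noise_sd: must be >= 0")
        for link in self.planted_links:
            if abs(link.target_r) > 1:
                raise ConfigurationError(
                    f"planted_links: |target_r| must be <= 1, got {link.target_r}"
                )
            if abs(link.target_r) > MAX_PLANTED_R:
                raise ConfigurationError(
                    f"planted_links: |target_r| <= {MAX_PLANTED_R:.3f} is attainable "
                    f"with a trichotomous gene state, got {link.target_r}"
                )
            if link.gene not in panel.entries:
                raise ConfigurationError(f"planted_links: unknown gene {link.gene!r}")
            link.modality  # raises on a malformed feature name
        if not 0 <= self.background_alteration_prob <= 0.5:
            raise ConfigurationError(
                "background_alteration_prob: must be in [0, 0.5]"
            )
        if self.qc_sd <= 0:
            raise ConfigurationError("qc_sd: must be > 0")


@dataclass
class SyntheticPatient:
    patient_id: str
    grade_group: int
    images: dict[str, RoiImage]
    segments: list[CnvSegment]
    qc_score: float
    truth: dict


def _disc_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= (0.45 * size) ** 2


def generate_roi_image(
    texture_param: TextureParams,
    image_size: int,
    rng: np.random.Generator,
    modality: str = "T2WI",
    patient_id: str = "",
) -> RoiImage:
    """One stationary random-field ROI on the 16-bit integer grid."""
    if texture_param.correlation_length >= image_size:
        raise ValueError("correlation_length must be < image_size")
    white = rng.standard_normal((image_size, image_size))
    smooth = ndimage.gaussian_filter(white, sigma=texture_param.correlation_length, mode="reflect")
    sd = smooth.std()
    if sd < 1e-12 or texture_param.contrast_scale <= 0:
        raise ValueError("degenerate texture parameters: zero-variance field")
    z = (smooth - smooth.mean()) / sd
    if texture_param.noise_sd > 0:
        z = z + texture_param.noise_sd * rng.standard_normal((image_size, image_size))
        z = z / np.sqrt(1.0 + texture_param.noise_sd**2)
    x = np.tanh(texture_param.contrast_scale * z)
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        raise ValueError("degenerate texture parameters: zero-variance field")
    pixels = np.round((x - lo) / (hi - lo) * 65535.0)
    return RoiImage(pixels=pixels, mask=_disc_mask(image_size), modality=modality, patient_id=patient_id)


def generate_cnv_segments(
    gene_states: Mapping[str, int],
    panel: GenePanel,
    rng: np.random.Generator,
    sample_id: str = "S1",
    n_decoys: int = 3,
) -> list[CnvSegment]:
    """Segments realising the requested per-gene gain/loss states.

    Each gene with state +1 (-1) is covered by one copy-number 3 (1) segment
    with random flank jitter; state-0 genes are overlapped by nothing.  Decoy
    segments with random states are placed far downstream of any panel locus
    so gene scoring is unaffected.
    """
    unknown = sorted(set(gene_states) - set(panel.entries))
    if unknown:
        raise ValueError(f"unknown genes in state map: {unknown}")
    segments: list[CnvSegment] = []
    for gene in panel.genes:
        state = int(gene_states.get(gene, 0))
        if state == 0:
            continue
        if state not in (-1, 1):
            raise ValueError(f"gene state must be in {{-1, 0, +1}}, got {state} for {gene}")
        entry = panel.entries[gene]
        left = int(rng.integers(0, 20_000))
        right = int(rng.integers(0, 20_000))
        segments.append(
            CnvSegment(
                sample_id=sample_id,
                chrom=entry.chrom,
                start=max(1, entry.start - left),
                end=entry.end + right,
                copy_number=2 + state,
            )
        )
    chroms = sorted({e.chrom for e in panel.entries.values()})
    far = max(e.end for e in panel.entries.values()) + 10_000_000
    for _ in range(n_decoys):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = far + int(rng.integers(0, 5_000_000))
        length = int(rng.integers(10_000, 100_000))
        cn = int(rng.choice([1, 2, 3]))
        segments.append(
            CnvSegment(sample_id=sample_id, chrom=chrom, start=start, end=start + length, copy_number=cn)
        )
    return segments


def _planted_rho(target_r: float) -> float:
    return float(target_r / _TRICHOTOMY_FACTOR)


def _trichotomise(u: float) -> int:
    if u > _CUT:
        return 1
    if u < -_CUT:
        return -1
    return 0


def generate_cohort(
    config: CohortConfig, panel: GenePanel | None = None
) -> list[SyntheticPatient]:
    """Generate the full synthetic cohort (3 x n_per_group patients).

    Deterministic: a fixed config (including seed) yields a bit-identical
    cohort.  Per-patient randomness is drawn from spawned child streams so
    the cohort is stable under changes elsewhere in the pipeline.
    """
    panel = panel or default_panel()
    config.validate(panel)
    root = np.random.SeedSequence(config.seed)
    patients: list[SyntheticPatient] = []
    n_patients = 3 * config.n_per_group
    children = root.spawn(n_patients)
    idx = 0
    for group in (1, 2, 3):
        params = config.texture_params[group]
        for k in range(config.n_per_group):
            rng = np.random.default_rng(children[idx])
            pid = f"P{idx + 1:04d}"
            idx += 1

            # latent drivers and planted gene states
            drivers: dict[str, float] = {}
            gene_states: dict[str, int] = {}
            log_mod = {m: 0.0 for m in MODALITIES}
            for link in config.planted_links:
                t = float(rng.standard_normal())
                drivers[link.gene] = t
                rho = _planted_rho(link.target_r)
                u = rho * t + np.sqrt(1.0 - rho**2) * float(rng.standard_normal())
                gene_states[link.gene] = _trichotomise(u)
                log_mod[link.modality] += config.driver_log_gain * t

            # background / grade-driven states for the remaining genes
            for gene in panel.genes:
                if gene in gene_states:
                    continue
                if config.grade_gene_effects and gene in config.grade_gene_effects:
                    p_loss, p_gain = config.grade_gene_effects[gene][group]
                else:
                    p_loss = p_gain = config.background_alteration_prob
                u = float(rng.uniform())
                gene_states[gene] = -1 if u < p_loss else (1 if u > 1.0 - p_gain else 0)

            contrast = {
                m: params.contrast_scale * float(np.exp(log_mod[m])) for m in MODALITIES
            }
            images = {}
            for m in MODALITIES:
                par = TextureParams(params.correlation_length, contrast[m], params.noise_sd)
                images[m] = generate_roi_image(
                    par, config.image_size, rng, modality=m, patient_id=pid
                )

            segments = generate_cnv_segments(
                gene_states, panel, rng, sample_id=pid, n_decoys=config.decoys_per_sample
            )
            a = (0.0 - config.qc_mean) / config.qc_sd
            b = (100.0 - config.qc_mean) / config.qc_sd
            qc = float(
                stats.truncnorm.rvs(
                    a, b, loc=config.qc_mean, scale=config.qc_sd, random_state=rng
                )
            )
            truth = {
                "grade_group": group,
                "drivers": drivers,
                "gene_states": gene_states,
                "contrast_scale": contrast,
                "texture_params": asdict(params),
            }
            patients.append(
                SyntheticPatient(
                    patient_id=pid,
                    grade_group=group,
                    images=images,
                    segments=segments,
                    qc_score=round(qc, 2),
                    truth=truth,
                )
            )
    return patients


# ---------------------------------------------------------------------------
# fixture I/O


def _write_image(img: RoiImage, stem: Path, image_format: str) -> list[Path]:
    if image_format == "png":
        px = Image.fromarray(img.pixels.astype(np.uint16))
        mk = Image.fromarray((img.mask.astype(np.uint8)) * 255)
        p1, p2 = stem.with_suffix(".png"), Path(f"{stem}_mask.png")
        px.save(p1)
        mk.save(p2)
    elif image_format == "txt":
        p1, p2 = stem.with_suffix(".txt"), Path(f"{stem}_mask.txt")
        np.savetxt(p1, img.pixels, fmt="%d")
        np.savetxt(p2, img.mask.astype(int), fmt="%d")
    else:
        raise ValueError(f"unknown image format {image_format!r}")
    return [p1, p2]


def _read_image(stem: Path, modality: str, patient_id: str) -> RoiImage:
    if stem.with_suffix(".png").exists():
        pixels = np.asarray(Image.open(stem.with_suffix(".png")), dtype=float)
        mask = np.asarray(Image.open(Path(f"{stem}_mask.png"))) > 0
    else:
        pixels = np.loadtxt(stem.with_suffix(".txt"))
        mask = np.loadtxt(Path(f"{stem}_mask.txt")).astype(bool)
    return RoiImage(pixels=pixels, mask=mask, modality=modality, patient_id=patient_id)


def write_fixtures(
    cohort: Sequence[SyntheticPatient],
    out_dir: Path | str,
    panel: GenePanel | None = None,
    image_format: str = "png",
) -> dict:
    """Write the cohort to disk and return a checksum manifest.

    Layout: ``images/<pid>_<modality>.(png|txt)`` (+ ``_mask``),
    ``segments.tsv``, ``panel.tsv``, ``metadata.tsv``, ``truth.json`` and
    ``manifest.json``.  Both raster and plain-text image formats round-trip
    the 16-bit pixel grid losslessly.
    """
    panel = panel or default_panel()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for pat in cohort:
        for m in MODALITIES:
            stem = out / "images" / f"{pat.patient_id}_{m}"
            written.extend(_write_image(pat.images[m], stem, image_format))
    seg_path = out / "segments.tsv"
    write_segments([s for p in cohort for s in p.segments], seg_path)
    written.append(seg_path)
    panel_path = out / "panel.tsv"
    write_panel(panel, panel_path)
    written.append(panel_path)
    meta_path = out / "metadata.tsv"
    pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "grade_group": [p.grade_group for p in cohort],
            "qc_score": [p.qc_score for p in cohort],
        }
    ).to_csv(meta_path, sep="\t", index=False)
    written.append(meta_path)
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump({p.patient_id: p.truth for p in cohort}, fh, indent=1, sort_keys=True)
    written.append(truth_path)

    manifest = {
        "n_patients": len(cohort),
        "image_format": image_format,
        "files": {str(p.relative_to(out)): sha256_file(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_fixtures(fixture_dir: Path | str) -> list[SyntheticPatient]:
    """Reload a fixture directory written by :func:`write_fixtures`."""
    from .genomics import read_metadata, read_segments

    root = Path(fixture_dir)
    meta = read_metadata(root / "metadata.tsv")
    segments = read_segments(root / "segments.tsv")
    by_sample: dict[str, list[CnvSegment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    truth = {}
    if (root / "truth.json").exists():
        with open(root / "truth.json") as fh:
            truth = json.load(fh)
    cohort = []
    for _, row in meta.iterrows():
        pid = str(row["patient_id"])
        images = {
            m: _read_image(root / "images" / f"{pid}_{m}", m, pid) for m in MODALITIES
        }
        cohort.append(
            SyntheticPatient(
                patient_id=pid,
                grade_group=int(row["grade_group"]),
                images=images,
                segments=by_sample.get(pid, []),
                qc_score=float(row["qc_score"]),
                truth=truth.get(pid, {}),
            )
        )
    return cohort
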