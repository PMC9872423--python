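"""Synthetic paired imaging / expression / clinical cohort with planted structure.

The generator emulates the data layout of a breast-MRI radiogenomic study:
each patient contributes several grayscale slices of a breast-like scene
containing a bright elliptical "tumor", an mRNA expression profile in which
a subset of "risk genes" is partially driven by the same latent patient
factors that shape the tumor, pathway gene sets that do or do not contain
the planted genes, and noisy binary clinical labels derived from the
latents.  Because the planted radiogenomic links are recorded exactly, every
downstream stage (feature extraction, association scan, classification) can
be tested against a known ground truth without any external download.

Latent model: each patient carries ``n_latent`` independent standard-normal
factors.  Factor 0 drives tumor radius, factor 1 drives tumor peak
intensity, factor 2 drives background texture amplitude; further factors
(if configured) are imaging-silent but may still drive genes and labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import ImageRecord

__all__ = [
    "SimConfig",
    "LatentPatient",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "render_slice",
    "tumor_radius",
    "simulate_drf_matrix",
    "write_cohort",
]

#: relative baseline tumor radius, as a fraction of the image half-width
BASELINE_RADIUS_FRAC = 0.18

_DEFAULT_LABELS = ("T", "N", "ER", "PR", "HER2")


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"SimConfig.{fieldname}: {msg}")


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Defaults mirror the study conditions: 2–8 images per patient, 64x64
    slices, 288 risk genes, five binary clinical labels (T, N, ER, PR,
    HER2) with optional HER2 missingness.
    """

    n_patients: int = 110
    images_per_patient_range: tuple[int, int] = (2, 8)
    image_size: int = 64
    n_latent: int = 3
    n_risk_genes: int = 288
    n_planted_genes: int = 30
    effect_size: float = 1.0
    gene_noise_sd: float = 1.0
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (5, 30)
    clinical_label_names: tuple[str, ...] = _DEFAULT_LABELS
    her2_missing_n: int = 0
    image_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_patients >= 1, "n_patients", "must be >= 1")
        lo, hi = self.images_per_patient_range
        _check(1 <= lo <= hi, "images_per_patient_range",
               "must be an interval of positive integers")
        _check(self.image_size >= 16, "image_size", "must be >= 16")
        _check(self.image_size % 4 == 0, "image_size",
               "must be divisible by 4 (two 2x2 poolings)")
        _check(self.n_latent >= 1, "n_latent", "must be >= 1")
        _check(self.n_risk_genes >= 1, "n_risk_genes", "must be >= 1")
        _check(0 <= self.n_planted_genes <= self.n_risk_genes,
               "n_planted_genes", "must be in [0, n_risk_genes]")
        _check(np.isfinite(self.effect_size) and self.effect_size >= 0,
               "effect_size", "must be a finite real >= 0")
        _check(self.gene_noise_sd > 0, "gene_noise_sd", "must be > 0")
        _check(self.n_pathways >= 1, "n_pathways", "must be >= 1")
        plo, phi = self.pathway_size_range
        _check(1 <= plo <= phi, "pathway_size_range",
               "must be an interval of positive integers")
        _check(phi <= self.n_risk_genes, "pathway_size_range",
               "upper bound cannot exceed n_risk_genes")
        _check(len(self.clinical_label_names) >= 1, "clinical_label_names",
               "must be non-empty")
        _check(0 <= self.her2_missing_n <= self.n_patients, "her2_missing_n",
               "must be in [0, n_patients]")
        _check(self.image_jitter_sd >= 0, "image_jitter_sd", "must be >= 0")


@dataclass
class LatentPatient:
    patient_id: str
    z: np.ndarray  # shape (n_latent,)


@dataclass
class GroundTruth:
    """Planted structure: which genes/pathways/labels are driven by which latent."""

    planted_links: set[tuple[str, int, float]] = field(default_factory=set)
    planted_pathways: set[str] = field(default_factory=set)
    label_models: dict[str, tuple[np.ndarray, float]] = field(default_factory=dict)


@dataclass
class Cohort:
    images: list[ImageRecord]
    expression: pd.DataFrame  # genes x patients
    clinical: pd.DataFrame    # patients x labels, NaN where missing
    truth: GroundTruth
    latents: list[LatentPatient]
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.expression.columns)


def tumor_radius(z_radius: float, image_size: int) -> float:
    """Tumor radius in pixels as a monotone function of the radius latent.

    At ``z_radius = 0`` this equals the configured baseline radius
    ``BASELINE_RADIUS_FRAC * image_size / 2``.
    """
    base = BASELINE_RADIUS_FRAC * image_size / 2.0
    return base * float(np.exp(0.35 * np.tanh(z_radius / 1.5)))


def _tumor_peak(z_intensity: float) -> float:
    # monotone in the intensity latent, bounded away from the background level
    return 0.9 + 0.4 * float(np.tanh(z_intensity / 2.0))


def render_slice(z: Sequence[float], image_size: int,
                 rng: np.random.Generator,
                 jitter_sd: float = 0.02) -> np.ndarray:
    """Render one synthetic sagittal-like slice from a patient latent vector.

    The scene is a smooth breast-like background, a correlated texture field
    whose amplitude tracks the texture latent, and a bright Gaussian-profile
    elliptical tumor whose radius and peak intensity are monotone in the
    designated latent components.  Per-image jitter (a Gaussian field plus a
    sub-pixel tumor-center shift) makes repeated slices of one patient
    strongly correlated but not identical.  Values are finite and
    non-negative; the caller is expected to min–max scale them.
    """
    if image_size < 16:
        raise ValueError("image_size too small to place the tumor (need >= 16)")
    z = np.asarray(z, dtype=float)
    s = image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    cy, cx = (s - 1) / 2.0, (s - 1) / 2.0

    # breast-like background: a broad half-ellipse of moderate intensity
    breast = 0.12 / (1.0 + np.exp(((xx - cx) ** 2 / (0.55 * s) ** 2
                                   + (yy - cy) ** 2 / (0.75 * s) ** 2 - 1.0) * 8.0))

    # smooth texture field, amplitude driven by the texture latent (if present)
    z_tex = z[2] if z.size > 2 else 0.0
    amp = 0.02 * (1.0 + 0.5 * np.tanh(z_tex / 2.0))
    texture = ndimage.gaussian_filter(rng.normal(size=(s, s)), sigma=2.0)
    texture *= amp / max(texture.std(), 1e-12)

    # tumor: Gaussian-profile ellipse, slight per-image center jitter
    r = tumor_radius(z[0], s)
    peak = _tumor_peak(z[1] if z.size > 1 else 0.0)
    jit_y, jit_x = rng.normal(scale=0.5, size=2)
    ty, tx = cy + 0.12 * s + jit_y, cx - 0.10 * s + jit_x
    d2 = ((yy - ty) ** 2 + (xx - tx) ** 2) / max(r, 1e-9) ** 2
    tumor = peak * np.exp(-d2)

    img = breast + texture + tumor
    if jitter_sd > 0:
        img = img + rng.normal(scale=jitter_sd, size=(s, s))
    return np.clip(img, 0.0, None)


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the full paired cohort; deterministic given ``config.seed``.

    Planted gene ``g`` assigned to latent ``k`` has expression
    ``effect_size * z[k] + Normal(0, gene_noise_sd)`` per patient; null genes
    are pure noise.  Each clinical label is Bernoulli(logistic(w.z + b))
    with (w, b) recorded in the ground truth.  Pathway gene sets are sampled
    without replacement from the risk genes; pathways containing at least
    one planted gene are flagged.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    pad = max(4, len(str(cfg.n_patients)))
    patients = [f"P{str(i + 1).zfill(pad)}" for i in range(cfg.n_patients)]
    latents = [LatentPatient(pid, rng.normal(size=cfg.n_latent))
               for pid in patients]

    # --- images -----------------------------------------------------------
    lo, hi = cfg.images_per_patient_range
    images: list[ImageRecord] = []
    for lat in latents:
        n_img = int(rng.integers(lo, hi + 1))
        for j in range(n_img):
            pix = render_slice(lat.z, cfg.image_size, rng,
                               jitter_sd=cfg.image_jitter_sd)
            images.append(ImageRecord(patient_id=lat.patient_id,
                                      image_id=f"{lat.patient_id}_img{j + 1:02d}",
                                      pixels=pix))

    # --- expression -------------------------------------------------------
    gpad = max(4, len(str(cfg.n_risk_genes)))
    genes = [f"gene_{str(i + 1).zfill(gpad)}" for i in range(cfg.n_risk_genes)]
    Z = np.stack([lat.z for lat in latents])  # patients x latent
    expr = rng.normal(scale=cfg.gene_noise_sd,
                      size=(cfg.n_risk_genes, cfg.n_patients))
    truth = GroundTruth()
    if cfg.effect_size > 0:
        for j in range(cfg.n_planted_genes):
            k = j % cfg.n_latent
            expr[j] += cfg.effect_size * Z[:, k]
            truth.planted_links.add((genes[j], k, cfg.effect_size))
    expression = pd.DataFrame(expr, index=genes, columns=patients)

    # --- pathways ---------------------------------------------------------
    planted_names = {g for g, _, _ in truth.planted_links}
    gene_sets: dict[str, list[str]] = {}
    plo, phi = cfg.pathway_size_range
    for p in range(cfg.n_pathways):
        size = int(rng.integers(plo, phi + 1))
        members = [genes[i] for i in
                   rng.choice(cfg.n_risk_genes, size=size, replace=False)]
        name = f"pathway_{p + 1:03d}"
        gene_sets[name] = members
        if planted_names.intersection(members):
            truth.planted_pathways.add(name)

    # --- clinical labels --------------------------------------------------
    clin = {}
    for li, label in enumerate(cfg.clinical_label_names):
        w = np.full(cfg.n_latent, 0.3)
        w[li % cfg.n_latent] = 2.0
        b = 0.0
        p = 1.0 / (1.0 + np.exp(-(Z @ w + b)))
        y = (rng.random(cfg.n_patients) < p).astype(float)
        truth.label_models[label] = (w, b)
        clin[label] = y
    clinical = pd.DataFrame(clin, index=patients)
    if cfg.her2_missing_n > 0 and "HER2" in clinical.columns:
        clinical.loc[patients[:cfg.her2_missing_n], "HER2"] = np.nan

    return Cohort(images=images, expression=expression, clinical=clinical,
                  truth=truth, latents=latents, gene_sets=gene_sets)


def simulate_drf_matrix(latents: Sequence[LatentPatient],
                        n_drfs: int,
                        images_per_patient_range: tuple[int, int] = (2, 8),
                        n_informative: int = 0,
                        latent_loading: float = 1.0,
                        patient_sd: float = 0.3,
                        image_sd: float = 0.3,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate an image-level feature matrix with patient random effects.

    Used to calibrate the association scan at an arbitrary feature count,
    independent of the autoencoder's bottleneck width.  Each feature f for
    image j of patient i is::

        a_f * z_i[k(f)] + u_{i,f} + e_{ij,f}

    with ``a_f = latent_loading`` for the first ``n_informative`` features
    (cycling over latent components) and 0 otherwise; ``u ~ N(0, patient_sd)``
    is a per-patient intercept shared by the patient's images and
    ``e ~ N(0, image_sd)`` is per-image noise.  Returns a DataFrame indexed
    by image_id with a ``patient_id`` column and ``fea_*`` feature columns.
    """
    rng = np.random.default_rng(seed)
    lo, hi = images_per_patient_range
    rows = []
    index = []
    pids = []
    n_latent = len(latents[0].z)
    loadings = np.zeros(n_drfs)
    loadings[:n_informative] = latent_loading
    latent_of = np.arange(n_drfs) % n_latent
    for lat in latents:
        n_img = int(rng.integers(lo, hi + 1))
        u = rng.normal(scale=patient_sd, size=n_drfs)
        base = loadings * lat.z[latent_of] + u
        for j in range(n_img):
            e = rng.normal(scale=image_sd, size=n_drfs)
            rows.append(base + e)
            index.append(f"{lat.patient_id}_img{j + 1:02d}")
            pids.append(lat.patient_id)
    df = pd.DataFrame(np.asarray(rows), index=pd.Index(index, name="image_id"),
                      columns=[f"fea_{i + 1}" for i in range(n_drfs)])
    df.insert(0, "patient_id", pids)
    return df


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort to disk: 16-bit PNG slices, TSV tables, GMT gene sets."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    img_dir = outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.images:
        pix = rec.pixels
        rng_span = pix.max() - pix.min()
        scaled = (pix - pix.min()) / rng_span if rng_span > 0 else np.zeros_like(pix)
        iio.imwrite(img_dir / f"{rec.image_id}.png",
                    (scaled * 65535).astype(np.uint16))

    paths = {"images": img_dir}
    paths["expression"] = outdir / "expression.tsv"
    cohort.expression.to_csv(paths["expression"], sep="\t")
    paths["clinical"] = outdir / "clinical.tsv"
    cohort.clinical.to_csv(paths["clinical"], sep="\t")

    paths["gene_sets"] = outdir / "pathways.gmt"
    with open(paths["gene_sets"], "w") as fh:
        for name, members in cohort.gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + members) + "\n")

    paths["truth"] = outdir / "ground_truth.tsv"
    links = pd.DataFrame(sorted(cohort.truth.planted_links),
                         columns=["gene_id", "latent_index", "effect_size"])
    links.to_csv(paths["truth"], sep="\t", index=False)
    return paths
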