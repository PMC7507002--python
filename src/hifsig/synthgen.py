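"""Synthetic data with known ground truth for the signature pipeline and qIHC.

The omics generator uses a single-latent-factor model: each sample carries a
latent transactivity h_i ~ N(0, 1); every regulon gene g measures it through
a linear loading, x_gi = lambda_g * h_i + eps (eps ~ N(0, noise_sd)), while
background genes are independent N(0, 1). Survival follows an exponential
hazard baseline_hazard * exp(survival_beta * h_i) with uniform censoring, and
the binary clinical covariate is Bernoulli(logistic(slope * h_i)). This is
the minimal structure under which correlation-based expansion, Cox signature
compaction and median-split validation all have a well-defined ground truth.

The histology generator renders non-overlapping circular nodules on a pale
background and fills each with spatially clustered blobs of a DAB-like brown
until a requested positive-pixel fraction is met exactly, so that area,
equivalent diameter and positive fraction are all known per nodule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, SurvivalTable
from .exceptions import ConfigError

#: Canonical seed HIF targets used throughout as synthetic regulon anchors.
DEFAULT_SEEDS = ("BNIP3", "DDIT4", "P4HA1", "P4HA2", "PLAUR")


def default_regulon(n_targets: int = 40) -> list[str]:
    """Seed symbols plus ``n_targets`` synthetic non-seed HIF-target symbols."""
    return list(DEFAULT_SEEDS) + [f"HIFT{i:03d}" for i in range(n_targets)]


@dataclass
class SynthOmicsConfig:
    """Parameters of the latent-factor expression/survival/clinical generator.

    Defaults emulate a bulk tumour cohort in which the HIF regulon is ~2% of
    the transcriptome: 45 regulon genes (5 canonical seeds + 40 targets) in a
    2,045-gene matrix, loadings drawn from U(0.6, 0.9) over unit-variance
    latent activity, residual noise SD 0.5. Survival uses a log-hazard of 0.8
    per latent-activity unit on an exponential baseline of 0.05 events per
    time unit, censored uniformly on (0, 30) time units.
    """

    n_samples: int = 300
    n_background_genes: int = 2000
    regulon_genes: list[str] = field(default_factory=default_regulon)
    loading_range: tuple[float, float] = (0.6, 0.9)
    noise_sd: float = 0.5
    survival_beta: float = 0.8
    baseline_hazard: float = 0.05
    censor_horizon: float = 30.0
    covariate_logit_slope: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ConfigError(f"n_samples must be >= 4, got {self.n_samples}")
        if self.n_background_genes < 0:
            raise ConfigError("n_background_genes must be >= 0")
        if len(set(self.regulon_genes)) != len(self.regulon_genes):
            raise ConfigError("regulon_genes contains duplicates")
        if not self.regulon_genes:
            raise ConfigError("regulon_genes must be non-empty")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError(
                f"loading_range must satisfy 0 < lo <= hi <= 1, got {self.loading_range}"
            )
        if not self.noise_sd > 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not self.baseline_hazard > 0:
            raise ConfigError(f"baseline_hazard must be > 0, got {self.baseline_hazard}")
        if not self.censor_horizon > 0:
            raise ConfigError(f"censor_horizon must be > 0, got {self.censor_horizon}")

    @property
    def background_genes(self) -> list[str]:
        return [f"BG{i:05d}" for i in range(self.n_background_genes)]


@dataclass
class SynthTruth:
    """Ground truth of one generated cohort."""

    sample_ids: list[str]
    latent_activity: np.ndarray
    regulon_members: list[str]
    loadings: np.ndarray
    true_beta: float

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": self.sample_ids, "latent_activity": self.latent_activity}
        ).to_csv(path, sep="\t", index=False)


def gen_expression(cfg: SynthOmicsConfig) -> tuple[ExpressionMatrix, SynthTruth]:
    """Draw an expression matrix from the latent-factor model.

    Returns the matrix (regulon rows first, then background rows) together
    with the :class:`SynthTruth` record. Deterministic given ``cfg.rng_seed``.
    """
    background = cfg.background_genes
    overlap = set(cfg.regulon_genes) & set(background)
    if overlap:
        raise ConfigError(f"regulon_genes collide with background symbols: {overlap}")
    rng = np.random.default_rng(cfg.rng_seed)
    n, g_reg = cfg.n_samples, len(cfg.regulon_genes)
    h = rng.standard_normal(n)
    lo, hi = cfg.loading_range
    loadings = rng.uniform(lo, hi, size=g_reg)
    reg = loadings[:, None] * h[None, :] + rng.normal(
        0.0, cfg.noise_sd, size=(g_reg, n)
    )
    bg = rng.standard_normal((cfg.n_background_genes, n))
    samples = [f"S{i:04d}" for i in range(n)]
    data = pd.DataFrame(
        np.vstack([reg, bg]) if cfg.n_background_genes else reg,
        index=list(cfg.regulon_genes) + background,
        columns=samples,
    )
    truth = SynthTruth(
        sample_ids=samples,
        latent_activity=h,
        regulon_members=list(cfg.regulon_genes),
        loadings=loadings,
        true_beta=cfg.survival_beta,
    )
    return ExpressionMatrix(data), truth


def gen_survival(truth: SynthTruth, cfg: SynthOmicsConfig) -> SurvivalTable:
    """Exponential event times with rate h0*exp(beta*h_i), uniform censoring.

    The censoring draw uses an RNG stream offset from ``cfg.rng_seed`` so
    survival is reproducible without replaying expression generation.
    """
    rng = np.random.default_rng((cfg.rng_seed, 1))
    h = np.asarray(truth.latent_activity, dtype=float)
    rate = cfg.baseline_hazard * np.exp(cfg.survival_beta * h)
    t_event = rng.exponential(1.0 / rate)
    c = rng.uniform(0.0, cfg.censor_horizon, size=h.shape)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    # guard against a zero from floating underflow; times must be positive
    time = np.maximum(time, np.finfo(float).tiny)
    return SurvivalTable.from_arrays(truth.sample_ids, time, event)


def gen_clinical(truth: SynthTruth, cfg: SynthOmicsConfig) -> ClinicalTable:
    """Binary covariate ~ Bernoulli(logistic(slope * h_i)); one row per sample."""
    rng = np.random.default_rng((cfg.rng_seed, 2))
    h = np.asarray(truth.latent_activity, dtype=float)
    p = 1.0 / (1.0 + np.exp(-cfg.covariate_logit_slope * h))
    cov = (rng.uniform(size=h.shape) < p).astype(int)
    return ClinicalTable(pd.DataFrame({"sample": truth.sample_ids, "covariate": cov}))


# ---------------------------------------------------------------------------
# Synthetic stained-tissue images
# ---------------------------------------------------------------------------

#: DAB-like brown used for stain-positive pixels (strong DAB optical density
#: under color deconvolution) and a pale hematoxylin-like background.
DAB_BROWN = (101, 67, 33)
PALE_BACKGROUND = (230, 225, 235)


@dataclass
class SynthImageConfig:
    """Layout of one synthetic brightfield slide.

    ``nodules`` is a list of ``(center_rc, radius_px, target_positive_fraction)``
    with centers in (row, col) pixel coordinates.
    """

    canvas_px: tuple[int, int] = (512, 512)  # (rows, cols)
    um_per_px: float = 1.0
    nodules: list[tuple[tuple[int, int], int, float]] = field(default_factory=list)
    stain_positive_color: tuple[int, int, int] = DAB_BROWN
    background_color: tuple[int, int, int] = PALE_BACKGROUND
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.canvas_px
        if h <= 0 or w <= 0:
            raise ConfigError(f"canvas_px must be positive, got {self.canvas_px}")
        if not self.um_per_px > 0:
            raise ConfigError(f"um_per_px must be > 0, got {self.um_per_px}")
        for (r, c), rad, frac in self.nodules:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"target fraction {frac} outside [0, 1]")
            if rad <= 0:
                raise ConfigError(f"nodule radius must be > 0, got {rad}")
            if not (rad <= r < h - rad and rad <= c < w - rad):
                raise ConfigError(
                    f"nodule at {(r, c)} radius {rad} not fully inside canvas"
                )
        centers = [np.array(ctr, dtype=float) for ctr, _, _ in self.nodules]
        radii = [rad for _, rad, _ in self.nodules]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) <= radii[i] + radii[j]:
                    raise ConfigError(
                        f"nodules {i} and {j} overlap; per-nodule truth would be ambiguous"
                    )


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def gen_histology(cfg: SynthImageConfig):
    """Render a synthetic stained slide with exact per-nodule ground truth.

    Positive pixels are laid down as random small disks clipped to the nodule
    (spatial clustering, emulating stained cell clusters) and then topped up
    or trimmed pixel-wise so the realized positive count equals
    ``round(target_fraction * nodule_area)`` exactly.

    Returns
    -------
    image : uint8 RGB array
    label_mask : int array, 0 = background, nodule i labelled i + 1
    records : list of dict with keys ``nodule_id, area_um2,
        equivalent_diameter_um, positive_fraction``
    """
    rng = np.random.default_rng(cfg.rng_seed)
    h, w = cfg.canvas_px
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = np.asarray(cfg.background_color, dtype=np.uint8)
    labels = np.zeros((h, w), dtype=np.int32)
    records = []
    for i, (center, radius, frac) in enumerate(cfg.nodules):
        nodule = _disk_mask((h, w), center, radius)
        labels[nodule] = i + 1
        area_px = int(nodule.sum())
        target_px = int(round(frac * area_px))
        positive = np.zeros((h, w), dtype=bool)
        if target_px == area_px:
            positive = nodule.copy()
        elif target_px > 0:
            blob_r = max(2, radius // 8)
            attempts = 0
            while positive.sum() < target_px and attempts < 10_000:
                ang = rng.uniform(0, 2 * np.pi)
                rad = radius * np.sqrt(rng.uniform())
                ctr = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
                positive |= _disk_mask((h, w), ctr, blob_r) & nodule
                attempts += 1
            # trim or top up individual pixels to hit the target count exactly
            excess = int(positive.sum()) - target_px
            if excess > 0:
                idx = np.flatnonzero(positive.ravel())
                drop = rng.choice(idx, size=excess, replace=False)
                positive.ravel()[drop] = False
            elif excess < 0:
                idx = np.flatnonzero((nodule & ~positive).ravel())
                add = rng.choice(idx, size=-excess, replace=False)
                positive.ravel()[add] = True
        image[positive] = np.asarray(cfg.stain_positive_color, dtype=np.uint8)
        records.append(
            {
                "nodule_id": i + 1,
                "area_um2": area_px * cfg.um_per_px**2,
                "equivalent_diameter_um": 2.0
                * np.sqrt(area_px * cfg.um_per_px**2 / np.pi),
                "positive_fraction": target_px / area_px if area_px else 0.0,
            }
        )
    return image, labels, records


def write_histology_bundle(cfg: SynthImageConfig, image, labels, records, outdir):
    """Write image (PNG), label mask (PNG) and a JSON sidecar with the truth."""
    import imageio.v3 as iio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(outdir / "slide.png", image)
    if labels.max() > 255:
        raise ConfigError("more than 255 nodules not supported by 8-bit mask PNG")
    iio.imwrite(outdir / "mask.png", labels.astype(np.uint8))
    sidecar = {"um_per_px": cfg.um_per_px, "nodules": records}
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return outdir / "slide.png", outdir / "mask.png", outdir / "truth.json"
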