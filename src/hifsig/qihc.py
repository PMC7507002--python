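"""Automated quantitative immunohistochemistry (qIHC).

Per-nodule morphometry from labeled masks (area, equivalent circular
diameter, max-Feret diameter), fixed-threshold positive-area fractions (DAB
optical density after color deconvolution, or a raw channel), size
dichotomization against a reference median diameter with a two-sided
chi-square test, log-normality checks of nodule diameters, translation-only
section alignment by normalized cross-correlation, colocalization of
matched per-nodule fractions on the log scale, fluorescence perfusion
fractions, and a thin wrapper for multi-group comparisons.

Conventions: pixel coordinates are 0-based row-major; masks are label
images with 0 = background; "equivalent diameter" is 2*sqrt(area/pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from skimage.color import rgb2gray, rgb2hed

from .exceptions import AlignmentError, InputError, ZeroAreaError


@dataclass
class StainImage:
    """An RGB (brightfield) or RGB/single-channel (fluorescence) raster."""

    pixels: np.ndarray
    um_per_px: float
    kind: str = "brightfield_DAB"  # or "fluorescence"

    def __post_init__(self) -> None:
        if self.pixels.ndim not in (2, 3) or min(self.pixels.shape[:2]) < 1:
            raise InputError(f"bad image shape {self.pixels.shape}")
        if not self.um_per_px > 0:
            raise InputError(f"um_per_px must be > 0, got {self.um_per_px}")
        if self.kind not in ("brightfield_DAB", "fluorescence"):
            raise InputError(f"unknown image kind {self.kind!r}")

    @classmethod
    def read(cls, path, um_per_px: float, kind: str = "brightfield_DAB"):
        import imageio.v3 as iio

        return cls(np.asarray(iio.imread(path)), um_per_px, kind)


@dataclass
class ThresholdSpec:
    """How a pixel counts as stain-positive.

    ``channel='DAB_optical_density'`` thresholds the DAB channel of the
    standard H&E-DAB color deconvolution (Ruifrok–Johnston stain vectors as
    shipped by scikit-image); ``'raw_channel'`` thresholds one raw image
    channel (``channel_index``). The default cutoff 0.05 OD separates
    DAB-brown chromogen from hematoxylin counterstain on this package's
    synthetic slides; real assays should calibrate per marker.
    """

    channel: str = "DAB_optical_density"
    cutoff: float = 0.05
    polarity: str = "above"
    channel_index: int = 1

    def __post_init__(self) -> None:
        if self.channel not in ("DAB_optical_density", "raw_channel"):
            raise InputError(f"unknown channel {self.channel!r}")
        if self.polarity not in ("above", "below"):
            raise InputError(f"polarity must be above/below, got {self.polarity!r}")


@dataclass
class NoduleRecord:
    """One metastatic nodule: morphometry plus per-marker positive fractions."""

    nodule_id: int
    group: str = ""
    area_um2: float = 0.0
    equivalent_diameter_um: float = 0.0
    feret_diameter_um: float = 0.0
    touches_border: bool = False
    positive_fraction: dict[str, float] = field(default_factory=dict)
    size_class: str = ""


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    markers = sorted({m for r in records for m in r.positive_fraction})
    for r in records:
        row = {
            "nodule_id": r.nodule_id,
            "group": r.group,
            "area_um2": r.area_um2,
            "eq_diameter_um": r.equivalent_diameter_um,
            "feret_um": r.feret_diameter_um,
            "touches_border": r.touches_border,
            "size_class": r.size_class,
        }
        for m in markers:
            row[f"fraction_{m}"] = r.positive_fraction.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def isolate_nodules(mask: np.ndarray, um_per_px: float, group: str = "") -> list[NoduleRecord]:
    """Morphometry of each connected component of a mask.

    Binary masks are labeled with 8-connectivity; integer label masks are
    used as-is. An empty mask yields an empty list. Components touching the
    raster border are flagged (their cross-sections are truncated).
    """
    if not um_per_px > 0:
        raise InputError(f"um_per_px must be > 0, got {um_per_px}")
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InputError(f"mask must be 2-D, got shape {mask.shape}")
    if mask.dtype == bool or set(np.unique(mask)).issubset({0, 1}):
        labels = measure.label(mask.astype(bool), connectivity=2)
    else:
        labels = mask.astype(int)
    h, w = labels.shape
    out = []
    for rp in measure.regionprops(labels):
        minr, minc, maxr, maxc = rp.bbox
        area_um2 = rp.area * um_per_px**2
        out.append(
            NoduleRecord(
                nodule_id=int(rp.label),
                group=group,
                area_um2=float(area_um2),
                equivalent_diameter_um=float(2.0 * np.sqrt(area_um2 / np.pi)),
                feret_diameter_um=float(rp.feret_diameter_max * um_per_px),
                touches_border=bool(minr == 0 or minc == 0 or maxr == h or maxc == w),
            )
        )
    out.sort(key=lambda r: r.nodule_id)
    return out


def _positive_pixels(img: StainImage, spec: ThresholdSpec) -> np.ndarray:
    px = img.pixels
    if spec.channel == "DAB_optical_density":
        if px.ndim != 3 or px.shape[2] < 3:
            raise InputError("DAB deconvolution needs an RGB image")
        chan = rgb2hed(px[..., :3])[..., 2]
    else:
        chan = px[..., spec.channel_index] if px.ndim == 3 else px
        chan = chan.astype(float)
    if spec.polarity == "above":
        return chan > spec.cutoff
    return chan < spec.cutoff


def positive_fraction(img: StainImage, nodule_mask: np.ndarray, spec: ThresholdSpec) -> float:
    """Fraction of in-mask pixels classified stain-positive under ``spec``."""
    nodule_mask = np.asarray(nodule_mask).astype(bool)
    if nodule_mask.shape != img.pixels.shape[:2]:
        raise InputError(
            f"mask shape {nodule_mask.shape} != image shape {img.pixels.shape[:2]}"
        )
    n = int(nodule_mask.sum())
    if n == 0:
        raise ZeroAreaError("nodule mask selects no pixels")
    pos = _positive_pixels(img, spec)
    return float((pos & nodule_mask).sum() / n)


def perfusion_fraction(fluor_img: StainImage, tissue_mask: np.ndarray, spec: ThresholdSpec) -> float:
    """Perfused area as a fraction of tissue cross-sectional area.

    Identical contract to :func:`positive_fraction` but intended for a
    fluorescence channel (e.g. FITC-dextran over a Hoechst tissue mask).
    """
    if fluor_img.kind != "fluorescence":
        raise InputError("perfusion_fraction expects a fluorescence image")
    return positive_fraction(fluor_img, tissue_mask, spec)


@dataclass
class SizeDichotomy:
    table: pd.DataFrame  # groups x {small, large}
    chi2: float
    df: int
    p: float
    warning: str | None = None


def size_dichotomize(records, reference_median_um: float) -> SizeDichotomy:
    """Label nodules small/large against a reference median diameter and test.

    ``large`` means equivalent diameter >= reference (closed on the large
    side). The group-by-size contingency table is tested with a Pearson
    chi-square, two-sided, without continuity correction. If any expected
    cell count is below 1 the test is still computed but flagged unreliable.
    Records are labelled in place.
    """
    if not reference_median_um > 0:
        raise InputError("reference_median must be > 0")
    for r in records:
        r.size_class = (
            "large" if r.equivalent_diameter_um >= reference_median_um else "small"
        )
    df_rec = records_to_frame(records)
    groups = df_rec["group"].unique()
    if len(groups) < 2:
        raise InputError("size dichotomization test needs >= 2 treatment groups")
    table = pd.crosstab(df_rec["group"], df_rec["size_class"]).reindex(
        columns=["small", "large"], fill_value=0
    )
    obs = table.to_numpy()
    warning = None
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return SizeDichotomy(table, 0.0, 0, float("nan"),
                             "degenerate contingency table (empty row/column)")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 1).any():
        warning = "expected cell count < 1; chi-square unreliable"
    return SizeDichotomy(table, float(chi2), int(dof), float(p), warning)


def lognormal_check(diameters) -> dict:
    """Shapiro–Wilk normality of log-diameters plus log-normal MLE parameters."""
    d = np.asarray(diameters, dtype=float)
    if d.size < 8:
        raise InputError(f"need >= 8 diameters, got {d.size}")
    if (d <= 0).any() or not np.isfinite(d).all():
        raise InputError("diameters must be positive and finite")
    logd = np.log(d)
    stat, p = stats.shapiro(logd)
    return {
        "shapiro_W": float(stat),
        "shapiro_p": float(p),
        "mu_hat": float(logd.mean()),
        "sigma_hat": float(logd.std(ddof=0)),
        "n": int(d.size),
    }


def _to_gray(img: StainImage) -> np.ndarray:
    px = img.pixels.astype(float)
    if px.ndim == 3:
        return rgb2gray(px[..., :3])
    return px


def align_sections(
    imgA: StainImage,
    imgB: StainImage,
    downsample: int = 1,
    min_correlation: float = 0.3,
    max_shift: int | None = None,
):
    """Translation-only registration of two consecutive sections.

    Maximizes the normalized cross-correlation (FFT-based, mean-subtracted,
    zero-padded) of grayscale versions of the two images, optionally
    downsampled. Returns ``((dr, dc), score)`` where (dr, dc) is the
    displacement of B's content relative to A's — shifting A by (dr, dc)
    overlays it on B. Raises :class:`AlignmentError` if the peak NCC is
    below ``min_correlation``.
    """
    if imgA.um_per_px != imgB.um_per_px:
        raise InputError("images must share one um/px scale")
    a = _to_gray(imgA)[::downsample, ::downsample]
    b = _to_gray(imgB)[::downsample, ::downsample]
    if a.shape != b.shape:
        raise InputError("aligned sections must share one raster shape")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise AlignmentError("blank image; no content to align")
    h, w = a.shape
    fa = np.fft.rfft2(a, s=(2 * h, 2 * w))
    fb = np.fft.rfft2(b, s=(2 * h, 2 * w))
    cc = np.fft.irfft2(fa * np.conj(fb), s=(2 * h, 2 * w))
    ncc = cc / (na * nb)
    dr = np.fft.fftfreq(2 * h, d=1.0 / (2 * h)).astype(int)
    dc = np.fft.fftfreq(2 * w, d=1.0 / (2 * w)).astype(int)
    valid = (np.abs(dr)[:, None] < h) & (np.abs(dc)[None, :] < w)
    if max_shift is not None:
        valid &= (np.abs(dr)[:, None] <= max_shift) & (np.abs(dc)[None, :] <= max_shift)
    masked = np.where(valid, ncc, -np.inf)
    peak = np.unravel_index(int(np.argmax(masked)), masked.shape)
    score = float(masked[peak])
    if score < min_correlation:
        raise AlignmentError(
            f"correlation peak {score:.3f} below floor {min_correlation}"
        )
    return (-int(dr[peak[0]]) * downsample, -int(dc[peak[1]]) * downsample), score


def coloc_correlation(fractionsA, fractionsB, zero_floor: float | None = None):
    """Pearson correlation of matched per-nodule fractions on the log scale.

    Accepts dicts keyed by nodule ID or equal-length sequences. Zero
    fractions are floored at half the smallest positive observed fraction
    (or ``zero_floor``) before the log transform; the applied floor is
    reported. Returns a dict with Pearson r, least-squares slope, the
    F-test p for slope != 0, n, and the floor used.
    """
    if isinstance(fractionsA, dict) and isinstance(fractionsB, dict):
        keys = sorted(set(fractionsA) & set(fractionsB))
        a = np.array([fractionsA[k] for k in keys], dtype=float)
        b = np.array([fractionsB[k] for k in keys], dtype=float)
    else:
        a = np.asarray(fractionsA, dtype=float)
        b = np.asarray(fractionsB, dtype=float)
        if a.shape != b.shape:
            raise InputError("fraction vectors must have matching length")
    if a.size < 4:
        raise InputError(f"need >= 4 matched pairs, got {a.size}")
    if (a < 0).any() or (b < 0).any():
        raise InputError("fractions must be non-negative")
    both = np.concatenate([a, b])
    pos = both[both > 0]
    if pos.size == 0:
        raise InputError("all fractions are zero; log transform undefined")
    floor = zero_floor if zero_floor is not None else float(pos.min() / 2.0)
    la = np.log(np.maximum(a, floor))
    lb = np.log(np.maximum(b, floor))
    res = stats.linregress(la, lb)
    return {
        "pearson_r": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p": float(res.pvalue),
        "n": int(a.size),
        "zero_floor": floor,
    }


def group_stats(groups: dict[str, np.ndarray], log_transform: bool = True) -> dict:
    """Multi-group comparison of per-nodule measurements (thin wrapper).

    Two groups are routed to Welch's t-test (with a notice); three or more
    use one-way Welch ANOVA on (optionally log-transformed) values followed
    by pairwise Welch t-tests corrected with the two-stage
    Benjamini–Krieger–Yekutieli FDR procedure. Delegates to established
    routines; this function only shapes inputs and tabulates outputs.
    """
    import itertools

    from statsmodels.stats.multitest import multipletests

    names = sorted(groups)
    if len(names) < 2:
        raise InputError("need >= 2 groups")
    clean = {}
    for k in names:
        v = np.asarray(groups[k], dtype=float)
        if v.size < 2:
            raise InputError(f"group {k!r} has < 2 values")
        if log_transform:
            if (v <= 0).any():
                raise InputError(f"group {k!r} has non-positive values; cannot log")
            v = np.log(v)
        clean[k] = v
    if len(names) == 2:
        a, b = clean[names[0]], clean[names[1]]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return {
            "test": "welch_t",
            "notice": "two groups supplied; routed to Welch t-test",
            "statistic": float(t),
            "p": float(p),
            "posthoc": None,
        }
    long = pd.DataFrame(
        {
            "value": np.concatenate([clean[k] for k in names]),
            "group": np.concatenate([[k] * len(clean[k]) for k in names]),
        }
    )
    import pingouin as pg

    aov = pg.welch_anova(data=long, dv="value", between="group")
    pairs = list(itertools.combinations(names, 2))
    raw = [
        stats.ttest_ind(clean[x], clean[y], equal_var=False).pvalue for x, y in pairs
    ]
    rej, adj, _, _ = multipletests(raw, alpha=0.05, method="fdr_tsbky")
    posthoc = pd.DataFrame(
        {
            "groupA": [x for x, _ in pairs],
            "groupB": [y for _, y in pairs],
            "p_raw": raw,
            "p_adj": adj,
            "significant": rej,
        }
    )
    return {
        "test": "welch_anova",
        "notice": None,
        "statistic": float(aov["F"].iloc[0]),
        "p": float(aov["p_unc"].iloc[0]),
        "posthoc": posthoc,
    }
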