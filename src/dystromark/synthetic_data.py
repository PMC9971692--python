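"""Seeded ground-truth generators for every pipeline stage.

The generators emulate the statistical structure the analyses assume —
not photorealistic histology:

- :func:`make_stain_image` — RGB stained-section images whose pixels fall
  into known classes (background / stain-positive / other tissue) with an
  exactly-known positive fraction, placed as spatially correlated blobs.
- :func:`make_fibre_map` — mosaics of non-overlapping fibre polygons with a
  lognormal minimum-Feret-diameter distribution of requested median and
  CoV, rendered as a bright-boundary image (perlecan-ring-like).
- :func:`simulate_cq_table` — long-format qPCR Cq tables with known fold
  changes, per-sample loading offsets, plate offsets, shared calibration
  samples and Gaussian Cq noise.
- :func:`simulate_cohort` — two-group longitudinal or multi-muscle cohorts
  with known cell means, between-animal variance and within-animal residual
  correlation.

Identical arguments plus seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely import affinity
from shapely.geometry import Polygon
from skimage.color import hsv2rgb
from skimage.draw import polygon as draw_polygon
import scipy.ndimage as ndi

from .fibre_morphometry import min_feret

# Generator colour windows (hue degrees).  These sit strictly inside the
# default analysis gates of :mod:`dystromark.stain_quant` (PSR red gate
# [330, 30), yellow [30, 90); AP red gate [330, 25)), so gate recovery is
# exact for noiseless colours and retains margin under colour jitter plus
# 8-bit quantisation.  A 2-degree interior margin absorbs rounding drift.
PSR_RED_HUE = (345.0, 15.0)
PSR_YELLOW_HUE = (40.0, 70.0)
AP_RED_HUE = (340.0, 20.0)
AP_COUNTERSTAIN_HUE = (220.0, 290.0)

_NOISELESS_COLOURS = {
    # exact uint8 triplets whose hues land inside the generator windows
    ("PSR", "positive"): (204, 26, 51),   # hue 351.6, S 0.87, B 0.80
    ("PSR", "other"): (230, 204, 26),     # hue 52.4,  S 0.89, B 0.90
    ("PSR", "background"): (242, 242, 242),
    ("AP", "positive"): (204, 26, 51),
    ("AP", "other"): (102, 51, 153),      # hue 270,   S 0.67, B 0.60
    ("AP", "background"): (250, 250, 250),
}


@dataclass
class StainImageTruth:
    """A synthetic stained-section image with its exact pixel-class truth."""

    image: np.ndarray = field(repr=False)  # (H, W, 3) uint8
    class_mask: np.ndarray = field(repr=False)  # 0 bg, 1 positive, 2 other
    true_fraction: float
    stain_kind: str
    seed: int
    params: dict = field(default_factory=dict, repr=False)


def _sample_hue(rng, window, n, margin=2.0):
    lo, hi = window
    lo, hi = lo + margin, hi - margin
    if lo > hi:  # wraps through 0
        span = (360.0 - lo) + hi
        h = lo + rng.uniform(0.0, span, n)
        return np.mod(h, 360.0)
    return rng.uniform(lo, hi, n)


def make_stain_image(
    stain_kind: str,
    target_fraction: float,
    size=(512, 512),
    texture_params: dict | None = None,
    seed: int = 0,
) -> StainImageTruth:
    """Generate a stained-section image with exactly known class fractions.

    Stain-positive pixels are placed as spatially correlated blobs: a
    Gaussian-smoothed noise field is thresholded at the exact within-tissue
    quantile, so ``true_fraction`` equals the realised positive/tissue pixel
    ratio by construction (within one pixel of ``target_fraction``).

    Parameters
    ----------
    stain_kind : {"PSR", "AP"}
    target_fraction : float in [0, 1]
        Requested stain-positive fraction of the tissue area.
    size : (height, width), each >= 64
    texture_params : dict, optional
        ``tissue_fraction`` (default 0.85) — fraction of the field occupied
        by tissue; ``blob_sigma`` (px, default 12) — correlation length of
        stain blobs; ``background_sigma`` (default 24); ``colour_noise``
        (default True) — jitter hue/saturation/brightness inside the
        generator windows; False gives one fixed exact colour per class.
    seed : int
    """
    kind = stain_kind.upper()
    if kind not in ("PSR", "AP"):
        raise ValueError(f"unknown stain kind {stain_kind!r}")
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    h, w = int(size[0]), int(size[1])
    if h < 64 or w < 64:
        raise ValueError("size must be at least 64x64")
    tp = {
        "tissue_fraction": 0.85,
        "blob_sigma": 12.0,
        "background_sigma": 24.0,
        "colour_noise": True,
    }
    tp.update(texture_params or {})
    rng = np.random.default_rng(seed)

    n_pixels = h * w
    bg_field = ndi.gaussian_filter(rng.standard_normal((h, w)), tp["background_sigma"])
    n_tissue = int(round(tp["tissue_fraction"] * n_pixels))
    order = np.argsort(bg_field, axis=None, kind="stable")
    tissue_flat = np.zeros(n_pixels, dtype=bool)
    tissue_flat[order[:n_tissue]] = True

    stain_field = ndi.gaussian_filter(rng.standard_normal((h, w)), tp["blob_sigma"])
    n_pos = int(round(target_fraction * n_tissue))
    tissue_idx = np.nonzero(tissue_flat)[0]
    pos_rank = np.argsort(stain_field.ravel()[tissue_idx], kind="stable")[::-1]
    positive_flat = np.zeros(n_pixels, dtype=bool)
    positive_flat[tissue_idx[pos_rank[:n_pos]]] = True

    class_mask = np.full(n_pixels, 0, dtype=np.uint8)
    class_mask[tissue_flat] = 2
    class_mask[positive_flat] = 1
    class_mask = class_mask.reshape(h, w)

    image = _paint_classes(class_mask, kind, rng, colour_noise=tp["colour_noise"])
    true_fraction = (n_pos / n_tissue) if n_tissue else 0.0
    return StainImageTruth(
        image=image,
        class_mask=class_mask,
        true_fraction=true_fraction,
        stain_kind=kind,
        seed=seed,
        params=tp,
    )


def _paint_classes(class_mask, kind, rng, colour_noise=True):
    h, w = class_mask.shape
    if not colour_noise:
        img = np.zeros((h, w, 3), dtype=np.uint8)
        for cls, name in ((0, "background"), (1, "positive"), (2, "other")):
            img[class_mask == cls] = _NOISELESS_COLOURS[(kind, name)]
        return img
    hsv = np.zeros((h, w, 3), dtype=float)
    for cls in (0, 1, 2):
        sel = class_mask == cls
        n = int(sel.sum())
        if n == 0:
            continue
        if cls == 0:  # background
            if kind == "PSR":
                # near-white grey: saturation exactly 0, below the S < 0.15 gate
                v = rng.uniform(0.93, 0.99, n)
                hsv[sel] = np.column_stack([np.zeros(n), np.zeros(n), v])
            else:
                # bright grey above the AP B > 0.92 background gate
                v = rng.uniform(0.965, 1.0, n)
                hsv[sel] = np.column_stack([np.zeros(n), np.zeros(n), v])
        elif cls == 1:  # stain positive (red)
            window = PSR_RED_HUE if kind == "PSR" else AP_RED_HUE
            hue = _sample_hue(rng, window, n)
            s = rng.uniform(0.55, 0.9, n) if kind == "PSR" else rng.uniform(0.45, 0.85, n)
            v = rng.uniform(0.5, 0.88, n)
            hsv[sel] = np.column_stack([hue / 360.0, s, v])
        else:  # other tissue
            window = PSR_YELLOW_HUE if kind == "PSR" else AP_COUNTERSTAIN_HUE
            hue = _sample_hue(rng, window, n)
            s = rng.uniform(0.5, 0.9, n) if kind == "PSR" else rng.uniform(0.3, 0.7, n)
            v = rng.uniform(0.6, 0.9, n) if kind == "PSR" else rng.uniform(0.45, 0.85, n)
            hsv[sel] = np.column_stack([hue / 360.0, s, v])
    return np.round(hsv2rgb(hsv) * 255.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# Fibre mosaics
# ---------------------------------------------------------------------------

@dataclass
class FibreMapTruth:
    """A fibre mosaic with per-polygon minimum Feret diameter ground truth."""

    polygons: list = field(repr=False)  # (n, 2) µm vertex arrays
    boundary_image: np.ndarray = field(repr=False)  # uint8, boundaries bright
    true_mfd: np.ndarray = field(repr=False)  # µm, one per polygon
    pixel_size: float  # µm / px
    seed: int
    requested_median: float | None = None
    requested_cov: float | None = None
    # generator-declared recovery tolerances for requested vs realised stats
    median_tolerance: float = 0.10  # relative
    cov_tolerance: float = 0.05  # absolute


def make_fibre_map(
    n_fibres: int,
    median_mfd_um: float = 40.0,
    cov: float = 0.25,
    pixel_size: float = 0.5,
    seed: int = 0,
) -> FibreMapTruth:
    """Generate a mosaic of fibre polygons with lognormal MFD distribution.

    A jittered-grid Voronoi tessellation supplies non-overlapping convex
    cells; each cell is eroded (leaving a bright inter-fibre boundary about
    3 px wide between neighbours) and then shrunk about its centroid so its
    minimum Feret diameter matches a lognormal target draw.  Targets are
    rank-matched to cell sizes; a target exceeding its cell is clamped to
    fit, which is why realised median/CoV carry a declared tolerance rather
    than matching the request exactly.  ``true_mfd`` is recomputed from the
    final polygons by rotating calipers, so it is exact by construction.
    """
    if n_fibres < 4:
        raise ValueError("need at least 4 fibres")
    if median_mfd_um <= 0:
        raise ValueError("median_mfd_um must be positive")
    if not 0 <= cov < 1:
        raise ValueError("cov must be in [0, 1): lognormal areas degenerate beyond")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cov ** 2))
    targets = rng.lognormal(mean=np.log(median_mfd_um), sigma=sigma, size=n_fibres)

    spacing = 1.3 * float(np.quantile(targets, 0.95))
    n_side = int(np.ceil(np.sqrt(n_fibres)))
    ii, jj = np.meshgrid(np.arange(n_side + 2), np.arange(n_side + 2), indexing="ij")
    pts = np.column_stack([(ii.ravel() + 0.5), (jj.ravel() + 0.5)]) * spacing
    pts += rng.uniform(-0.2 * spacing, 0.2 * spacing, pts.shape)
    vor = Voronoi(pts)

    interior = [
        k
        for k in range(len(pts))
        if 1 <= k // (n_side + 2) <= n_side and 1 <= k % (n_side + 2) <= n_side
    ]
    cells = []
    for k in interior:
        region = vor.regions[vor.point_region[k]]
        if -1 in region or len(region) < 3:
            continue
        cell = Polygon(vor.vertices[region])
        base = cell.buffer(-1.5 * pixel_size, join_style=2)
        if base.is_empty or base.geom_type != "Polygon":
            continue
        cells.append(base)
        if len(cells) == n_fibres:
            break
    if len(cells) < n_fibres:
        raise RuntimeError("tessellation produced too few usable cells")

    base_mfd = np.array([min_feret(c) for c in cells])
    cell_rank = np.argsort(base_mfd)
    target_rank = np.argsort(targets)
    polygons: list[np.ndarray | None] = [None] * n_fibres
    true_mfd = np.zeros(n_fibres)
    for ci, ti in zip(cell_rank, target_rank):
        factor = min(1.0, targets[ti] / base_mfd[ci])
        scaled = affinity.scale(cells[ci], xfact=factor, yfact=factor, origin="centroid")
        coords = np.asarray(scaled.exterior.coords)[:-1]
        polygons[ti] = coords
        true_mfd[ti] = min_feret(coords)

    # translate into a tight positive frame and render
    allpts = np.vstack(polygons)
    offset = allpts.min(axis=0) - 2.0 * pixel_size
    polygons = [p - offset for p in polygons]
    extent = np.vstack(polygons).max(axis=0) + 2.0 * pixel_size
    boundary_image = _render_boundary_image(polygons, extent, pixel_size)
    return FibreMapTruth(
        polygons=polygons,
        boundary_image=boundary_image,
        true_mfd=true_mfd,
        pixel_size=pixel_size,
        seed=seed,
        requested_median=median_mfd_um,
        requested_cov=cov,
    )


def _render_boundary_image(polygons, extent_um, pixel_size,
                           boundary_value=220, interior_value=30):
    w = int(np.ceil(extent_um[0] / pixel_size)) + 1
    h = int(np.ceil(extent_um[1] / pixel_size)) + 1
    img = np.full((h, w), boundary_value, dtype=np.uint8)
    for poly in polygons:
        rr, cc = draw_polygon(poly[:, 1] / pixel_size, poly[:, 0] / pixel_size, (h, w))
        img[rr, cc] = interior_value
    return img


def fibre_map_from_polygons(polygons, pixel_size: float, seed: int = 0) -> FibreMapTruth:
    """Build a :class:`FibreMapTruth` from explicit polygons (µm coordinates)."""
    polys = [np.asarray(p, dtype=float) for p in polygons]
    allpts = np.vstack(polys)
    offset = allpts.min(axis=0) - 2.0 * pixel_size
    polys = [p - offset for p in polys]
    extent = np.vstack(polys).max(axis=0) + 2.0 * pixel_size
    img = _render_boundary_image(polys, extent, pixel_size)
    return FibreMapTruth(
        polygons=polys,
        boundary_image=img,
        true_mfd=np.array([min_feret(p) for p in polys]),
        pixel_size=pixel_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCqTable:
    """Long-format Cq table plus the generating truth."""

    table: pd.DataFrame = field(repr=False)
    truth: dict = field(repr=False)
    seed: int = 0


def simulate_cq_table(
    n_per_group: int = 12,
    goi_fold_changes: dict | None = None,
    *,
    groups=("WT", "DE50MD"),
    reference_targets=("SDHA", "RPL13a", "HPRT1"),
    ref_gene_sd: float = 0.0,
    plate_offsets=(0.0,),
    cq_noise_sd: float = 0.1,
    sample_loading_sd: float = 0.5,
    n_replicates: int = 2,
    n_calibration: int = 4,
    seed: int = 0,
) -> SimulatedCqTable:
    """Simulate a multi-plate qPCR experiment with known fold changes.

    The Cq model for sample *s*, target *g*, plate *p*, replicate *r*::

        Cq = base_g − log2(FC_g)·[s in group 2] + load_s + offset_p + ε

    ``load_s`` is a per-sample cDNA-loading offset shared by every target
    (what reference normalisation removes), ``offset_p`` a whole-plate
    shift (what inter-plate calibration removes), and ε Gaussian noise of
    SD ``cq_noise_sd``; reference targets additionally carry N(0,
    ``ref_gene_sd``) per-sample instability.  Before noise, the normalised
    RQ ratio between groups equals ``goi_fold_changes`` by construction.

    The first ``n_calibration`` samples (split evenly across groups) are
    measured on every plate; remaining samples are assigned round-robin.
    Multi-plate designs require at least 4 calibration samples.
    """
    if goi_fold_changes is None:
        goi_fold_changes = {"GOI1": 1.0}
    if ref_gene_sd < 0 or cq_noise_sd < 0 or sample_loading_sd < 0:
        raise ValueError("noise SDs must be non-negative")
    if set(goi_fold_changes) & set(reference_targets):
        raise ValueError("a target cannot be both GOI and reference")
    n_plates = len(plate_offsets)
    if n_plates > 1 and n_calibration < 4:
        raise ValueError("multi-plate designs need >= 4 calibration samples")
    if n_calibration > n_per_group * len(groups):
        raise ValueError("more calibration samples than samples")
    rng = np.random.default_rng(seed)

    samples = [(f"{g}-{i + 1:02d}", g) for g in groups for i in range(n_per_group)]
    # calibration samples drawn evenly from the groups, first animals first
    per_group = int(np.ceil(n_calibration / len(groups)))
    calib_ids = [
        f"{g}-{i + 1:02d}" for g in groups for i in range(per_group)
    ][:n_calibration]

    targets = list(goi_fold_changes) + list(reference_targets)
    base_cq = {t: rng.uniform(20.0, 26.0) for t in targets}
    loading = {sid: rng.normal(0.0, sample_loading_sd) for sid, _ in samples}

    plate_of = {}
    rot = 0
    for sid, _ in samples:
        if sid in calib_ids:
            continue
        plate_of[sid] = rot % n_plates
        rot += 1

    rows = []
    for sid, grp in samples:
        plates = range(n_plates) if sid in calib_ids else [plate_of[sid]]
        for t in targets:
            fc = goi_fold_changes.get(t, 1.0)
            cq_true = base_cq[t] + loading[sid]
            if grp == groups[1]:
                cq_true -= np.log2(fc)
            if t in reference_targets and ref_gene_sd > 0:
                cq_true += rng.normal(0.0, ref_gene_sd)
            for p in plates:
                for rep in range(n_replicates):
                    cq = cq_true + plate_offsets[p]
                    if cq_noise_sd > 0:
                        cq += rng.normal(0.0, cq_noise_sd)
                    rows.append(
                        {
                            "sample_id": sid,
                            "group": grp,
                            "target": t,
                            "plate_id": f"P{p + 1}",
                            "well": f"P{p + 1}_{t}_{sid}_r{rep + 1}",
                            "cq": cq,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = {
        "fold_changes": dict(goi_fold_changes),
        "base_cq": base_cq,
        "loading": loading,
        "plate_offsets": list(plate_offsets),
        "calibration_samples": calib_ids,
        "reference_targets": list(reference_targets),
        "groups": list(groups),
    }
    return SimulatedCqTable(table=table, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Tidy cohort records plus the generating truth."""

    records: pd.DataFrame = field(repr=False)
    truth: dict = field(repr=False)
    seed: int = 0


def _correlation_matrix(corr, k):
    if np.isscalar(corr):
        R = np.full((k, k), float(corr))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(corr, dtype=float)
        if R.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    return R


def simulate_cohort(
    cell_means,
    sd_between: float,
    sd_within: float,
    corr=0.0,
    n_per_group: int = 6,
    *,
    levels=None,
    biomarker: str = "biomarker",
    dropout: float = 0.0,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a two-or-more-group repeated-measures cohort.

    ``value = cell_mean + animal_intercept + correlated_residual`` with the
    intercept N(0, ``sd_between``) per animal and residuals across the
    repeated levels MVN(0, ``sd_within²·R``), R a compound-symmetry matrix
    from scalar ``corr`` or a full correlation matrix.

    Parameters
    ----------
    cell_means : dict or DataFrame
        ``{group: per-level means}``; all groups must share the levels.
    dropout : float in [0, 1)
        Per-cell missingness probability (mimics incomplete biopsy series).
    """
    if isinstance(cell_means, pd.DataFrame):
        means = {g: cell_means.loc[g].to_numpy(float) for g in cell_means.index}
    else:
        means = {g: np.asarray(v, dtype=float) for g, v in cell_means.items()}
    k = len(next(iter(means.values())))
    if any(len(v) != k for v in means.values()):
        raise ValueError("every group needs the same number of levels")
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    if sd_between < 0 or sd_within < 0:
        raise ValueError("SDs must be non-negative")
    if levels is None:
        levels = [f"L{i + 1}" for i in range(k)]
    R = _correlation_matrix(corr, k)
    w, V = np.linalg.eigh(R)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)

    rows = []
    for grp, mu in means.items():
        for a in range(n_per_group):
            animal = f"{grp}-{a + 1:03d}"
            intercept = rng.normal(0.0, sd_between) if sd_between > 0 else 0.0
            resid = sd_within * (L @ rng.standard_normal(k)) if sd_within > 0 else np.zeros(k)
            keep = rng.uniform(size=k) >= dropout if dropout > 0 else np.ones(k, bool)
            for j, lev in enumerate(levels):
                if not keep[j]:
                    continue
                rows.append(
                    {
                        "animal_id": animal,
                        "group": grp,
                        "level": lev,
                        "biomarker": biomarker,
                        "value": mu[j] + intercept + resid[j],
                    }
                )
    truth = {
        "cell_means": {g: list(v) for g, v in means.items()},
        "sd_between": sd_between,
        "sd_within": sd_within,
        "correlation": R,
        "levels": list(levels),
    }
    return SimulatedCohort(records=pd.DataFrame(rows), truth=truth, seed=seed)
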