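"""HSB colour-gated quantification of histological stains.

Two brightfield stains are quantified by partitioning pixels in
hue/saturation/brightness (HSB) space:

- **Picrosirius red (PSR)**: Sirius red marks collagen, picric acid stains
  muscle yellow.  Saturation gating removes the near-white background
  (brightness is ignored), and hue separates red from yellow tissue.  The
  per-image *fibrosis fraction* is ``red / (red + yellow)``; the per-sample
  value is the arithmetic mean over images.
- **Acid phosphatase (AP)**: red reaction product over a blue/purple
  haemalum counterstain.  Brightness gating removes background, a minimum
  saturation thresholds genuine staining, and hue separates red AP signal
  from counterstained tissue.  The per-image *AP fraction* is
  ``red / total tissue``; because AP staining is focal, the per-sample
  value is the geometric mean over images.

Both metrics are area-based: a pixel either counts or it does not, with no
intensity weighting.  Gate windows are explicit, serialisable numbers so
they can be recalibrated per staining batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as skcolor

logger = logging.getLogger(__name__)

BACKGROUND, POSITIVE, OTHER = 0, 1, 2


class EmptyFieldError(ValueError):
    """Raised when an image contains too little tissue to quantify."""


# ---------------------------------------------------------------------------
# Colour-space conversion and circular hue arithmetic
# ---------------------------------------------------------------------------

def rgb_to_hsb(image: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to HSB (hexcone model).

    Returns an array of the same spatial shape with channels
    (hue in degrees [0, 360), saturation [0, 1], brightness [0, 1]).
    Grey pixels have saturation 0 and hue 0 by convention.  8-bit input is
    assumed; 16-bit images are rescaled by their dtype maximum.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if img.dtype == np.uint8:
        rgb = img / 255.0
    elif img.dtype == np.uint16:
        rgb = img / 65535.0
    else:
        rgb = img.astype(float)
        if rgb.max() > 1.0:
            rgb = rgb / 255.0
    hsv = skcolor.rgb2hsv(rgb)
    hsb = hsv.copy()
    hsb[..., 0] = hsv[..., 0] * 360.0
    return hsb


def hue_in_windows(hue_deg: np.ndarray, windows) -> np.ndarray:
    """Membership of hue values in a union of circular [lo, hi) windows.

    A window with ``lo > hi`` wraps through 0° (e.g. ``(330, 30)``).
    """
    h = np.mod(np.asarray(hue_deg, dtype=float), 360.0)
    out = np.zeros(h.shape, dtype=bool)
    for lo, hi in windows:
        if lo <= hi:
            out |= (h >= lo) & (h < hi)
        else:
            out |= (h >= lo) | (h < hi)
    return out


def hue_distance_to_windows(hue_deg: np.ndarray, windows) -> np.ndarray:
    """Minimal circular distance (degrees) from each hue to a window union."""
    h = np.mod(np.asarray(hue_deg, dtype=float), 360.0)
    dist = np.full(h.shape, np.inf)
    inside = hue_in_windows(h, windows)
    for lo, hi in windows:
        for edge in (lo, hi):
            d = np.abs(h - edge)
            d = np.minimum(d, 360.0 - d)
            dist = np.minimum(dist, d)
    dist[inside] = 0.0
    return dist


# ---------------------------------------------------------------------------
# Gate specification
# ---------------------------------------------------------------------------

@dataclass
class HsbGateSpec:
    """HSB windows defining the pixel classes of one staining protocol.

    The numeric defaults are package choices made to contain the synthetic
    generator's colour models with margin; real staining batches should be
    recalibrated and the spec stored alongside the results.
    """

    stain_kind: str  # "PSR" | "AP"
    positive_hue_windows: tuple = ()  # circular [lo, hi) degree intervals
    other_hue_windows: tuple = ()
    background_max_saturation: float | None = None  # PSR background rule
    background_min_brightness: float | None = None  # AP background rule
    min_saturation_for_stain: float = 0.0  # AP stain-intensity threshold
    min_tissue_fraction: float = 0.01  # empty-field floor

    def __post_init__(self):
        pos = set()
        for lo, hi in self.positive_hue_windows:
            pos.update(self._degrees(lo, hi))
        for lo, hi in self.other_hue_windows:
            if pos & set(self._degrees(lo, hi)):
                raise ValueError("positive and other hue windows overlap")

    @staticmethod
    def _degrees(lo, hi):
        if lo <= hi:
            return range(int(lo), int(np.ceil(hi)))
        return list(range(int(lo), 360)) + list(range(0, int(np.ceil(hi))))

    @classmethod
    def psr_default(cls) -> "HsbGateSpec":
        return cls(
            stain_kind="PSR",
            positive_hue_windows=((330.0, 30.0),),
            other_hue_windows=((30.0, 90.0),),
            background_max_saturation=0.15,
        )

    @classmethod
    def ap_default(cls) -> "HsbGateSpec":
        return cls(
            stain_kind="AP",
            positive_hue_windows=((330.0, 25.0),),
            other_hue_windows=(),
            background_min_brightness=0.92,
            min_saturation_for_stain=0.20,
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "HsbGateSpec":
        d = json.loads(Path(path).read_text())
        for key in ("positive_hue_windows", "other_hue_windows"):
            d[key] = tuple(tuple(w) for w in d[key])
        return cls(**d)


def default_gate(stain_kind: str) -> HsbGateSpec:
    kind = stain_kind.upper()
    if kind == "PSR":
        return HsbGateSpec.psr_default()
    if kind == "AP":
        return HsbGateSpec.ap_default()
    raise ValueError(f"unknown stain kind {stain_kind!r}")


# ---------------------------------------------------------------------------
# Pixel classification and fractions
# ---------------------------------------------------------------------------

def classify_pixels(image: np.ndarray, gate: HsbGateSpec):
    """Partition every pixel into background / stain-positive / other tissue.

    PSR: a pixel is background iff its saturation is below the background
    threshold (brightness ignored); tissue pixels are split red vs yellow by
    hue, and tissue hues falling in neither window are force-assigned to the
    nearer window by circular distance so that red + yellow exhaust the
    tissue (the fibrosis-fraction denominator is red + yellow only).

    AP: a pixel is background iff its brightness exceeds the background
    threshold; stain-positive requires both saturation at or above the
    stain-intensity minimum and hue inside the red window; every other
    non-background pixel is counterstained tissue.

    Returns
    -------
    labels : ndarray of uint8
        Per-pixel class (0 background, 1 positive, 2 other).
    counts : dict
        ``n_background``, ``n_positive``, ``n_other``.
    """
    hsb = rgb_to_hsb(image)
    hue, sat, bri = hsb[..., 0], hsb[..., 1], hsb[..., 2]
    labels = np.zeros(hue.shape, dtype=np.uint8)
    if gate.stain_kind == "PSR":
        tissue = sat >= gate.background_max_saturation
        in_pos = hue_in_windows(hue, gate.positive_hue_windows)
        in_other = hue_in_windows(hue, gate.other_hue_windows)
        unassigned = tissue & ~in_pos & ~in_other
        if unassigned.any():
            d_pos = hue_distance_to_windows(hue[unassigned], gate.positive_hue_windows)
            d_other = hue_distance_to_windows(hue[unassigned], gate.other_hue_windows)
            in_pos = in_pos.copy()
            in_other = in_other.copy()
            sub_pos = d_pos <= d_other
            idx = np.nonzero(unassigned)
            in_pos[idx[0][sub_pos], idx[1][sub_pos]] = True
            in_other[idx[0][~sub_pos], idx[1][~sub_pos]] = True
        labels[tissue & in_pos] = POSITIVE
        labels[tissue & in_other & ~in_pos] = OTHER
    elif gate.stain_kind == "AP":
        tissue = bri <= gate.background_min_brightness
        stain = (
            tissue
            & (sat >= gate.min_saturation_for_stain)
            & hue_in_windows(hue, gate.positive_hue_windows)
        )
        labels[stain] = POSITIVE
        labels[tissue & ~stain] = OTHER
    else:
        raise ValueError(f"unknown stain kind {gate.stain_kind!r}")
    counts = {
        "n_background": int((labels == BACKGROUND).sum()),
        "n_positive": int((labels == POSITIVE).sum()),
        "n_other": int((labels == OTHER).sum()),
    }
    n_tissue = counts["n_positive"] + counts["n_other"]
    if n_tissue < gate.min_tissue_fraction * labels.size:
        raise EmptyFieldError(
            f"only {n_tissue} tissue pixels of {labels.size} "
            f"(floor {gate.min_tissue_fraction:.0%}): empty field"
        )
    return labels, counts


@dataclass
class StainFraction:
    """Per-image stain fraction with its pixel bookkeeping."""

    image_id: str
    stain_kind: str
    n_positive: int
    n_other: int
    n_background: int
    fraction: float


def stain_fraction(counts: dict, stain_kind: str, image_id: str = "") -> StainFraction:
    """Per-image fraction from pixel counts.

    PSR: red/(red + yellow).  AP: red/total tissue.  Both reduce to
    positive/(positive + other) because tissue = positive + other;
    background never enters the denominator.
    """
    n_pos, n_other = counts["n_positive"], counts["n_other"]
    if n_pos + n_other <= 0:
        raise EmptyFieldError("no tissue pixels; cannot form a fraction")
    return StainFraction(
        image_id=image_id,
        stain_kind=stain_kind,
        n_positive=n_pos,
        n_other=n_other,
        n_background=counts.get("n_background", 0),
        fraction=n_pos / (n_pos + n_other),
    )


@dataclass
class SampleStainSummary:
    sample_id: str
    stain_kind: str
    per_image: list = field(repr=False)
    summary: float = 0.0
    aggregation: str = "arithmetic"


def sample_summary(
    fractions,
    stain_kind: str,
    *,
    sample_id: str = "",
    zero_substitute: float | None = None,
) -> SampleStainSummary:
    """Aggregate per-image fractions into the per-sample value.

    PSR uses the arithmetic mean.  AP uses the geometric mean (AP staining
    is focal, so a log-scale average is the stabler summary); zero
    per-image fractions are replaced before taking logs by
    ``1 / tissue-pixel count`` of that image — the smallest expressible
    nonzero fraction — when :class:`StainFraction` objects are supplied, or
    by ``zero_substitute`` for bare floats.
    """
    if len(fractions) == 0:
        raise ValueError("need at least one per-image fraction")
    vals, subs = [], []
    for f in fractions:
        if isinstance(f, StainFraction):
            vals.append(f.fraction)
            subs.append(1.0 / max(f.n_positive + f.n_other, 1))
        else:
            vals.append(float(f))
            subs.append(zero_substitute)
    vals = np.asarray(vals, dtype=float)
    kind = stain_kind.upper()
    if kind == "PSR":
        summary, agg = float(np.mean(vals)), "arithmetic"
    elif kind == "AP":
        adj = vals.copy()
        for i, v in enumerate(vals):
            if v <= 0:
                if subs[i] is None:
                    raise ValueError(
                        "zero AP fraction needs tissue counts or zero_substitute"
                    )
                adj[i] = subs[i]
        summary, agg = float(np.exp(np.mean(np.log(adj)))), "geometric"
    else:
        raise ValueError(f"unknown stain kind {stain_kind!r}")
    return SampleStainSummary(
        sample_id=sample_id,
        stain_kind=kind,
        per_image=list(fractions),
        summary=summary,
        aggregation=agg,
    )


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------

def _read_image(path):
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        return tifffile.imread(p)
    import imageio.v3 as iio

    return iio.imread(p)


def batch_quantify(manifest, gate: HsbGateSpec | None = None):
    """Quantify a manifest of images and aggregate per sample.

    Parameters
    ----------
    manifest : DataFrame or path to CSV
        Columns ``image_path, sample_id, batch_id`` (and optionally
        ``stain``, otherwise the gate's kind applies to every row).
    gate : HsbGateSpec, optional
        Defaults per stain kind.

    Returns
    -------
    per_image : DataFrame
        One row per successfully quantified image.
    per_sample : DataFrame
        One row per sample with its aggregated summary, deterministically
        ordered by (batch_id, sample_id).
    failures : list of (image_path, message)
        Unreadable or empty images; the run continues past them, but a
        batch in which every image failed raises.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"image_path", "sample_id", "batch_id"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rows, failures = [], []
    for _, rec in manifest.sort_values(["batch_id", "sample_id", "image_path"]).iterrows():
        kind = str(rec.get("stain", gate.stain_kind if gate else "PSR")).upper()
        g = gate if gate is not None else default_gate(kind)
        try:
            img = _read_image(rec["image_path"])
            _, counts = classify_pixels(img, g)
            frac = stain_fraction(counts, kind, image_id=str(rec["image_path"]))
        except Exception as exc:  # row-level failure: record and continue
            logger.warning("failed on %s: %s", rec["image_path"], exc)
            failures.append((str(rec["image_path"]), str(exc)))
            continue
        rows.append(
            {
                "batch_id": rec["batch_id"],
                "sample_id": rec["sample_id"],
                "image_path": str(rec["image_path"]),
                "stain": kind,
                "n_positive": frac.n_positive,
                "n_other": frac.n_other,
                "n_background": frac.n_background,
                "fraction": frac.fraction,
            }
        )
    per_image = pd.DataFrame(rows)
    if per_image.empty:
        raise EmptyFieldError("every image in the batch failed")
    summaries = []
    for (batch, sample), grp in per_image.groupby(["batch_id", "sample_id"], sort=True):
        kind = grp["stain"].iloc[0]
        fracs = [
            StainFraction(r.image_path, kind, r.n_positive, r.n_other,
                          r.n_background, r.fraction)
            for r in grp.itertuples()
        ]
        summ = sample_summary(fracs, kind, sample_id=str(sample))
        summaries.append(
            {
                "batch_id": batch,
                "sample_id": sample,
                "stain": kind,
                "n_images": len(fracs),
                "summary": summ.summary,
                "aggregation": summ.aggregation,
            }
        )
    per_sample = pd.DataFrame(summaries)
    return per_image, per_sample, failures
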