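"""qPCR relative quantification with inter-plate calibration.

The pipeline is the standard efficiency-based relative-quantity (RQ)
workflow for SYBR-green assays spread over multiple plates:

1. technical replicates of each (sample, target, plate) are averaged on the
   Cq scale (replicate SD above 0.5 cycles is flagged);
2. each mean Cq becomes ``RQ = (1 + E)^(anchor − Cq)`` with per-target
   amplification efficiency E (assays in this study all fell in the
   95–105% band, so the default is E = 1, i.e. perfect doubling); the
   anchor is the per-target mean Cq of the calibration samples, making RQs
   unitless and comparable within a target only;
3. a set of calibration samples run on every plate supplies per-plate
   correction factors (geometric means in log space), cancelling
   whole-plate offsets exactly;
4. gene-of-interest RQs are normalised per sample to the geometric mean of
   the three reference genes (SDHA, RPL13a, HPRT1 by default), removing
   cDNA-loading differences.

Multi-site dystrophin metrics express the 3' (exon 62–64, mature
transcript) and mid-transcript (exon 44–45) signals as fractions of total
transcriptional initiation (exon 1–2): nonsense-mediated decay degrades
only mature mutant transcripts, so the maturity fraction collapses in
dystrophic muscle while initiation is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_REFERENCES = ("SDHA", "RPL13a", "HPRT1")
REPLICATE_SD_FLAG = 0.5  # cycles


class CalibrationError(ValueError):
    """A calibration sample is missing from a plate."""


def _geomean(x):
    x = np.asarray(x, dtype=float)
    return float(np.exp(np.mean(np.log(x))))


# ---------------------------------------------------------------------------
# Cq -> RQ
# ---------------------------------------------------------------------------

def cq_to_rq(cq, efficiency: float = 1.0, anchor_cq: float = 0.0):
    """Convert Cq values to relative quantities.

    ``RQ = (1 + efficiency)^(anchor_cq − cq)``; with efficiency 1 each cycle
    is a perfect doubling, so a Cq three cycles above the anchor gives
    RQ = 1/8.  Non-finite Cq values (non-detects) propagate as NaN — they
    are treated as missing, never as zero.
    """
    if not 0.5 < efficiency < 1.5:
        raise ValueError("efficiency must be in (0.5, 1.5) (fraction above 1x/cycle)")
    cq = np.asarray(cq, dtype=float)
    out = (1.0 + efficiency) ** (anchor_cq - cq)
    return float(out) if out.ndim == 0 else out


def aggregate_replicates(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq per (sample, target, plate), flagging noisy replicates.

    Returns one row per well group with ``cq`` (mean), ``cq_sd``,
    ``n_replicates`` and ``replicate_flag`` (SD > 0.5 cycles).
    """
    required = {"sample_id", "target", "plate_id", "cq"}
    if not required.issubset(cq_table.columns):
        raise ValueError(f"Cq table must have columns {sorted(required)}")
    keys = ["sample_id", "target", "plate_id"]
    extra = [c for c in ("group",) if c in cq_table.columns]
    agg = (
        cq_table.groupby(keys + extra, sort=True)["cq"]
        .agg(cq="mean", cq_sd="std", n_replicates="count")
        .reset_index()
    )
    agg["cq_sd"] = agg["cq_sd"].fillna(0.0)
    agg["replicate_flag"] = agg["cq_sd"] > REPLICATE_SD_FLAG
    return agg


def rq_table_from_cq(
    cq_table: pd.DataFrame,
    calibration_samples,
    efficiencies: dict | None = None,
) -> pd.DataFrame:
    """Aggregate replicates and convert to raw RQs.

    The anchor for each target is the mean Cq of the calibration samples
    across all their plates; any anchor choice cancels in between-group
    ratios, which is what downstream figures report.
    """
    agg = aggregate_replicates(cq_table)
    efficiencies = efficiencies or {}
    out = []
    for target, grp in agg.groupby("target", sort=True):
        calib = grp[grp["sample_id"].isin(calibration_samples)]
        if calib.empty:
            raise CalibrationError(f"no calibration samples measured for {target!r}")
        anchor = float(calib["cq"].mean())
        eff = efficiencies.get(target, 1.0)
        g = grp.copy()
        g["rq_raw"] = cq_to_rq(g["cq"].to_numpy(), efficiency=eff, anchor_cq=anchor)
        g["anchor_cq"] = anchor
        g["efficiency"] = eff
        out.append(g)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Inter-plate calibration
# ---------------------------------------------------------------------------

def calibrate_plates(rq_table: pd.DataFrame, calibration_samples) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cancel plate-to-plate offsets using the shared calibration samples.

    Per target and plate the correction factor is the geometric mean over
    calibration samples of (consensus RQ / plate RQ), where the consensus is
    the cross-plate geometric mean for that sample.  Multiplying each
    plate's RQs by its factor leaves every calibration sample's cross-plate
    geometric mean unchanged and removes any whole-plate multiplicative
    offset exactly.  Single-plate targets get factor 1.  Idempotent.

    Returns
    -------
    calibrated : DataFrame
        Input plus ``rq_calibrated``.
    factors : DataFrame
        One row per (target, plate_id) with the applied factor.
    """
    if "rq_raw" not in rq_table.columns:
        raise ValueError("expected an RQ table with an 'rq_raw' column")
    calib_ids = list(calibration_samples)
    pieces, factor_rows = [], []
    for target, grp in rq_table.groupby("target", sort=True):
        plates = sorted(grp["plate_id"].unique())
        calib = grp[grp["sample_id"].isin(calib_ids)]
        for plate in plates:
            present = set(calib.loc[calib["plate_id"] == plate, "sample_id"])
            missing = set(calib_ids) - present
            if missing and len(plates) > 1:
                raise CalibrationError(
                    f"calibration sample(s) {sorted(missing)} missing from "
                    f"plate {plate!r} for target {target!r}"
                )
        consensus = calib.groupby("sample_id")["rq_raw"].apply(_geomean)
        factors = {}
        for plate in plates:
            on_plate = calib[calib["plate_id"] == plate]
            if len(plates) == 1:
                factors[plate] = 1.0
            else:
                ratios = consensus.loc[on_plate["sample_id"]].to_numpy() / on_plate[
                    "rq_raw"
                ].to_numpy()
                factors[plate] = _geomean(ratios)
        g = grp.copy()
        g["rq_calibrated"] = g["rq_raw"] * g["plate_id"].map(factors)
        pieces.append(g)
        factor_rows += [
            {"target": target, "plate_id": p, "factor": f} for p, f in factors.items()
        ]
    return pd.concat(pieces, ignore_index=True), pd.DataFrame(factor_rows)


# ---------------------------------------------------------------------------
# Reference normalisation
# ---------------------------------------------------------------------------

def normalize_to_references(
    calibrated: pd.DataFrame,
    reference_targets=DEFAULT_REFERENCES,
) -> pd.DataFrame:
    """Normalise GOI RQs per sample to the geometric mean of the references.

    Calibration samples measured on several plates are first collapsed to
    their cross-plate geometric mean.  A sample missing any reference gene
    is excluded and reported in the ``excluded`` attribute of the result
    (``result.attrs["excluded"]``), never imputed.
    """
    refs = list(reference_targets)
    rq_col = "rq_calibrated" if "rq_calibrated" in calibrated.columns else "rq_raw"
    keep = [c for c in ("group",) if c in calibrated.columns]
    collapsed = (
        calibrated.groupby(["sample_id", "target"] + keep, sort=True)[rq_col]
        .apply(_geomean)
        .reset_index(name="rq")
    )
    wide = collapsed.pivot_table(index="sample_id", columns="target", values="rq")
    excluded = [
        s for s in wide.index if any(t not in wide.columns or pd.isna(wide.loc[s, t]) for t in refs)
    ]
    rows = []
    for _, rec in collapsed.iterrows():
        if rec["sample_id"] in excluded or rec["target"] in refs:
            continue
        ref_geomean = _geomean([wide.loc[rec["sample_id"], t] for t in refs])
        row = dict(rec)
        row["rq_normalised"] = rec["rq"] / ref_geomean
        row["ref_geomean"] = ref_geomean
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    out.attrs["reference_targets"] = refs
    return out


def group_fold_change(normalised: pd.DataFrame, groups=("WT", "DE50MD")) -> pd.Series:
    """Geometric-mean RQ ratio (group 2 / group 1) per target."""
    gm = normalised.groupby(["target", "group"])["rq_normalised"].apply(_geomean).unstack()
    return gm[groups[1]] / gm[groups[0]]


def reference_stability_m(calibrated: pd.DataFrame, reference_targets=DEFAULT_REFERENCES) -> pd.Series:
    """geNorm-style M stability value per reference gene (diagnostic only).

    M is the mean SD of log2 pairwise ratios with the other references;
    lower is more stable.  Reported for QC — the reference trio is fixed by
    design and never auto-swapped.
    """
    refs = list(reference_targets)
    rq_col = "rq_calibrated" if "rq_calibrated" in calibrated.columns else "rq_raw"
    wide = (
        calibrated[calibrated["target"].isin(refs)]
        .groupby(["sample_id", "target"])[rq_col]
        .apply(_geomean)
        .unstack()
    )
    m = {}
    for a in refs:
        sds = [
            np.std(np.log2(wide[a] / wide[b]), ddof=1) for b in refs if b != a
        ]
        m[a] = float(np.mean(sds))
    return pd.Series(m, name="genorm_m")


# ---------------------------------------------------------------------------
# Multi-site dystrophin metrics
# ---------------------------------------------------------------------------

@dataclass
class DystrophinPanel:
    """Per-sample multi-site dystrophin transcript metrics."""

    sample_id: str
    rq_ex1_2: float  # total dp427m initiation
    rq_ex44_45: float | None
    rq_ex62_64: float | None
    rq_dp71: float | None
    mid_fraction: float | None  # ex44_45 / ex1_2
    maturity_fraction: float | None  # ex62_64 / ex1_2
    log10_dp71: float | None = None


DYSTROPHIN_TARGETS = {
    "ex1_2": "DMD_ex1-2",
    "ex44_45": "DMD_ex44-45",
    "ex62_64": "DMD_ex62-64",
    "dp71": "DMD_dp71",
}


def dystrophin_metrics(
    normalised: pd.DataFrame,
    targets: dict | None = None,
) -> list[DystrophinPanel]:
    """Compute transcript-maturity fractions along the dystrophin gene.

    ``mid_fraction`` (exon 44–45 over exon 1–2) and ``maturity_fraction``
    (exon 62–64 over exon 1–2) track how far along the ~16 h transcription
    unit the transcript pool survives; the mid site is transcribed roughly
    8 h before the 3' site and so is the larger subset in well-behaved
    data.  dp71, driven by an internal promoter, is carried as its own
    normalised RQ with a log10 reporting column.
    """
    t = dict(DYSTROPHIN_TARGETS)
    t.update(targets or {})
    wide = normalised.pivot_table(index="sample_id", columns="target", values="rq_normalised")
    panels = []
    for sid, row in wide.iterrows():
        ex12 = row.get(t["ex1_2"], np.nan)
        if pd.isna(ex12):
            continue
        if ex12 <= 0:
            raise ValueError(f"non-positive exon 1-2 RQ for sample {sid!r}")
        ex4445 = row.get(t["ex44_45"], np.nan)
        ex6264 = row.get(t["ex62_64"], np.nan)
        dp71 = row.get(t["dp71"], np.nan)
        panels.append(
            DystrophinPanel(
                sample_id=str(sid),
                rq_ex1_2=float(ex12),
                rq_ex44_45=None if pd.isna(ex4445) else float(ex4445),
                rq_ex62_64=None if pd.isna(ex6264) else float(ex6264),
                rq_dp71=None if pd.isna(dp71) else float(dp71),
                mid_fraction=None if pd.isna(ex4445) else float(ex4445 / ex12),
                maturity_fraction=None if pd.isna(ex6264) else float(ex6264 / ex12),
                log10_dp71=None if (pd.isna(dp71) or dp71 <= 0) else float(np.log10(dp71)),
            )
        )
    return panels


def log10_transform(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Elementwise log10 of the named columns; NaN propagates as missing.

    A non-positive value is an error naming the offending row, because a
    zero RQ indicates an upstream non-detect that should have been treated
    as missing.
    """
    out = table.copy()
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        bad = np.nonzero(~np.isnan(vals) & (vals <= 0))[0]
        if len(bad):
            raise ValueError(
                f"non-positive value in column {col!r} at row index "
                f"{out.index[bad[0]]!r}: cannot take log10"
            )
        out[f"log10_{col}"] = np.log10(vals)
    return out
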