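"""Sample naming, exclusion handling and report assembly.

Animal identifiers follow the study nomenclature: a genotype prefix (WT or
DE50), a litter letter (alphabetical, skipping 'F'), and an animal number —
``DE50-E4`` and ``WT-E5`` are dystrophic and healthy littermates.  An
optional suffix selects a muscle (three-letter code from the 17-muscle
post-mortem vocabulary) or an age in months (e.g. ``-6m``).

Exclusion handling is asymmetric by design: biopsy-site re-sampling injury
in healthy muscle (iatrogenic injury) mimics regeneration markers, so
flagged samples are removed from qPCR comparisons but retained for
histology, where sections were collected from unaffected regions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, asdict

import pandas as pd

logger = logging.getLogger(__name__)

MUSCLE_CODES = frozenset(
    "CRT VLA CRS CAS SEM SET BFE GRA SGL BIC TRI LAT DIA INT MAS TEM TON".split()
)

_KEY_RE = re.compile(
    r"^(?P<prefix>WT|DE50)-(?P<litter>[A-Z])(?P<number>\d+)"
    r"(?:-(?P<suffix>[A-Z]{3}|\d+m))?$"
)


@dataclass
class SampleKey:
    """Parsed animal/sample identifier."""

    genotype_prefix: str  # "WT" | "DE50"
    litter: str  # single letter, never 'F'
    animal_number: int
    muscle_code: str | None = None
    age_months: int | None = None
    exclusion_flag: str = "none"  # "none" | "iatrogenic_injury"

    @property
    def animal_id(self) -> str:
        return f"{self.genotype_prefix}-{self.litter}{self.animal_number}"


def parse_sample_key(key: str) -> SampleKey:
    """Parse ``PREFIX-L#[-MUSCLE|-AGEm]`` identifiers.

    Litter 'F' is rejected: the letter was never used in litter assignment,
    so its appearance signals a typo.
    """
    if not key:
        raise ValueError("empty sample key")
    m = _KEY_RE.match(key.strip())
    if not m:
        raise ValueError(f"malformed sample key {key!r}")
    litter = m.group("litter")
    if litter == "F":
        raise ValueError(f"invalid litter 'F' in {key!r}: letter F is never assigned")
    muscle, age = None, None
    suffix = m.group("suffix")
    if suffix:
        if suffix.endswith("m"):
            age = int(suffix[:-1])
        else:
            if suffix not in MUSCLE_CODES:
                raise ValueError(
                    f"unknown muscle code {suffix!r} in {key!r} "
                    f"(expected one of {sorted(MUSCLE_CODES)})"
                )
            muscle = suffix
    return SampleKey(
        genotype_prefix=m.group("prefix"),
        litter=litter,
        animal_number=int(m.group("number")),
        muscle_code=muscle,
        age_months=age,
    )


def apply_exclusions(
    dataset: pd.DataFrame,
    exclusion_table: pd.DataFrame,
    mode: str,
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Apply the study's mode-dependent sample exclusions.

    ``mode='qpcr'`` removes flagged samples (iatrogenic injury contaminates
    expression comparisons); ``mode='histology'`` retains them, since
    histology sections come from unaffected regions.  Removed rows are
    logged with reasons; exclusion ids absent from the dataset produce a
    warning, not an error.
    """
    if mode not in ("qpcr", "histology"):
        raise ValueError("mode must be 'qpcr' or 'histology'")
    if exclusion_table is None or exclusion_table.empty:
        return dataset.copy()
    if "sample_id" not in exclusion_table.columns:
        raise ValueError("exclusion table needs a 'sample_id' column")
    flagged = set(exclusion_table["sample_id"])
    present = set(dataset[sample_col])
    missing = flagged - present
    if missing:
        logger.warning("exclusion ids not found in dataset: %s", sorted(missing))
    if mode == "histology":
        logger.info("histology mode: %d flagged samples retained", len(flagged & present))
        return dataset.copy()
    keep = ~dataset[sample_col].isin(flagged)
    removed = dataset.loc[~keep]
    reasons = dict(
        zip(exclusion_table["sample_id"], exclusion_table.get("reason", "flagged"))
    )
    for sid in removed[sample_col].unique():
        logger.info("excluded %s (%s)", sid, reasons.get(sid, "flagged"))
    logger.info("qpcr mode: removed %d of %d rows", (~keep).sum(), len(dataset))
    return dataset.loc[keep].copy()


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance blocks."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def assemble_report(
    stage_outputs: dict[str, pd.DataFrame],
    config: dict | None = None,
    seeds: dict | None = None,
    sample_col: str = "sample_id",
) -> tuple[pd.DataFrame, dict]:
    """Join per-stage per-sample tables into one report keyed on sample id.

    Stages typically come from serial sections of the same biopsy, so an
    outer join on the sample key pairs histology, morphometry and qPCR
    values; a sample present in only some stages keeps its row with the
    other stages' fields missing and is flagged in ``incomplete_stages``.
    Duplicate sample ids within one stage are an error (key collision).

    Returns the merged table and a provenance block (config hash, seeds,
    per-stage row counts).
    """
    if not stage_outputs:
        raise ValueError("need at least one stage output")
    merged = None
    for stage, table in stage_outputs.items():
        if sample_col not in table.columns:
            raise ValueError(f"stage {stage!r} output lacks {sample_col!r}")
        dupes = table[sample_col][table[sample_col].duplicated()].unique()
        if len(dupes):
            raise ValueError(f"stage {stage!r} has duplicate sample ids: {list(dupes)}")
        renamed = table.rename(
            columns={c: f"{stage}_{c}" for c in table.columns if c != sample_col}
        )
        merged = renamed if merged is None else merged.merge(
            renamed, on=sample_col, how="outer"
        )
    merged = merged.sort_values(sample_col).reset_index(drop=True)
    incomplete = []
    for stage, table in stage_outputs.items():
        probe = f"{stage}_{[c for c in table.columns if c != sample_col][0]}"
        incomplete.append(merged[probe].isna())
    merged["incomplete_stages"] = pd.concat(incomplete, axis=1).any(axis=1)
    provenance = {
        "config_hash": config_hash(config or {}),
        "seeds": dict(seeds or {}),
        "stage_rows": {stage: len(t) for stage, t in stage_outputs.items()},
    }
    return merged, provenance
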