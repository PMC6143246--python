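"""Blood-pressure phenotype processing and analysis-table assembly.

Three seated oscillometric readings are taken per participant; the phenotype
is the mean of the last two.  Antihypertensive treatment is corrected by
adding 10 mmHg to mean SBP and 5 mmHg to mean DBP of medicated participants
(a standard additive treatment correction).  A sensitivity mode instead keeps
the uncorrected means and carries medication as a model covariate.

Right-skewed network measures (mean betweenness, mean distance, percent
family, percent central positions family) are square-root transformed before
regression; proportions stay on the [0, 1] scale.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SBP_MED_OFFSET = 10.0
DBP_MED_OFFSET = 5.0
BP_RANGE = (30.0, 300.0)

SQRT_MEASURES = ("mean_betweenness", "mean_distance",
                 "pct_family", "pct_central_family")


class PhenotypeError(ValueError):
    pass


def process_bp(sbp_readings, dbp_readings, medicated: bool):
    """Medication-corrected (SBP, DBP) from three readings each.

    Mean of readings 2 and 3 ("last two" in recorded order); +10/+5 mmHg for
    medicated participants.  Rejects rows with missing or non-physiologic
    (outside 30-300 mmHg) readings.
    """
    for label, readings in (("SBP", sbp_readings), ("DBP", dbp_readings)):
        readings = list(readings)
        if len(readings) != 3:
            raise PhenotypeError(f"{label}: expected 3 readings, got {len(readings)}")
        for r in readings:
            if not np.isfinite(r) or not (BP_RANGE[0] <= r <= BP_RANGE[1]):
                raise PhenotypeError(f"{label}: reading {r} outside {BP_RANGE}")
    sbp = (sbp_readings[1] + sbp_readings[2]) / 2.0
    dbp = (dbp_readings[1] + dbp_readings[2]) / 2.0
    if medicated:
        sbp += SBP_MED_OFFSET
        dbp += DBP_MED_OFFSET
    return float(sbp), float(dbp)


def process_bp_table(participants: pd.DataFrame, correct: bool = True) -> pd.DataFrame:
    """Per-participant processed BP; rows failing validation are dropped.

    Returns columns ``participant_id, sbp, dbp`` (corrected when ``correct``)
    with an ``attrs["exclusions"]`` list of (participant_id, reason).
    """
    rows, exclusions = [], []
    for r in participants.itertuples(index=False):
        try:
            sbp, dbp = process_bp(
                (r.sbp1, r.sbp2, r.sbp3), (r.dbp1, r.dbp2, r.dbp3),
                bool(r.medicated) if correct else False)
        except PhenotypeError as exc:
            exclusions.append((r.participant_id, str(exc)))
            continue
        rows.append({"participant_id": r.participant_id, "sbp": sbp, "dbp": dbp})
    out = pd.DataFrame(rows, columns=["participant_id", "sbp", "dbp"])
    out.attrs["exclusions"] = exclusions
    if exclusions:
        logger.info("process_bp_table: rejected %d rows", len(exclusions))
    return out


def transform_for_model(measures: pd.DataFrame) -> pd.DataFrame:
    """Square-root transform the four network measures; other columns pass.

    Column names gain a ``sqrt_`` prefix so a transformed table cannot be
    transformed twice by accident.
    """
    out = measures.copy()
    for col in SQRT_MEASURES:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise PhenotypeError(f"{col}: negative value, cannot square-root")
        out[f"sqrt_{col}"] = np.sqrt(vals)
        out = out.drop(columns=[col])
    out.attrs["transformed"] = True
    return out


def assemble_analysis_table(participants: pd.DataFrame, measures: pd.DataFrame,
                            codings: pd.DataFrame,
                            med_mode: str = "corrected") -> pd.DataFrame:
    """Inner-join participants, transformed network measures and haplotype
    codings into the model-ready table; complete cases only.

    ``med_mode="corrected"`` (default) uses +10/+5-corrected BP;
    ``"covariate"`` keeps the raw means and adds ``medicated`` as a model
    column.  Exclusions are counted by reason in ``attrs["exclusions"]``.
    """
    if med_mode not in ("corrected", "covariate"):
        raise ValueError(f"unknown med_mode {med_mode!r}")
    for name, tbl in (("participants", participants), ("measures", measures),
                      ("codings", codings)):
        if tbl["participant_id"].duplicated().any():
            dup = tbl.loc[tbl["participant_id"].duplicated(), "participant_id"].iloc[0]
            raise PhenotypeError(f"{name}: duplicate participant_id {dup!r}")

    bp = process_bp_table(participants, correct=(med_mode == "corrected"))
    exclusions = {"bp_invalid": len(bp.attrs["exclusions"])}

    cov_cols = ["participant_id", "age", "sex", "bmi", "medicated"]
    tbl = participants[cov_cols].merge(bp, on="participant_id", how="inner")

    if not measures.attrs.get("transformed"):
        measures = transform_for_model(measures)
    meas_cols = ["participant_id"] + [f"sqrt_{c}" for c in SQRT_MEASURES
                                      if f"sqrt_{c}" in measures.columns]
    n_before = len(tbl)
    tbl = tbl.merge(measures[meas_cols], on="participant_id", how="inner")
    exclusions["no_network"] = n_before - len(tbl)

    code_cols = ["participant_id"] + [c for c in codings.columns
                                      if c.startswith("dosage_") or c == "group"]
    n_before = len(tbl)
    tbl = tbl.merge(codings[code_cols], on="participant_id", how="inner")
    exclusions["no_genotype"] = n_before - len(tbl)

    n_before = len(tbl)
    model_cols = [c for c in tbl.columns if c not in ("participant_id", "group")]
    tbl = tbl.dropna(subset=model_cols)
    exclusions["incomplete"] = n_before - len(tbl)

    if med_mode == "corrected":
        tbl = tbl.drop(columns=["medicated"])
    tbl = tbl.sort_values("participant_id", kind="stable").reset_index(drop=True)
    tbl.attrs["exclusions"] = exclusions
    tbl.attrs["med_mode"] = med_mode
    logger.info("analysis table: %d rows (%s)", len(tbl), exclusions)
    return tbl
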