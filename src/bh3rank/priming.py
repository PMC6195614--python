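"""Percent apoptotic priming from plate-reader fluorescence.

BH3 profiling reads mitochondrial depolarization (loss of ψm) as a JC-1
fluorescence decrease. Each sample carries a solvent-only control (DMSO,
defining 0% depolarization) and an uncoupler positive control (FCCP,
defining 100%). Percent priming for a drug condition is the linear
interpolation of its replicate-mean fluorescence between those anchors:

    priming(i, j) = 100 · (F̄_DMSO(i) − F̄_j(i)) / (F̄_DMSO(i) − F̄_FCCP(i))

then clamped to [0, 100]. Clamping events are counted, not hidden: replicate
noise routinely pushes conditions slightly past the anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DMSO = "DMSO"
FCCP = "FCCP"
CONTROL_CONDITIONS = (DMSO, FCCP)


class PlateError(ValueError):
    """Invalid plate layout (missing controls, bad RFU, duplicate replicates)."""


class ControlInversionError(PlateError):
    """F̄_DMSO ≤ F̄_FCCP for a sample: depolarization polarity violated."""


@dataclass
class FluorescencePlate:
    """Well-level fluorescence readings.

    ``wells`` columns: ``sample_id``, ``condition`` (drug name, DMSO or FCCP),
    ``replicate`` (int), ``rfu`` (relative fluorescence units, ≥ 0).
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate", "rfu"}
        missing = required - set(self.wells.columns)
        if missing:
            raise PlateError(f"plate table missing columns {sorted(missing)}")
        w = self.wells
        if (w["rfu"].to_numpy(dtype=float) < 0).any():
            bad = w.loc[w["rfu"] < 0, "sample_id"].iloc[0]
            raise PlateError(f"negative rfu for sample {bad!r}")
        dup = w.duplicated(subset=["sample_id", "condition", "replicate"])
        if dup.any():
            bad = w.loc[dup, ["sample_id", "condition", "replicate"]].iloc[0]
            raise PlateError(
                "duplicate replicate index: "
                f"sample {bad['sample_id']!r}, condition {bad['condition']!r}, "
                f"replicate {bad['replicate']}"
            )
        conds = w.groupby("sample_id")["condition"].agg(set)
        for sid, cset in conds.items():
            if cset - set(CONTROL_CONDITIONS):  # has at least one drug well
                for ctrl in CONTROL_CONDITIONS:
                    if ctrl not in cset:
                        raise PlateError(
                            f"sample {sid!r} has drug wells but no {ctrl} control wells"
                        )

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.wells["sample_id"]))

    @property
    def drug_ids(self) -> list[str]:
        conds = pd.unique(self.wells["condition"])
        return [c for c in conds if c not in CONTROL_CONDITIONS]

    def condition_means(self) -> pd.DataFrame:
        """Replicate-mean RFU per (sample, condition)."""
        return (
            self.wells.groupby(["sample_id", "condition"], sort=False)["rfu"]
            .mean()
            .unstack("condition")
        )


@dataclass
class PrimingMatrix:
    """Tumor × drug percent apoptotic priming with replicate QC."""

    priming: pd.DataFrame       # % priming, clamped to [0, 100]
    replicate_cv: pd.DataFrame  # CV (sample SD / mean) of raw drug-well RFU
    clamped: pd.DataFrame       # bool mask of clamped cells
    n_clamped: int

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.priming.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.priming.columns)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for sid in self.priming.index:
            for drug in self.priming.columns:
                rows.append(
                    {
                        "sample_id": sid,
                        "drug": drug,
                        "priming": self.priming.at[sid, drug],
                        "replicate_cv": self.replicate_cv.at[sid, drug],
                        "clamped": bool(self.clamped.at[sid, drug]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PlateQC:
    """Reporting-only plate quality summary."""

    control_separation: pd.Series  # F̄_DMSO − F̄_FCCP per sample
    replicate_cv: pd.DataFrame
    n_clamped: int
    flagged: list[tuple[str, str]]  # (sample, drug) pairs with CV above limit
    cv_limit: float


def read_plate(path) -> FluorescencePlate:
    """Read a ``plate.csv`` file (``sample_id,condition,replicate,rfu``)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "condition": str})
    try:
        df["replicate"] = df["replicate"].astype(int)
        df["rfu"] = df["rfu"].astype(float)
    except (ValueError, KeyError) as exc:
        raise PlateError(f"{path}: malformed plate table ({exc})") from exc
    return FluorescencePlate(wells=df)


def write_plate(plate: FluorescencePlate, path) -> None:
    plate.wells.to_csv(path, index=False)


def percent_priming(plate: FluorescencePlate) -> PrimingMatrix:
    """Normalize drug-well fluorescence to the DMSO (0%) / FCCP (100%) anchors.

    By construction the DMSO condition maps to 0% and FCCP to 100%; the
    normalization is invariant to any positive affine rescaling of a
    sample's RFU values (plate-reader gain cancels).
    """
    means = plate.condition_means()
    drugs = plate.drug_ids
    samples = [s for s in plate.sample_ids if s in means.index]
    priming = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample_id"), columns=drugs)
    cv = pd.DataFrame(np.nan, index=priming.index, columns=drugs)
    grouped = plate.wells.groupby(["sample_id", "condition"], sort=False)["rfu"]
    sd = grouped.std(ddof=1).unstack("condition")
    for sid in samples:
        f_dmso = means.at[sid, DMSO] if DMSO in means.columns else np.nan
        f_fccp = means.at[sid, FCCP] if FCCP in means.columns else np.nan
        row_has_drug = any(pd.notna(means.at[sid, d]) for d in drugs if d in means.columns)
        if not row_has_drug:
            continue
        if not (pd.notna(f_dmso) and pd.notna(f_fccp)):
            raise PlateError(f"sample {sid!r} lacks control means")
        if f_dmso <= f_fccp:
            raise ControlInversionError(
                f"sample {sid!r}: F̄_DMSO ({f_dmso:g}) ≤ F̄_FCCP ({f_fccp:g})"
            )
        span = f_dmso - f_fccp
        for drug in drugs:
            if drug not in means.columns or pd.isna(means.at[sid, drug]):
                continue
            priming.at[sid, drug] = 100.0 * (f_dmso - means.at[sid, drug]) / span
            s = sd.at[sid, drug] if drug in sd.columns else np.nan
            m = means.at[sid, drug]
            cv.at[sid, drug] = (s / m) if (pd.notna(s) and m != 0) else np.nan
    defined = priming.notna()
    clamped = defined & ((priming < 0.0) | (priming > 100.0))
    priming = priming.clip(lower=0.0, upper=100.0)
    return PrimingMatrix(
        priming=priming,
        replicate_cv=cv,
        clamped=clamped,
        n_clamped=int(clamped.to_numpy().sum()),
    )


def qc_plate(plate: FluorescencePlate, cv_limit: float = 0.20) -> PlateQC:
    """Per-sample control separation, replicate CVs and clamp counts.

    Flags (sample, drug) pairs whose replicate CV exceeds ``cv_limit``.
    Reporting only: nothing is rejected here.
    """
    pm = percent_priming(plate)
    means = plate.condition_means()
    sep = pd.Series(np.nan, index=pm.priming.index, name="control_separation")
    for sid in sep.index:
        if DMSO in means.columns and FCCP in means.columns:
            sep[sid] = means.at[sid, DMSO] - means.at[sid, FCCP]
    flagged = [
        (sid, drug)
        for sid in pm.replicate_cv.index
        for drug in pm.replicate_cv.columns
        if pd.notna(pm.replicate_cv.at[sid, drug])
        and pm.replicate_cv.at[sid, drug] > cv_limit
    ]
    return PlateQC(
        control_separation=sep,
        replicate_cv=pm.replicate_cv,
        n_clamped=pm.n_clamped,
        flagged=flagged,
        cv_limit=float(cv_limit),
    )
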