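"""Synthetic tumor cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes for an
oral squamous cell carcinoma cohort profiled on a qPCR drug-resistance array
and by BH3 profiling: a single latent per-tumor resistance score drives
multidrug-resistance gene expression up (Ct down) and apoptotic priming
down, drugs differ by a mean priming offset (a taxane-like drug highest),
one gender carries an additive latent-score shift, and tumors fall into
three planted response classes (sensitive / moderate / resistant) given by
increasing latent-score class means.

The fluorescence plate is produced by inverting the priming normalization
contract: drug-well RFU is placed linearly between the DMSO and FCCP control
levels so that percent_priming recovers the generated true priming exactly
when well noise is zero, and up to replicate noise otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .priming import DMSO, FCCP, FluorescencePlate, write_plate
from .qpcr import CtTable, write_ct_table

GENES = (
    "ABCB1", "ABCC1", "ABCC2", "ABCC3", "ABCC5", "ABCG2",
    "TP53", "STAT5B", "LRP1", "CDKN1A", "CDK2",
)
DRUGS = ("paclitaxel", "vinblastine", "daunorubicin", "doxorubicin", "vincristine")

#: study-condition drug mean primings (%): taxane ~40–45, vincas/anthracyclines below
DEFAULT_DRUG_MEAN_PRIMING = {
    "paclitaxel": 42.5,
    "vinblastine": 37.5,
    "daunorubicin": 37.5,
    "doxorubicin": 32.5,
    "vincristine": 32.5,
}

#: per-gene baseline Ct (cycles) for an average tumor; reference gene high-abundance
DEFAULT_BASELINE_CT = {
    "ABCB1": 27.0, "ABCC1": 25.0, "ABCC2": 26.0, "ABCC3": 25.5, "ABCC5": 24.5,
    "ABCG2": 28.0, "TP53": 23.0, "STAT5B": 24.0, "LRP1": 26.5, "CDKN1A": 22.5,
    "CDK2": 23.5, "GAPDH": 18.0,
}

CLASS_NAMES = ("sensitive", "moderate", "resistant")


class ParameterError(ValueError):
    """Invalid cohort parameters."""


@dataclass
class CohortParams:
    """Generator parameters; defaults are the emulated study conditions
    (31 tumors, 11 target genes + GAPDH reference, 5 drugs)."""

    n_tumors: int = 31
    n_normals: int = 3
    genes: tuple[str, ...] = GENES
    reference_gene: str = "GAPDH"
    protective_genes: tuple[str, ...] = ("TP53",)
    drugs: tuple[str, ...] = DRUGS
    drug_mean_priming: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_MEAN_PRIMING)
    )
    baseline_ct: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_CT)
    )
    resistance_effect_ct: float = 1.0      # Ct decrease (cycles) per unit latent score
    resistance_effect_priming: float = 10.0  # priming decrease (pp) per unit latent score
    ct_noise_sd: float = 0.5               # cycles
    priming_noise_sd: float = 5.0          # percentage points
    rfu_noise_cv: float = 0.02             # well-level replicate noise (fraction of RFU)
    class_proportions: tuple[float, float, float] = (13 / 31, 16 / 31, 2 / 31)
    class_score_means: tuple[float, float, float] = (-3.0, 0.0, 3.0)
    gender_effect: float = 0.5             # additive latent shift for male tumors
    dmso_rfu: float = 1000.0               # control fluorescence levels (arbitrary units)
    fccp_rfu: float = 200.0
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 1:
            raise ParameterError("n_tumors must be >= 1")
        if self.n_normals < 1:
            raise ParameterError("n_normals must be >= 1 (ΔΔCt needs a control)")
        if len(self.genes) < 1:
            raise ParameterError("need at least one target gene")
        if self.reference_gene in self.genes:
            raise ParameterError("reference gene must be distinct from target genes")
        if not self.drugs:
            raise ParameterError("drugs must be nonempty")
        missing = set(self.drugs) - set(self.drug_mean_priming)
        if missing:
            raise ParameterError(f"drug_mean_priming missing drugs {sorted(missing)}")
        for d, m in self.drug_mean_priming.items():
            if not 0.0 <= m <= 100.0:
                raise ParameterError(f"drug_mean_priming[{d!r}]={m} outside [0, 100]")
        for name in ("resistance_effect_ct", "resistance_effect_priming",
                     "ct_noise_sd", "priming_noise_sd", "rfu_noise_cv"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size != 3 or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ParameterError("class_proportions must be 3 nonnegative fractions summing to 1")
        means = np.asarray(self.class_score_means, dtype=float)
        if means.size != 3 or not (np.diff(means) > 0).all():
            raise ParameterError("class_score_means must be 3 strictly increasing values")
        if self.dmso_rfu <= self.fccp_rfu:
            raise ParameterError("dmso_rfu must exceed fccp_rfu (polarity of JC-1 signal)")
        if self.n_replicates < 3:
            raise ParameterError("need at least 3 replicate wells per condition")
        missing_base = ({self.reference_gene, *self.genes}) - set(self.baseline_ct)
        if missing_base:
            raise ParameterError(f"baseline_ct missing genes {sorted(missing_base)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes"] = list(self.genes)
        d["drugs"] = list(self.drugs)
        d["protective_genes"] = list(self.protective_genes)
        d["class_proportions"] = list(self.class_proportions)
        d["class_score_means"] = list(self.class_score_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortParams":
        kwargs = dict(d)
        for k in ("genes", "drugs", "protective_genes", "class_proportions", "class_score_means"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class SyntheticCohort:
    """A generated cohort: inputs for the pipeline plus ground truth."""

    params: CohortParams
    ct_table: CtTable
    plate: FluorescencePlate
    true_priming: pd.DataFrame    # tumor × drug, before plate noise
    true_scores: pd.Series        # latent resistance score per tumor
    true_classes: pd.Series       # planted label per tumor

    def __post_init__(self) -> None:
        tumors = set(self.ct_table.tumor_ids)
        plate_ids = set(self.plate.sample_ids)
        if tumors != plate_ids:
            raise ValueError("ct_table and plate must cover exactly the same tumor ids")


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Draw a reproducible synthetic cohort from a single seeded stream.

    Latent score: s_i ~ Normal(class mean, 1) + gender_effect·[male].
    Ct(i, g) = baseline_g − resistance_effect_ct·s_i·loading_g + ε, with
    loading +1 for resistance genes, −1 for protective genes (they are
    higher-expressed in sensitive tumors) and 0 for the reference gene.
    True priming: clamp(drug mean − resistance_effect_priming·s_i + ε, 0, 100).
    Wells invert the DMSO/FCCP normalization around the control levels.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    tumor_ids = [f"T{i+1:02d}" for i in range(params.n_tumors)]
    normal_ids = [f"N{i+1:02d}" for i in range(params.n_normals)]

    class_idx = rng.choice(3, size=params.n_tumors, p=np.asarray(params.class_proportions))
    classes = pd.Series([CLASS_NAMES[c] for c in class_idx], index=tumor_ids, name="class")
    gender = rng.choice(["male", "female"], size=params.n_tumors)
    scores = (
        np.asarray(params.class_score_means)[class_idx]
        + rng.normal(0.0, 1.0, size=params.n_tumors)
        + params.gender_effect * (gender == "male")
    )
    scores = pd.Series(scores, index=tumor_ids, name="score")

    all_genes = [*params.genes, params.reference_gene]
    loading = {g: (-1.0 if g in params.protective_genes else 1.0) for g in params.genes}
    loading[params.reference_gene] = 0.0
    ct = pd.DataFrame(index=pd.Index(tumor_ids + normal_ids, name="sample_id"),
                      columns=all_genes, dtype=float)
    for g in all_genes:
        base = params.baseline_ct[g]
        ct.loc[tumor_ids, g] = (
            base
            - params.resistance_effect_ct * scores.to_numpy() * loading[g]
            + rng.normal(0.0, params.ct_noise_sd, size=params.n_tumors)
        )
        ct.loc[normal_ids, g] = base + rng.normal(0.0, params.ct_noise_sd, size=params.n_normals)
    ct = ct.clip(lower=1.0, upper=45.0)

    roles = pd.Series(
        ["tumor"] * params.n_tumors + ["normal"] * params.n_normals,
        index=ct.index, name="role",
    )
    grade = rng.choice(["well", "moderate", "poor"], size=params.n_tumors)
    metadata = pd.DataFrame(
        {
            "gender": list(gender) + ["female"] * params.n_normals,
            "grade": list(grade) + ["normal"] * params.n_normals,
        },
        index=ct.index,
    )
    ct_table = CtTable(ct=ct, roles=roles,
                       reference_genes=(params.reference_gene,), metadata=metadata)

    mean_vec = np.asarray([params.drug_mean_priming[d] for d in params.drugs])
    prim = (
        mean_vec[None, :]
        - params.resistance_effect_priming * scores.to_numpy()[:, None]
        + rng.normal(0.0, params.priming_noise_sd, size=(params.n_tumors, len(params.drugs)))
    )
    prim = np.clip(prim, 0.0, 100.0)
    true_priming = pd.DataFrame(prim, index=pd.Index(tumor_ids, name="sample_id"),
                                columns=list(params.drugs))

    span = params.dmso_rfu - params.fccp_rfu
    rows = []
    for i, sid in enumerate(tumor_ids):
        for cond, target in (
            (DMSO, params.dmso_rfu),
            (FCCP, params.fccp_rfu),
            *[(d, params.dmso_rfu - prim[i, j] / 100.0 * span)
              for j, d in enumerate(params.drugs)],
        ):
            for rep in range(1, params.n_replicates + 1):
                rfu = target * (1.0 + rng.normal(0.0, params.rfu_noise_cv))
                rows.append((sid, cond, rep, max(rfu, 0.0)))
    plate = FluorescencePlate(
        wells=pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "rfu"])
    )

    return SyntheticCohort(
        params=params,
        ct_table=ct_table,
        plate=plate,
        true_priming=true_priming,
        true_scores=scores,
        true_classes=classes,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write ``ct_table.csv``, ``plate.csv`` and ``truth.json``; reading the
    CSVs back through the pipeline readers reproduces the values exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct_table": directory / "ct_table.csv",
        "plate": directory / "plate.csv",
        "truth": directory / "truth.json",
    }
    write_ct_table(cohort.ct_table, paths["ct_table"])
    write_plate(cohort.plate, paths["plate"])
    truth = {
        "seed": cohort.params.seed,
        "params": cohort.params.to_dict(),
        "true_scores": {k: float(v) for k, v in cohort.true_scores.items()},
        "true_classes": dict(cohort.true_classes.items()),
        "true_priming": {
            sid: {d: float(cohort.true_priming.at[sid, d]) for d in cohort.true_priming.columns}
            for sid in cohort.true_priming.index
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
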