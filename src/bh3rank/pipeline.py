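"""End-to-end pipeline: read (or synthesize) → express → prime → rank →
classify → report, with deterministic, config-stamped outputs.

Every output carries the SHA-256 hash of the canonical config and the seed;
identical config + inputs yield byte-identical ``report.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as cls
from .cohort import CohortParams, generate_cohort, write_cohort
from .priming import percent_priming, qc_plate, read_plate
from .qpcr import call_overexpressed, delta_delta_ct, quartile_classes, read_ct_table
from .ranking import rank_drugs

logger = logging.getLogger("bh3rank")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str
    ct_path: str | None = None
    plate_path: str | None = None
    synthesize: dict | None = None        # CohortParams fields
    reference_genes: tuple[str, ...] = ("GAPDH",)
    fold_threshold: float = 2.0
    quartile_gene: str | None = "ABCB1"
    quartile_boundaries: tuple[float, ...] | None = None
    classification_method: str = "both"   # "threshold" | "pam" | "both"
    k: int = 3
    cuts: tuple[float, float] | None = None
    group_by: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = self.ct_path is not None or self.plate_path is not None
        has_synth = self.synthesize is not None
        if has_paths and has_synth:
            raise ConfigError("config must give either input paths or a synthesize block, not both")
        if not has_synth and (self.ct_path is None or self.plate_path is None):
            raise ConfigError("config must give both ct_path and plate_path, or a synthesize block")
        if self.classification_method not in ("threshold", "pam", "both"):
            raise ConfigError(f"unknown classification method {self.classification_method!r}")
        out = Path(self.out_dir).resolve()
        for p in (self.ct_path, self.plate_path):
            if p is not None and Path(p).resolve().parent == out:
                raise ConfigError("output directory must be distinct from the input directory")

    def canonical(self) -> str:
        d = {
            "ct_path": self.ct_path,
            "plate_path": self.plate_path,
            "synthesize": self.synthesize,
            "reference_genes": list(self.reference_genes),
            "fold_threshold": self.fold_threshold,
            "quartile_gene": self.quartile_gene,
            "quartile_boundaries": list(self.quartile_boundaries) if self.quartile_boundaries else None,
            "classification_method": self.classification_method,
            "k": self.k,
            "cuts": list(self.cuts) if self.cuts else None,
            "group_by": self.group_by,
            "seed": self.seed,
        }
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        for k in ("reference_genes", "quartile_boundaries", "cuts"):
            if raw.get(k) is not None:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle into ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json``). On any
    stage failure, partially written outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        stage = "input"
        if config.synthesize is not None:
            params_dict = dict(config.synthesize)
            params_dict.setdefault("seed", config.seed)
            params = CohortParams.from_dict(params_dict)
            cohort = generate_cohort(params)
            cohort_dir = out / "cohort"
            paths = write_cohort(cohort, cohort_dir)
            written.extend(paths.values())
            ct_table = cohort.ct_table
            plate = cohort.plate
            logger.info("input: synthesized cohort with %d tumors, %d genes, %d drugs",
                        params.n_tumors, len(params.genes), len(params.drugs))
        else:
            ct_table = read_ct_table(config.ct_path, reference_genes=config.reference_genes)
            plate = read_plate(config.plate_path)
            logger.info("input: read %d samples, %d plate wells",
                        len(ct_table.sample_ids), len(plate.wells))

        # -------------------------------------------------------- expression
        stage = "expression"
        expr = delta_delta_ct(ct_table)
        p = out / "expression.csv"
        expr.to_long().to_csv(p, index=False)
        written.append(p)
        logger.info("expression: %d samples x %d genes", *expr.ddct.shape)

        # ----------------------------------------------------------- priming
        stage = "priming"
        pm = percent_priming(plate)
        qc = qc_plate(plate)
        p = out / "priming.csv"
        pm.to_long().to_csv(p, index=False)
        written.append(p)
        logger.info("priming: %d tumors x %d drugs, %d clamped, %d CV-flagged",
                    *pm.priming.shape, pm.n_clamped, len(qc.flagged))

        # ----------------------------------------------------------- ranking
        stage = "ranking"
        ranking = rank_drugs(pm.priming)
        p = out / "ranking.csv"
        ranking.to_long(pm.priming).to_csv(p, index=False)
        written.append(p)
        summary = {
            "avg_rd": {d: ranking.avg_rd[d] for d in ranking.drug_ids},
            "conditional_rd": {
                ref: {d: (None if pd.isna(v) else float(v))
                      for d, v in ranking.conditional_rd[ref].items()}
                for ref in ranking.drug_ids
            },
            "bpd_frequency": {d: ranking.bpd_frequency[d] for d in ranking.drug_ids},
            "effective_n": {d: int(ranking.effective_n[d]) for d in ranking.drug_ids},
            "excluded_tumors": list(ranking.excluded_tumors),
        }
        p = out / "ranking_summary.json"
        p.write_text(json.dumps(_round_floats(summary), indent=2, sort_keys=True))
        written.append(p)
        logger.info("ranking: modal BPD %s", ranking.bpd_frequency.idxmax())

        # ------------------------------------------------------- correlation
        stage = "correlation"
        corr = cls.gene_drug_correlation(expr, pm)
        frames = [corr.to_long()]
        if config.group_by and ct_table.metadata is not None:
            strata = cls.gene_drug_correlation(
                expr, pm, metadata=ct_table.metadata, group_by=config.group_by
            )
            frames.extend(cm.to_long() for cm in strata.values())
        p = out / "correlations.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        written.append(p)
        logger.info("correlation: %d gene x drug pairs", corr.r.size)

        # --------------------------------------------------------- quartiles
        stage = "quartiles"
        if config.quartile_gene is not None:
            qb = quartile_classes(ct_table, config.quartile_gene, config.quartile_boundaries)
            qdf = pd.DataFrame(
                {
                    "sample_id": qb.assignment.index,
                    "gene": config.quartile_gene,
                    "quartile": qb.assignment.to_numpy(),
                    "predicted_class": qb.predicted_class.to_numpy(),
                }
            )
            p = out / "quartiles.csv"
            qdf.to_csv(p, index=False)
            written.append(p)
            logger.info("quartiles: %s counts %s", config.quartile_gene,
                        qb.counts().to_dict())

        # ---------------------------------------------------- classification
        stage = "classification"
        frames = []
        class_counts: dict[str, dict[str, int]] = {}
        scores = cls.tumor_response_score(expr, pm)
        if config.classification_method in ("threshold", "both"):
            cuts = config.cuts or (None, None)
            tc = cls.classify_threshold(scores, *cuts)
            frames.append(tc.to_frame().reset_index())
            class_counts["threshold"] = {k: int(v) for k, v in tc.counts().items()}
        pam_info = None
        if config.classification_method in ("pam", "both"):
            feats = cls.pam_features(ct_table, pm)
            tc = cls.pam_cluster(feats, k=config.k)
            frames.append(tc.to_frame().reset_index())
            class_counts["pam"] = {k: int(v) for k, v in tc.counts().items()}
            pam_info = {
                "medoids": list(tc.medoids),
                "cost": tc.cluster_cost,
                "n_swaps": tc.extras["n_swaps"],
                "k": config.k,
            }
            p = out / "pam.json"
            p.write_text(json.dumps(_round_floats(pam_info), indent=2, sort_keys=True))
            written.append(p)
        p = out / "classification.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        written.append(p)
        logger.info("classification: %s", class_counts)

        # ------------------------------------------------------------ report
        stage = "report"
        calls = call_overexpressed(expr, config.fold_threshold)
        overexpr_counts = {
            g: sum(1 for s in calls.calls.values() if g in s) for g in calls.genes
        }
        report = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_tumors": len(pm.tumor_ids),
            "n_genes": len(expr.gene_ids),
            "n_drugs": len(pm.drug_ids),
            "bpd_frequency": summary["bpd_frequency"],
            "avg_rd": summary["avg_rd"],
            "class_counts": class_counts,
            "overexpressed_counts": overexpr_counts,
            "n_clamped_priming": pm.n_clamped,
            "pam": pam_info,
        }
        p = out / "report.json"
        p.write_text(json.dumps(_round_floats(report), indent=2, sort_keys=True))
        written.append(p)
        logger.info("report: written to %s", p)
        return report
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
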