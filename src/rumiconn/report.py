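"""Pipeline orchestration: simulate/load -> CPM -> anatomy -> mediation -> report.

One :class:`RunConfig` drives the whole workflow and every source of
randomness, so a config reproduces its report bit-for-bit (timestamps
aside).  The report is versioned JSON; tables are TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import anatomy as anat
from .cpm import CohortEdgeTable, permutation_test, run_kfold, run_loocv
from .io import Parcellation, SubjectTable, load_cohort_matrices, load_parcellation, load_subject_table
from .mediation import bootstrap_indirect
from .synthetic import SyntheticConfig, generate_cohort, generate_null_cohort, synthetic_parcellation

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

__all__ = ["RunConfig", "correlate_behaviors", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips losslessly through YAML/TOML."""

    # input mode A: files on disk
    subjects: str | None = None
    matrices: str | None = None        # path to a matrix manifest TSV
    parcellation: str | None = None
    # input mode B: simulate a cohort in memory
    simulate: dict | None = None       # SyntheticConfig fields
    simulate_null: bool = False
    # analysis settings
    alpha: float = 0.01
    cv: str = "loocv"                  # "loocv" | "kfold"
    k: int = 10
    repeats: int = 100
    n_perm: int = 1000
    n_boot: int = 5000
    seed: int = 0
    covariates: tuple[str, ...] = ()
    top_k_nodes: int = 10
    out_dir: str = "rumiconn_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            raw = yaml.safe_load(path.read_text())
        elif path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    def content_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def correlate_behaviors(table: SubjectTable) -> tuple[float, float]:
    """Pearson r (and two-tailed p) between rejection and rumination."""
    rej = table.data["rejection"].to_numpy(dtype=float)
    rum = table.data["rumination"].to_numpy(dtype=float)
    if rej.size < 4:
        raise ValueError("need at least 4 subjects")
    if np.var(rej) == 0.0 or np.var(rum) == 0.0:
        raise ValueError("behavioral scores have zero variance")
    res = stats.pearsonr(rej, rum)
    return float(res.statistic), float(res.pvalue)


def _load_inputs(cfg: RunConfig):
    if cfg.simulate is not None:
        sim = SyntheticConfig(**{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)})
        gen = generate_null_cohort if cfg.simulate_null else generate_cohort
        cohort = gen(sim)
        parc = synthetic_parcellation(sim.n_rois)
        return cohort.fc, cohort.table, parc, cohort.truth
    if not (cfg.subjects and cfg.matrices and cfg.parcellation):
        raise ValueError(
            "config must provide either a 'simulate' block or the three input "
            "paths 'subjects', 'matrices' and 'parcellation'"
        )
    matrices = load_cohort_matrices(cfg.matrices)
    table = load_subject_table(cfg.subjects)
    parc = load_parcellation(cfg.parcellation)
    return matrices, table, parc, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full workflow and write the report bundle to ``cfg.out_dir``.

    Stages: behavior correlation; cross-validated CPM for both network signs
    with permutation inference; anatomical decomposition of the consensus
    networks; mediation of rejection -> network strength -> rumination, where
    the mediator is each subject's summed FC over the consensus negative
    network from the selected CV scheme.

    Writes ``report.json``, ``predictions.tsv``,
    ``edges_consensus_{pos,neg}.tsv``, ``pair_counts.tsv``,
    ``node_strength.tsv`` and ``mediation.json``.
    """
    try:
        return _run_pipeline(cfg)
    except Exception as exc:  # annotate which stage died, then re-raise
        logger.error("pipeline aborted: %s", exc)
        raise


def _stage(name: str):
    logger.info("stage: %s", name)


def _run_pipeline(cfg: RunConfig) -> dict:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    _stage("load inputs")
    matrices, table, parc, truth = _load_inputs(cfg)
    tbl = CohortEdgeTable.from_matrices(matrices, table, covariate_columns=cfg.covariates)

    _stage("behavior correlation")
    behav_r, behav_p = correlate_behaviors(table)

    _stage(f"CPM ({cfg.cv})")
    if cfg.cv == "loocv":
        cv_results = run_loocv(tbl, alpha=cfg.alpha)
    elif cfg.cv == "kfold":
        cv_results = run_kfold(tbl, k=cfg.k, repeats=cfg.repeats,
                               alpha=cfg.alpha, seed=cfg.seed)
    else:
        raise ValueError(f"unknown cv scheme {cfg.cv!r}")

    _stage("permutation test")
    perm = permutation_test(
        tbl, cv=cfg.cv, n_perm=cfg.n_perm, seed=cfg.seed,
        alpha=cfg.alpha, k=cfg.k, repeats=cfg.repeats,
    )

    _stage("network anatomy")
    anatomy_out = {}
    for sign, short in (("positive", "pos"), ("negative", "neg")):
        res = cv_results[sign]
        pc = anat.pair_counts(res.consensus_mask, parc)
        ns = anat.node_strengths(res.consensus_mask, res.mean_training_r, parc)
        anatomy_out[sign] = {
            "n_edges": res.n_consensus_edges,
            "top_pairs": pc.ranked.head(5).to_dict(orient="records"),
            "top_nodes": anat.top_nodes(ns, cfg.top_k_nodes).to_dict(orient="records"),
        }
        if sign == "negative":
            pc.ranked.to_csv(out_dir / "pair_counts.tsv", sep="\t", index=False)
            ns.to_csv(out_dir / "node_strength.tsv", sep="\t", index=False)
        _write_consensus_edges(out_dir / f"edges_consensus_{short}.tsv", res, tbl)

    _stage("mediation")
    neg = cv_results["negative"]
    strength_m = tbl.edges[:, neg.consensus_mask].sum(axis=1)
    rejection = table.data.set_index("subject_id").loc[tbl.subject_ids, "rejection"].to_numpy(float)
    med_error = None
    med = None
    try:
        med = bootstrap_indirect(
            rejection, strength_m, tbl.scores,
            n_boot=cfg.n_boot, seed=cfg.seed,
        )
    except ValueError as exc:  # e.g. empty consensus network on null data
        med_error = str(exc)
        logger.warning("mediation skipped: %s", med_error)

    _stage("write report")
    preds = pd.DataFrame(
        {
            "subject_id": tbl.subject_ids,
            "observed": tbl.scores,
            "predicted_pos": cv_results["positive"].predicted,
            "predicted_neg": cv_results["negative"].predicted,
        }
    )
    preds.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "n_subjects": tbl.n_subjects,
        "n_edges": tbl.n_edges,
        "behavior": {"rejection_rumination_r": behav_r, "p": behav_p},
        "cpm": {
            sign: {
                "r_pred": cv_results[sign].r_pred,
                "p_pred": cv_results[sign].p_pred,
                "p_perm": perm[sign].p_perm,
                "n_consensus_edges": cv_results[sign].n_consensus_edges,
            }
            for sign in ("positive", "negative")
        },
        "anatomy": anatomy_out,
        "mediation": _mediation_block(med, med_error),
        "truth": {k: v for k, v in (truth or {}).items() if k != "latent"} or None,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    (out_dir / "mediation.json").write_text(
        json.dumps(report["mediation"], indent=2, default=_json_default)
    )
    return report


def _mediation_block(med, error):
    if med is None:
        return {"error": error}
    return {
        "a": med.a, "b": med.b, "c": med.c, "c_prime": med.c_prime,
        "indirect": med.indirect,
        "p_a": med.p_a, "p_b": med.p_b, "p_c": med.p_c, "p_c_prime": med.p_c_prime,
        "ci_low": med.ci_low, "ci_high": med.ci_high,
        "n_boot": med.n_boot, "level": med.level,
        "significant": med.significant,
        "standardized": med.standardized, "ci_method": med.ci_method,
    }


def _write_consensus_edges(path: Path, res, tbl: CohortEdgeTable) -> None:
    from .io import edge_pairs

    if tbl.n_rois is None:
        return
    i, j = edge_pairs(tbl.n_rois)
    sel = np.flatnonzero(res.consensus_mask)
    pd.DataFrame(
        {
            "edge": sel,
            "roi_i": i[sel],
            "roi_j": j[sel],
            "mean_training_r": res.mean_training_r[sel],
        }
    ).to_csv(path, sep="\t", index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
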