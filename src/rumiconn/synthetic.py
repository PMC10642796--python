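"""Synthetic cohorts with planted edge-behavior effects and a mediation chain.

The generator emulates the data model the rest of the package analyses: a
cohort of subjects, each with a symmetric nonnegative Fisher-z FC matrix and
behavioral scores, where

* a rejection score X drives a latent mediator M (path ``a``),
* M and X drive the rumination score Y (paths ``b`` and ``c'``), and
* a planted subset of edges carries signal through M, so that "network
  strength mediates the X -> Y association" is true by construction and the
  mediation stage has a recoverable ground truth.

All three behavioral quantities are standard normal in the latent model;
the questionnaire-like columns written to the subject table are affine
rescalings of X and Y (recorded in ``truth``), so planted path coefficients
are directly comparable to standardized estimates.

Planted-edge calibration
------------------------
A planted edge is ``z = mu + lambda * M + eps`` with ``eps ~ N(0, sigma^2)``.
With Var(M) = Var(Y) = 1 and Cov(M, Y) = kappa = c'*a + b, the edge-outcome
correlation is ``cor(z, Y) = lambda * kappa / sqrt(lambda^2 + sigma^2)``.
Solving for the target correlation rho gives

    lambda = sigma * rho * sign(kappa) / sqrt(kappa^2 - rho^2),

which requires |rho| < |kappa|: an edge can never correlate with the outcome
more strongly than the mediator that carries its signal does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    NETWORKS,
    FCMatrix,
    Parcellation,
    SubjectTable,
    devectorize_edges,
    n_edges,
    edge_pairs,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_cohort",
    "synthetic_parcellation",
    "write_cohort",
]

#: Affine maps from latent standard-normal scores to questionnaire-like
#: scales: rumination mimics a 10-item two-subscale total (range 10-40),
#: rejection an 8-item perceived-rejection total (range 8-40).
RUMINATION_SCALE = (25.0, 5.0)  # (intercept, slope)
REJECTION_SCALE = (20.0, 6.0)


@dataclass
class SyntheticConfig:
    """Cohort-level generative parameters.

    Defaults define the reference study conditions used throughout the test
    suite: 300 subjects, 60 ROIs (1770 edges), 30 planted edges whose values
    correlate -0.3 with rumination, and mediation paths a = b = -0.5,
    c' = 0.2 (signs matching the fitted mediation pattern: higher rejection,
    weaker network, more rumination).
    """

    n_subjects: int = 300
    n_rois: int = 60
    planted_edges: int = 30
    edge_effect: float = -0.3
    path_a: float = -0.5
    path_b: float = -0.5
    path_cprime: float = 0.2
    baseline_mu: float = 0.3
    edge_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (abs(self.path_a) < 1 and abs(self.path_b) < 1):
            raise ValueError("|path_a| and |path_b| must be < 1")
        if not abs(self.edge_effect) < 1:
            raise ValueError("|edge_effect| must be < 1")
        if self.planted_edges > n_edges(self.n_rois):
            raise ValueError(
                f"{self.planted_edges} planted edges exceed the "
                f"{n_edges(self.n_rois)} available edges"
            )
        if self.edge_noise_sd <= 0:
            raise ValueError("edge_noise_sd must be positive")
        if self.n_subjects < 2 or self.n_rois < 2:
            raise ValueError("need at least 2 subjects and 2 ROIs")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    fc: list[FCMatrix]
    table: SubjectTable
    truth: dict

    @property
    def planted_edge_indices(self) -> np.ndarray:
        return np.asarray(self.truth["planted_edge_indices"], dtype=int)


def _edge_loading(cfg: SyntheticConfig) -> float:
    """Loading lambda of planted edges on the latent mediator (see module doc)."""
    rho = cfg.edge_effect
    kappa = cfg.path_cprime * cfg.path_a + cfg.path_b
    if rho == 0.0:
        return 0.0
    if abs(rho) >= abs(kappa):
        raise ValueError(
            f"target edge correlation {rho} unattainable: |rho| must be below "
            f"|cor(M, Y)| = {abs(kappa):.4f} implied by the paths"
        )
    return cfg.edge_noise_sd * rho * math.copysign(1.0, kappa) / math.sqrt(
        kappa**2 - rho**2
    )


def _generate(cfg: SyntheticConfig, null: bool) -> SyntheticCohort:
    rng = np.random.default_rng(cfg.seed)
    n, r = cfg.n_subjects, cfg.n_rois
    p = n_edges(r)

    a = 0.0 if null else cfg.path_a
    b = 0.0 if null else cfg.path_b
    cp = 0.0 if null else cfg.path_cprime

    x = rng.standard_normal(n)
    m = a * x + math.sqrt(1.0 - a**2) * rng.standard_normal(n)
    var_signal = cp**2 + b**2 + 2.0 * cp * b * a  # Var(c'X + bM), Cov(X,M)=a
    if var_signal >= 1.0:
        raise ValueError("path coefficients imply Var(Y) >= 1 before noise")
    y = cp * x + b * m + math.sqrt(1.0 - var_signal) * rng.standard_normal(n)

    lam = 0.0 if null else _edge_loading(cfg)
    planted = np.sort(rng.choice(p, size=cfg.planted_edges, replace=False))
    edges = cfg.baseline_mu + cfg.edge_noise_sd * rng.standard_normal((n, p))
    edges[:, planted] += lam * m[:, None]
    np.maximum(edges, 0.0, out=edges)  # Fisher-z matrices carry no negatives

    rum_b0, rum_b1 = RUMINATION_SCALE
    rej_b0, rej_b1 = REJECTION_SCALE
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "rumination": rum_b0 + rum_b1 * y,
            "rejection": rej_b0 + rej_b1 * x,
            "age": np.round(rng.normal(19.3, 1.3, size=n), 1),
            "sex": rng.choice(["F", "M"], size=n, p=[0.72, 0.28]),
            "mean_fd": np.round(np.clip(rng.normal(0.12, 0.05, size=n), 0.02, 0.29), 4),
        }
    )

    i_idx, j_idx = edge_pairs(r)
    truth = {
        "null": null,
        "planted_edge_indices": planted.tolist(),
        "planted_edge_pairs": [
            (int(i_idx[e]), int(j_idx[e])) for e in planted
        ],
        "paths": {"a": a, "b": b, "c_prime": cp, "lambda": lam},
        "edge_effect_target": 0.0 if null else cfg.edge_effect,
        "latent": {"x": x.tolist(), "m": m.tolist(), "y": y.tolist()},
        "rescale": {
            "rumination": {"intercept": rum_b0, "slope": rum_b1},
            "rejection": {"intercept": rej_b0, "slope": rej_b1},
        },
        "config": asdict(cfg),
    }

    fc = [
        devectorize_edges(edges[i], r, subject_id=table["subject_id"][i])
        for i in range(n)
    ]
    return SyntheticCohort(fc=fc, table=SubjectTable(data=table), truth=truth)


def generate_cohort(cfg: SyntheticConfig | None = None, **kwargs) -> SyntheticCohort:
    """Generate a cohort with planted edge effects and mediation structure.

    Keyword arguments override fields of a default :class:`SyntheticConfig`.
    The same seed always yields a bitwise-identical cohort.
    """
    if cfg is None:
        cfg = SyntheticConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config object or keyword overrides, not both")
    return _generate(cfg, null=False)


def generate_null_cohort(cfg: SyntheticConfig | None = None, **kwargs) -> SyntheticCohort:
    """Generate a cohort with identical marginals but no planted dependence.

    All paths and the edge loading are forced to zero: edges, rejection and
    rumination are mutually independent.  Used for type-I-error and
    permutation-calibration checks.
    """
    if cfg is None:
        cfg = SyntheticConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config object or keyword overrides, not both")
    return _generate(cfg, null=True)


def synthetic_parcellation(n_rois: int) -> Parcellation:
    """A 7-network block parcellation for simulated cohorts.

    ROIs are split into seven contiguous, near-equal blocks labelled with the
    canonical network names, alternating hemispheres within each block.  This
    is a synthetic stand-in for an anatomical atlas lookup: it carries the
    structure the anatomy stage needs (a closed 7-label set and a hemisphere
    flag) and nothing else.
    """
    blocks = np.array_split(np.arange(n_rois), len(NETWORKS))
    rows = []
    for net, block in zip(NETWORKS, blocks):
        for k, roi in enumerate(block):
            hemi = "L" if k % 2 == 0 else "R"
            rows.append(
                {
                    "roi_id": int(roi),
                    "roi_name": f"{hemi}_{net}_{k}",
                    "network": net,
                    "hemisphere": hemi,
                }
            )
    return Parcellation(data=pd.DataFrame(rows))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort in the on-disk formats the loaders read.

    Produces ``subjects.csv``, ``parcellation.tsv``, per-subject matrix CSVs
    with ``matrices/manifest.tsv``, and a ``truth.json`` sidecar (without the
    per-subject latent draws, which can be regenerated from the config).
    """
    import json

    from .io import save_cohort_matrices

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = out_dir / "subjects.csv"
    cohort.table.data.to_csv(subjects, index=False)
    parc_path = out_dir / "parcellation.tsv"
    n_rois = cohort.fc[0].n_rois
    synthetic_parcellation(n_rois).data.to_csv(parc_path, sep="\t", index=False)
    manifest = save_cohort_matrices(cohort.fc, out_dir / "matrices")
    truth = {k: v for k, v in cohort.truth.items() if k != "latent"}
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {
        "subjects": subjects,
        "parcellation": parc_path,
        "manifest": manifest,
        "truth": truth_path,
    }
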