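"""Reading, writing and constructing functional-connectivity data structures.

The pipeline starts from per-subject ROI time series (timepoints x ROIs) or
from precomputed ROI x ROI connectivity matrices.  A functional-connectivity
(FC) matrix holds pairwise Pearson correlations of ROI BOLD time series,
Fisher z-transformed, with negative values set to zero (their meaning in
resting-state data is ambiguous) and a zero diagonal.

Every module in the package shares a single edge convention: the row-major
upper triangle (i < j), zero-based, so an R-ROI matrix has P = R(R-1)/2
unique edges enumerated (0,1), (0,2), ..., (R-2, R-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven canonical resting-state networks (Yeo/Krienen style): visual,
#: somatomotor, dorsal attention, salience/ventral attention, limbic,
#: frontoparietal control and default mode.
NETWORKS = ("VIS", "SMN", "DAN", "SAL", "LIM", "FPCN", "DMN")

#: Clamp for perfect (anti)correlations so atanh stays finite.
_R_CLAMP = 1.0 - 1e-7

SUBJECT_COLUMNS = ("subject_id", "rumination", "rejection", "age", "sex", "mean_fd")
PARCELLATION_COLUMNS = ("roi_id", "roi_name", "network", "hemisphere")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ROITimeSeries:
    """BOLD time series for one subject: ``data`` is T timepoints x R ROIs."""

    subject_id: str
    data: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D array (timepoints x ROIs)")
        t, r = self.data.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if r < 2:
            raise ValueError(f"need at least 2 ROIs, got {r}")
        if len(self.roi_ids) != r:
            raise ValueError("roi_ids length does not match data columns")
        if len(set(self.roi_ids)) != r:
            raise ValueError("roi_ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in time series of {self.subject_id!r}")


@dataclass
class FCMatrix:
    """One subject's symmetric ROI x ROI Fisher-z connectivity, negatives clipped."""

    subject_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.validate()

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]

    def validate(self) -> None:
        z = self.z
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.all(np.isfinite(z)):
            raise ValueError("FC matrix contains non-finite values")
        if not np.array_equal(z, z.T):
            raise ValueError("FC matrix must be exactly symmetric")
        if np.any(np.diagonal(z) != 0.0):
            raise ValueError("FC matrix diagonal must be zero")
        if np.any(z < 0.0):
            raise ValueError("FC matrix must be nonnegative after clipping")


@dataclass
class EdgeVector:
    """Upper-triangle vectorization of an FC matrix (row-major, i < j)."""

    values: np.ndarray
    n_rois: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n_edges(self.n_rois),):
            raise ValueError(
                f"expected {n_edges(self.n_rois)} edge values for "
                f"{self.n_rois} ROIs, got {self.values.shape}"
            )

    @property
    def edge_index(self) -> list[tuple[int, int]]:
        i, j = edge_pairs(self.n_rois)
        return list(zip(i.tolist(), j.tolist()))


@dataclass
class SubjectTable:
    """Behavioral/covariate table, one row per subject.

    Rows with missing rumination or rejection scores are dropped on load
    (listwise deletion); the count is kept in ``n_dropped_missing`` and
    logged, so exclusions remain auditable.
    """

    data: pd.DataFrame
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in SUBJECT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"subject table missing required column(s): {missing}")
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValueError(f"duplicate subject_id(s): {dupes}")
        if self.data[["rumination", "rejection"]].isna().any().any():
            raise ValueError("retained rows must have rumination and rejection scores")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].astype(str).tolist()


@dataclass
class Parcellation:
    """ROI lookup: id, anatomical name, one of the 7 networks, hemisphere.

    Row order defines the ROI order of every FC matrix in the cohort.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PARCELLATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"parcellation missing required column(s): {missing}")
        ids = self.data["roi_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate roi_id in parcellation")
        bad = set(self.data["network"].unique()) - set(NETWORKS)
        if bad:
            raise ValueError(
                f"unknown network label(s) {sorted(bad)}; allowed: {list(NETWORKS)}"
            )
        bad_hemi = set(self.data["hemisphere"].unique()) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"hemisphere must be 'L' or 'R', got {sorted(bad_hemi)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def networks(self) -> np.ndarray:
        """Network label per ROI, in matrix row order."""
        return self.data["network"].to_numpy()

    @property
    def roi_ids(self) -> np.ndarray:
        return self.data["roi_id"].to_numpy()


# ---------------------------------------------------------------------------
# Edge indexing helpers
# ---------------------------------------------------------------------------

def n_edges(n_rois: int) -> int:
    """Number of unique edges P = R(R-1)/2 for an R-ROI parcellation."""
    return n_rois * (n_rois - 1) // 2


def edge_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the row-major upper triangle (i < j)."""
    return np.triu_indices(n_rois, k=1)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_fc_matrix(ts: ROITimeSeries) -> FCMatrix:
    """Construct a subject's FC matrix from ROI time series.

    Pearson correlation over time for every ROI pair, Fisher z transform
    (atanh), negative z set to zero, zero diagonal.  Because atanh preserves
    sign, clipping after the transform equals clipping before it; the order
    here fixes bit-level behavior.  Perfect correlations are clamped to
    ``1 - 1e-7`` in absolute value so z stays finite.

    Raises
    ------
    ValueError
        If any ROI column has zero variance (the ROI is named) or the input
        contains non-finite values.
    """
    data = ts.data
    sd = data.std(axis=0)
    if np.any(sd == 0.0):
        bad = [ts.roi_ids[k] for k in np.flatnonzero(sd == 0.0)]
        raise ValueError(f"zero-variance ROI column(s): {bad}")
    r = np.corrcoef(data, rowvar=False)
    # np.corrcoef can stray an ulp outside [-1, 1]; clamp before atanh.
    r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(r)
    z[z < 0.0] = 0.0
    np.fill_diagonal(z, 0.0)
    z = np.maximum(z, z.T)  # exact symmetry despite float noise in corrcoef
    return FCMatrix(subject_id=ts.subject_id, z=z)


def vectorize_edges(fc: FCMatrix) -> EdgeVector:
    """Flatten an FC matrix into its canonical upper-triangle edge vector."""
    fc.validate()
    i, j = edge_pairs(fc.n_rois)
    return EdgeVector(values=fc.z[i, j], n_rois=fc.n_rois, subject_id=fc.subject_id)


def devectorize_edges(ev: EdgeVector | np.ndarray, n_rois: int,
                      subject_id: str = "") -> FCMatrix:
    """Rebuild the symmetric FC matrix from an edge vector (exact inverse)."""
    if isinstance(ev, EdgeVector):
        values, subject_id = ev.values, ev.subject_id or subject_id
    else:
        values = np.asarray(ev, dtype=float)
    if values.shape != (n_edges(n_rois),):
        raise ValueError(
            f"edge vector of length {values.size} does not match "
            f"{n_rois} ROIs (expected {n_edges(n_rois)})"
        )
    z = np.zeros((n_rois, n_rois))
    i, j = edge_pairs(n_rois)
    z[i, j] = values
    z[j, i] = values
    return FCMatrix(subject_id=subject_id, z=z)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a headered CSV/TSV, sniffing the delimiter from the suffix."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def load_subject_table(path: str | Path) -> SubjectTable:
    """Load the subject table, applying listwise deletion on missing scores."""
    df = _read_delimited(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table {path} missing column(s): {missing}")
    keep = df["rumination"].notna() & df["rejection"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d subject(s) with missing behavioral scores", n_dropped)
    df = df.loc[keep].reset_index(drop=True)
    df["subject_id"] = df["subject_id"].astype(str)
    return SubjectTable(data=df, n_dropped_missing=n_dropped)


def load_parcellation(path: str | Path) -> Parcellation:
    """Load an ROI -> (name, network, hemisphere) lookup table."""
    df = _read_delimited(path)
    return Parcellation(data=df)


def load_time_series(path: str | Path, subject_id: str | None = None) -> ROITimeSeries:
    """Load a T x R delimited time-series file with an ROI header row."""
    path = Path(path)
    df = _read_delimited(path)
    sid = subject_id if subject_id is not None else path.stem
    return ROITimeSeries(subject_id=sid, data=df.to_numpy(dtype=float),
                         roi_ids=[str(c) for c in df.columns])


def load_fc_matrix(path: str | Path, subject_id: str | None = None) -> FCMatrix:
    """Load one delimited R x R matrix; filename stem is the subject id."""
    path = Path(path)
    z = np.loadtxt(path, delimiter=None if path.suffix == ".txt" else ",")
    sid = subject_id if subject_id is not None else path.stem
    return FCMatrix(subject_id=sid, z=np.atleast_2d(z))


def save_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    np.savetxt(path, fc.z, delimiter=",", fmt="%.10g")


def load_cohort_matrices(manifest_path: str | Path) -> list[FCMatrix]:
    """Load a cohort of FC matrices via a manifest mapping subject_id -> file.

    The manifest is a TSV with columns ``subject_id`` and ``path``; relative
    paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    for col in ("subject_id", "path"):
        if col not in manifest.columns:
            raise ValueError(f"matrix manifest missing column {col!r}")
    root = manifest_path.parent
    out = []
    for sid, rel in zip(manifest["subject_id"].astype(str), manifest["path"]):
        p = Path(rel)
        out.append(load_fc_matrix(p if p.is_absolute() else root / p, subject_id=sid))
    return out


def save_cohort_matrices(matrices: list[FCMatrix], out_dir: str | Path) -> Path:
    """Write one CSV matrix per subject plus a manifest; return manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for fc in matrices:
        fname = f"{fc.subject_id}.csv"
        save_fc_matrix(fc, out_dir / fname)
        rows.append({"subject_id": fc.subject_id, "path": fname})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
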