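"""Delimited-text input/output, real-data preprocessing helpers, manifests.

All interchange is plain text: time series and square matrices as CSV/TSV
(auto-detected delimiter), point clouds as CSV with a JSON metadata sidecar,
Betti curves as long-format CSV, and a JSON manifest capturing enough of the
configuration (including the seed and package version) to reproduce a run
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .filtration import OrderComplex, build_order_complex, corr_to_distance
from .geometry import PointCloud
from .homology import BettiCurves, betti_curves
from .matrices import SymmetricMatrix, TimeSeriesSet, pearson_correlation
from .signatures import Signature, integral_signature

__all__ = [
    "read_time_series",
    "write_time_series",
    "read_matrix",
    "write_matrix",
    "write_point_cloud",
    "read_point_cloud",
    "write_order_complex",
    "write_betti_curves",
    "write_signature",
    "write_manifest",
    "log_returns",
    "analyze_matrix",
]

log = logging.getLogger("bettisig")


def read_time_series(path: str | Path) -> TimeSeriesSet:
    """Read a delimited time-series file: rows = time points, columns = series.

    The first row must hold series labels; CSV and TSV are auto-detected.
    Missing values are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    values = df.to_numpy(dtype=float)
    return TimeSeriesSet(values, labels=[str(c) for c in df.columns])


def write_time_series(ts: TimeSeriesSet, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=ts.labels).to_csv(path, index=False)


def read_matrix(path: str | Path, role: str = "generic") -> SymmetricMatrix:
    """Read a square symmetric matrix from delimited text.

    Accepts either a plain numeric grid or a labelled grid (header row plus
    index column); symmetry and role invariants are validated on load.
    """
    raw = pd.read_csv(path, sep=None, engine="python", header=None)
    try:
        values = raw.to_numpy(dtype=float)
    except ValueError:
        labelled = pd.read_csv(path, sep=None, engine="python", index_col=0)
        values = labelled.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{path}: matrix contains missing/NaN entries")
    return SymmetricMatrix(values, role=role)


def write_matrix(M: SymmetricMatrix, path: str | Path, labels: list[str] | None = None) -> None:
    """Write a square matrix as labelled CSV (row and column labels)."""
    if labels is None:
        labels = [f"v{i:03d}" for i in range(M.n)]
    pd.DataFrame(M.values, index=labels, columns=labels).to_csv(path, index=True)


def write_point_cloud(cloud: PointCloud, path: str | Path) -> None:
    """Point cloud as CSV (one point per row) plus a JSON metadata sidecar."""
    path = Path(path)
    cols = [f"x{i}" for i in range(cloud.ambient_dim)]
    pd.DataFrame(cloud.points, columns=cols).to_csv(path, index=False)
    meta = {"geometry": cloud.geometry, "seed": cloud.seed, "radius": cloud.radius}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, sort_keys=True))


def read_point_cloud(path: str | Path) -> PointCloud:
    path = Path(path)
    pts = pd.read_csv(path).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PointCloud(pts, meta["geometry"], meta["seed"], radius=meta["radius"])


def write_order_complex(oc: OrderComplex, path: str | Path) -> None:
    """Filtration as 3-column CSV (i, j, weight) in edge-insertion order."""
    pd.DataFrame(
        {"i": oc.edges[:, 0], "j": oc.edges[:, 1], "weight": oc.weights}
    ).to_csv(path, index=False)


def write_betti_curves(bc: BettiCurves, path: str | Path) -> None:
    """Betti curves as long-format CSV: step, density, dimension, betti."""
    k = bc.n_steps
    frames = []
    for dim in range(bc.max_dim + 1):
        frames.append(
            pd.DataFrame(
                {
                    "step": np.arange(k + 1),
                    "density": bc.densities,
                    "dimension": dim,
                    "betti": bc.curves[dim],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_signature(sig: Signature, path: str | Path) -> None:
    row = {
        "geometry": sig.geometry_label,
        "dim": sig.ambient_dim_or_length,
        "replicate": sig.replicate,
        "seed": sig.seed,
        "n_vertices": sig.n_vertices,
        "b0_auc": sig.b0_auc,
        "b1_auc": sig.b1_auc,
    }
    for i, a in enumerate(sig.higher_auc, start=2):
        row[f"b{i}_auc"] = a
    pd.DataFrame([row]).to_csv(path, index=False)


def write_manifest(config: dict, path: str | Path) -> None:
    """JSON manifest of a run: configuration, seed and package version."""
    payload = {"package": "bettisig", "version": __version__, **config}
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def log_returns(prices: TimeSeriesSet | np.ndarray) -> TimeSeriesSet:
    """Logarithmic returns ``r(t) = log[p(t) / p(t-1)]`` of a price panel.

    Input is a T x N matrix of strictly positive prices; output has T-1 rows.
    """
    if isinstance(prices, TimeSeriesSet):
        values, labels = prices.values, prices.labels
    else:
        values = np.asarray(prices, dtype=float)
        labels = None
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("prices must be a (T, N) matrix with T >= 2")
    bad = np.argwhere(values <= 0)
    if bad.size:
        t, i = bad[0]
        raise ValueError(f"non-positive price at row {t}, column {i}")
    lp = np.log(values)
    return TimeSeriesSet(lp[1:] - lp[:-1], labels=labels or [])


def analyze_matrix(
    input_path: str | Path,
    input_type: str,
    max_dim: int = 1,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[BettiCurves, Signature]:
    """Full pipeline on one file: input -> Betti curves -> integral signature.

    ``input_type`` selects the entry stage: ``"timeseries"`` runs Pearson
    correlation, ``1 - C`` and the filtration; ``"correlation"`` skips the
    correlation stage; ``"distance"`` filters the matrix directly.  When
    ``out_dir`` is given, writes the curves CSV, signature CSV and a JSON
    manifest there.
    """
    if input_type not in ("timeseries", "correlation", "distance"):
        raise ValueError(f"unknown input_type {input_type!r}")
    input_path = Path(input_path)
    if input_type == "timeseries":
        ts = read_time_series(input_path)
        log.info("stage=read_timeseries shape=%s path=%s", ts.values.shape, input_path)
        M = corr_to_distance(pearson_correlation(ts))
        length = ts.n_timepoints
    else:
        role = "correlation" if input_type == "correlation" else "distance"
        M = read_matrix(input_path, role=role)
        log.info("stage=read_matrix shape=%s path=%s", M.values.shape, input_path)
        if role == "correlation":
            M = corr_to_distance(M)
        length = M.n
    oc = build_order_complex(M)
    log.info("stage=order_complex n=%d steps=%d", oc.n_vertices, oc.n_steps)
    bc = betti_curves(oc, max_dim=max_dim)
    log.info("stage=betti_curves max_dim=%d", max_dim)
    sig = integral_signature(
        bc,
        geometry_label=input_type,
        ambient_dim_or_length=length,
        seed=seed,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_betti_curves(bc, out_dir / "betti_curves.csv")
        write_signature(sig, out_dir / "signature.csv")
        write_manifest(
            {
                "input": str(input_path),
                "input_type": input_type,
                "max_dim": max_dim,
                "seed": seed,
            },
            out_dir / "manifest.json",
        )
        log.info("stage=write out_dir=%s", out_dir)
    return bc, sig
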