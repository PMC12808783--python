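"""Pairwise separability of geometry strata from (B0AUC, B1AUC) features.

A linear support-vector machine is trained to tell two strata apart using
only the two integral-signature coordinates, with balanced 50/50 train-test
splits.  High test accuracy means the two reference geometries produce
distinguishable signature clouds at that dimension; accuracy near chance
(0.5) means the low-dimensional summary cannot separate them — as happens
for random correlation versus spherical strata, whose filtrations are
equivalent up to a monotone transformation.

A single 50/50 split of 100-point strata has high variance, so the reported
accuracy is averaged over ``repeats`` random splits (set ``repeats=1`` for a
strict single-split protocol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["SeparabilityResult", "pairwise_separability", "accuracy_matrix"]


@dataclass
class SeparabilityResult:
    """Mean linear-SVM test accuracy for one stratum pair at one dimension."""

    geometry_a: str
    geometry_b: str
    dim: int
    accuracy: float
    accuracy_sem: float
    n_train: int
    n_test: int
    repeats: int
    seed: int


def _stratum(signatures: pd.DataFrame, label: str, dim: int, radius: float | None) -> np.ndarray:
    sel = (signatures["geometry"] == label) & (signatures["dim"] == dim)
    if radius is not None:
        sel &= np.isclose(signatures["radius"], radius)
    feats = signatures.loc[sel, ["b0_auc", "b1_auc"]].to_numpy(dtype=float)
    if feats.shape[0] < 10:
        raise ValueError(f"stratum {label!r} at dim {dim} has {feats.shape[0]} points (< 10)")
    return feats


def pairwise_separability(
    signatures: pd.DataFrame,
    pair: tuple[str, str],
    dim: int,
    seed: int,
    repeats: int = 20,
    radii: tuple[float | None, float | None] = (None, None),
) -> SeparabilityResult:
    """Linear-SVM accuracy separating two strata of a signature table.

    Parameters
    ----------
    signatures
        Signature table as produced by :func:`bettisig.signatures.signature_sweep`.
    pair
        Two geometry labels; for an ``HG`` member pass its radius in ``radii``.
    dim
        Stratum dimension (ambient dim or series length) to select.
    repeats
        Number of random balanced 50/50 splits to average over.

    Features are z-scored on the training half only; the classifier is a
    linear SVM with C = 1.  Classes are balanced by truncating both strata
    to the smaller size.
    """
    a, b = pair
    # canonical internal order so that swapping the pair's labels cannot
    # change the splits and hence the reported accuracy
    if (str(b), str(radii[1])) < (str(a), str(radii[0])):
        (a0, b0), radii0 = (b, a), (radii[1], radii[0])
    else:
        (a0, b0), radii0 = (a, b), radii
    xa = _stratum(signatures, a0, dim, radii0[0])
    xb = _stratum(signatures, b0, dim, radii0[1])
    n = min(len(xa), len(xb))
    x = np.vstack([xa[:n], xb[:n]])
    y = np.repeat([0, 1], n)
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        xtr, xte, ytr, yte = train_test_split(
            x, y, test_size=0.5, stratify=y, random_state=rs
        )
        scaler = StandardScaler().fit(xtr)
        clf = SVC(kernel="linear", C=1.0).fit(scaler.transform(xtr), ytr)
        accs.append(clf.score(scaler.transform(xte), yte))
    accs = np.asarray(accs)
    sem = float(accs.std(ddof=1) / np.sqrt(len(accs))) if repeats > 1 else 0.0
    return SeparabilityResult(
        geometry_a=a,
        geometry_b=b,
        dim=dim,
        accuracy=float(accs.mean()),
        accuracy_sem=sem,
        n_train=len(y) // 2,
        n_test=len(y) - len(y) // 2,
        repeats=repeats,
        seed=seed,
    )


def accuracy_matrix(
    signatures: pd.DataFrame,
    labels: list[str],
    dim: int,
    seed: int,
    repeats: int = 20,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise accuracies between the listed strata."""
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        mat.loc[a, a] = np.nan
        for b in labels[i + 1 :]:
            res = pairwise_separability(signatures, (a, b), dim, seed=seed, repeats=repeats)
            mat.loc[a, b] = mat.loc[b, a] = res.accuracy
    return mat
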