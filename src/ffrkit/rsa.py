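"""Representational similarity analysis over decoding confusion matrices.

Conditions (species x recording level) are compared through their tone
confusion matrices with the diagonal removed: pairwise Pearson correlations
of the off-diagonal cells (with permutation significance), and per-condition
2-D multidimensional scaling of the tone confusion structure with all
configurations Procrustes-aligned to the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import procrustes as _procrustes
from scipy.stats import pearsonr

from .decode import ConfusionMatrix

__all__ = ["RsaResult", "rsa_similarity", "classical_mds", "mds_procrustes"]

logger = logging.getLogger(__name__)


@dataclass
class RsaResult:
    r: np.ndarray  # condition x condition Pearson r (off-diagonal cells)
    p: np.ndarray  # permutation p per pair
    coords: list[np.ndarray]  # per condition, tones x 2, Procrustes-aligned
    disparities: list[float]  # Procrustes disparity vs the first condition
    labels: list[str]


def _offdiag(cm) -> np.ndarray:
    if isinstance(cm, ConfusionMatrix):
        return cm.off_diagonal()
    cm = np.asarray(cm, dtype=float)
    return cm[~np.eye(cm.shape[0], dtype=bool)]


def rsa_similarity(cm_a, cm_b, n_perm: int = 10000, seed: int = 0
                   ) -> tuple[float, float]:
    """Pearson r between two confusion matrices' off-diagonal cells, with a
    permutation p-value (cell assignments of the second matrix shuffled)."""
    a, b = _offdiag(cm_a), _offdiag(cm_b)
    if a.shape != b.shape:
        raise ValueError("confusion matrices must share a shape")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in off-diagonal cells")
    r = float(pearsonr(a, b).statistic)
    rng = np.random.default_rng(seed)
    perm_r = np.empty(n_perm)
    for i in range(n_perm):
        perm_r[i] = np.corrcoef(a, rng.permutation(b))[0, 1]
    p = float((np.sum(np.abs(perm_r) >= abs(r) - 1e-12) + 1) / (n_perm + 1))
    return r, p


def classical_mds(dissim: np.ndarray, n_dim: int = 2) -> np.ndarray:
    """Torgerson classical MDS (cmdscale): eigendecomposition of the
    double-centred squared dissimilarity matrix.  Falls back to fewer
    dimensions (warning) when positive eigenvalues run out."""
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-9
    usable = min(n_dim, int(pos.sum()))
    if usable < n_dim:
        logger.warning("rank-deficient dissimilarity: %d of %d MDS "
                       "dimensions available", usable, n_dim)
    coords = np.zeros((n, n_dim))
    coords[:, :usable] = vecs[:, :usable] * np.sqrt(vals[:usable])
    return coords


def confusion_to_dissimilarity(cm) -> np.ndarray:
    """Symmetrized tone dissimilarity from a confusion matrix, diagonal 0.

    Mutual confusability s_ij = (c_ij + c_ji)/2 (the diagonal discarded);
    dissimilarity is 1 - s_ij.
    """
    m = cm.matrix if isinstance(cm, ConfusionMatrix) else np.asarray(cm, float)
    s = 0.5 * (m + m.T)
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    return d


def mds_procrustes(cms: list, labels: list[str] | None = None) -> RsaResult:
    """Full RSA bundle: pairwise similarity plus aligned MDS configurations.

    Each confusion matrix is embedded in 2-D by classical MDS of its
    symmetrized tone dissimilarity; every configuration is Procrustes-aligned
    (rotation, scale, translation) to the first.
    """
    if len(cms) < 2:
        raise ValueError("need at least 2 confusion matrices")
    labels = labels or [f"cond{i}" for i in range(len(cms))]
    n = len(cms)
    r = np.eye(n)
    p = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            try:
                r[i, k], p[i, k] = rsa_similarity(cms[i], cms[k])
            except ValueError:
                # a perfectly diagonal confusion matrix has no error
                # structure to correlate; similarity is undefined
                logger.warning("conditions %d/%d: zero off-diagonal "
                               "variance; similarity undefined", i, k)
                r[i, k], p[i, k] = np.nan, np.nan
            r[k, i], p[k, i] = r[i, k], p[i, k]
    configs = [classical_mds(confusion_to_dissimilarity(cm)) for cm in cms]
    ref = configs[0]
    coords, disparities = [], []
    for conf in configs:
        ref_std, conf_std, disparity = _procrustes(ref, conf)
        coords.append(conf_std)
        disparities.append(float(disparity))
    return RsaResult(r=r, p=p, coords=coords, disparities=disparities,
                     labels=labels)
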