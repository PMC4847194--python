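"""Gaussian-mixture clustering of sPLS latent scores and cluster transitions.

Samples are grouped in the low-dimensional sPLS score space with finite
Gaussian mixtures fit by EM, initialised from a Ward agglomerative partition,
and the covariance family and number of components are chosen by maximal BIC
(on the 2*loglik - params*ln(n) scale, so larger is better). Per-subject
trajectories through the chosen clusters give a transition diagram; rare
transitions are pruned for readability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

FAMILIES = ("spherical", "diag", "tied", "full")


@dataclass
class GmmFit:
    """Best-BIC Gaussian mixture over (family, k) candidates."""

    k: int
    model_family: str
    means: np.ndarray
    covariances: np.ndarray
    assignment: np.ndarray        # hard argmax labels
    responsibilities: np.ndarray  # n x k, rows sum to 1
    bic_table: pd.DataFrame       # families x k, larger is better
    model: GaussianMixture


def _ward_init(T: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(T)
    means = np.vstack([T[labels == j].mean(axis=0) for j in range(k)])
    weights = np.bincount(labels, minlength=k) / len(labels)
    return means, weights


def cluster_scores(T: np.ndarray, k_range=range(1, 10),
                   families=FAMILIES, seed: int | None = 0,
                   reg_covar: float = 1e-6) -> GmmFit:
    """Cluster samples by their latent scores, selecting (family, k) by BIC."""
    T = np.asarray(T, dtype=float)
    if not np.isfinite(T).all():
        raise ValueError("scores must be finite")
    n = T.shape[0]
    k_range = [k for k in k_range if k < n]
    if not k_range:
        raise ValueError("no admissible cluster count below n")
    bic = pd.DataFrame(np.nan, index=list(families), columns=list(k_range))
    best = None
    for fam in families:
        for k in k_range:
            if k == 1:
                means = T.mean(axis=0, keepdims=True)
                weights = np.ones(1)
            else:
                means, weights = _ward_init(T, k)
            gm = GaussianMixture(n_components=k, covariance_type=fam,
                                 means_init=means, weights_init=weights,
                                 reg_covar=reg_covar, random_state=seed,
                                 n_init=1, max_iter=500)
            try:
                gm.fit(T)
            except ValueError as exc:  # EM collapse
                log.warning("GMM (%s, k=%d) failed: %s", fam, k, exc)
                continue
            score = -gm.bic(T)  # 2*loglik - params*ln(n)
            bic.loc[fam, k] = score
            if best is None or score > best[0]:
                best = (score, fam, k, gm)
    if best is None:
        raise RuntimeError("every mixture fit failed")
    _, fam, k, gm = best
    resp = gm.predict_proba(T)
    return GmmFit(k, fam, gm.means_, gm.covariances_,
                  resp.argmax(axis=1), resp, bic, gm)


def transition_diagram(assignments, subjects, weeks,
                       min_count: int = 6) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count per-subject consecutive-week cluster moves.

    Returns ``(changes, self_loops)``: ordered cluster-change edges with
    counts below ``min_count`` dropped, and self-loop (no-change) counts
    reported separately without pruning. Transitions are taken between each
    subject's successive available weeks, whatever the spacing.
    """
    df = pd.DataFrame({"subject": np.asarray(subjects),
                       "week": np.asarray(weeks, dtype=int),
                       "cluster": np.asarray(assignments)})
    if df.duplicated(["subject", "week"]).any():
        raise ValueError("one assignment per (subject, week) required")
    moves: dict[tuple, int] = {}
    loops: dict[tuple, int] = {}
    for _, grp in df.sort_values("week").groupby("subject"):
        cl = grp["cluster"].to_numpy()
        for a, b in zip(cl[:-1], cl[1:]):
            if a == b:
                loops[(a, b)] = loops.get((a, b), 0) + 1
            else:
                moves[(a, b)] = moves.get((a, b), 0) + 1
    changes = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(moves.items()) if c >= min_count],
        columns=["from", "to", "count"])
    self_loops = pd.DataFrame(
        [(a, c) for (a, _), c in sorted(loops.items())],
        columns=["cluster", "count"])
    return changes, self_loops
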