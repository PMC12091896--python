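"""Post-hoc model interpretation.

Two procedures:

* masking-based feature importance -- zero one node-feature column at a
  time across the whole evaluation set, re-score, and record the drop in
  Pearson correlation and the rise in RMSE relative to the unmasked
  baseline; large drops mark features the model leans on;
* embedding PCA -- collect the per-slice sum-pooled embeddings h_k of
  every complex, project each slice onto its first principal component,
  and regress the binding strength on that projection, exposing how each
  contact range relates to affinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .evaluation import pearson, rmse
from .model import ModelState, forward

__all__ = [
    "FeatureImportance",
    "EmbeddingProjection",
    "masking_importance",
    "embedding_pca",
]


@dataclass
class FeatureImportance:
    feature_names: tuple[str, ...]
    delta_pc: np.ndarray  # PC_0 - PC_masked, signed
    delta_rmse: np.ndarray  # RMSE_masked - RMSE_0, signed
    baseline_pc: float
    baseline_rmse: float

    def ranking(self, by: str = "delta_pc") -> list[int]:
        """Feature indices sorted by descending importance."""
        vals = self.delta_pc if by == "delta_pc" else self.delta_rmse
        return list(np.argsort(-vals, kind="stable"))


@dataclass
class SliceProjection:
    pc1_scores: np.ndarray  # per-complex PC1 projection
    explained_variance_ratio: np.ndarray
    slope: float
    intercept: float
    correlation: Optional[float]


@dataclass
class EmbeddingProjection:
    slices: list[SliceProjection]  # one entry per adjacency slice


def _score_dataset(state: ModelState, dataset) -> np.ndarray:
    return np.array([forward(state, F, N)[0] for F, N, _ in dataset])


def masking_importance(state: ModelState, dataset: Sequence) -> FeatureImportance:
    """Mask each feature column in turn and measure the performance drop.

    ``dataset`` items are ``(F, N, label)`` with F the node-feature matrix
    of one complex.  Masking replaces the column with zeros in every
    complex; the inputs themselves are never modified.
    """
    from .features import NodeFeatureMatrix

    labels = np.array([float(lbl) for _, _, lbl in dataset])
    mats = [
        (F.values if isinstance(F, NodeFeatureMatrix) else np.asarray(F, float))
        for F, _, _ in dataset
    ]
    adjs = [N for _, N, _ in dataset]
    base_pred = np.array([forward(state, F, N)[0] for F, N in zip(mats, adjs)])
    pc0 = pearson(labels, base_pred)
    if pc0 is None:
        raise RuntimeError("baseline Pearson correlation undefined; cannot rank features")
    rmse0 = rmse(labels, base_pred)
    m = mats[0].shape[1]
    delta_pc = np.zeros(m)
    delta_rmse = np.zeros(m)
    for j in range(m):
        preds = []
        for F, N in zip(mats, adjs):
            masked = F.copy()
            masked[:, j] = 0.0
            preds.append(forward(state, masked, N)[0])
        preds = np.array(preds)
        pc_j = pearson(labels, preds)
        delta_pc[j] = pc0 - (pc_j if pc_j is not None else 0.0)
        delta_rmse[j] = rmse(labels, preds) - rmse0
    return FeatureImportance(
        feature_names=state.feature_names,
        delta_pc=delta_pc,
        delta_rmse=delta_rmse,
        baseline_pc=pc0,
        baseline_rmse=rmse0,
    )


def embedding_pca(state: ModelState, dataset: Sequence) -> EmbeddingProjection:
    """PCA of the per-slice embeddings against binding strength.

    For each slice k the h_k of all complexes are centered and decomposed;
    PC1 scores are sign-fixed so the largest-magnitude loading is
    positive, then the label is regressed on PC1 by ordinary least
    squares.
    """
    from sklearn.decomposition import PCA

    if len(dataset) < 3:
        raise ValueError("embedding PCA needs at least 3 complexes")
    labels = np.array([float(lbl) for _, _, lbl in dataset])
    embeddings = [forward(state, F, N)[1] for F, N, _ in dataset]
    K = len(embeddings[0].h_k)
    slices = []
    for k in range(K):
        H = np.array([emb.h_k[k] for emb in embeddings])
        if np.allclose(H.std(axis=0), 0.0):
            import warnings

            warnings.warn(f"slice {k}: constant embeddings, PCA degenerate; fit skipped")
            slices.append(
                SliceProjection(
                    pc1_scores=np.zeros(len(dataset)),
                    explained_variance_ratio=np.zeros(min(H.shape)),
                    slope=np.nan,
                    intercept=np.nan,
                    correlation=None,
                )
            )
            continue
        n_comp = min(H.shape[0], H.shape[1])
        pca = PCA(n_components=n_comp)
        scores = pca.fit_transform(H)
        loading = pca.components_[0]
        if loading[np.argmax(np.abs(loading))] < 0:  # sign convention
            loading = -loading
            scores[:, 0] = -scores[:, 0]
        pc1 = scores[:, 0]
        slope, intercept = np.polyfit(pc1, labels, 1)
        slices.append(
            SliceProjection(
                pc1_scores=pc1,
                explained_variance_ratio=pca.explained_variance_ratio_,
                slope=float(slope),
                intercept=float(intercept),
                correlation=pearson(labels, pc1) if np.std(pc1) > 0 else None,
            )
        )
    return EmbeddingProjection(slices=slices)


def export_importance(imp: FeatureImportance, path) -> None:
    """Tab-separated importance table, one row per feature."""
    with open(path, "w") as fh:
        fh.write(f"# baseline_pc={imp.baseline_pc:.6f}\tbaseline_rmse={imp.baseline_rmse:.6f}\n")
        fh.write("feature\tdelta_pc\tdelta_rmse\n")
        for name, dpc, drm in zip(imp.feature_names, imp.delta_pc, imp.delta_rmse):
            fh.write(f"{name}\t{dpc:.6f}\t{drm:.6f}\n")
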