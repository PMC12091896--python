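"""Scoring metrics, train/eval leakage filtering and screening enrichment.

Scoring quality is summarized by the Pearson correlation (PC) and RMSE
between experimental and predicted binding strengths.  To keep evaluation
honest, an evaluation complex is discarded when some training complex is
simultaneously similar in protein sequence (>= 0.3) and in ligand
structure (>= 0.7); i.e. a pair is acceptable when at least one of the two
similarities stays strictly below its threshold.

Screening power is measured by the enrichment factor EF_X: the fraction
of all actives recovered in the top X% of the score-ranked library,
divided by X/100.  Because real screening libraries are highly imbalanced,
EF is swept over decoy-to-active ratios r_DTA: for each ratio, all actives
are kept, ``n_actives * r_DTA`` decoys are sampled without replacement,
and the EF of the subsampled library is averaged over repeats (10 by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "MetricsReport",
    "ScreeningConfig",
    "EnrichmentResult",
    "SimilarityFilterConfig",
    "pearson",
    "rmse",
    "evaluate_scores",
    "similarity_filter",
    "enrichment_factor",
    "screening_protocol",
    "rdta_max",
    "protein_sequence_identity",
    "ligand_tanimoto",
]


@dataclass
class MetricsReport:
    pc: Optional[float]  # None when either vector has zero variance
    rmse: float
    n: int


@dataclass
class ScreeningConfig:
    top_percents: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    ratios: tuple[int, ...] = (2, 5, 10, 20)
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.top_percents = tuple(float(x) for x in self.top_percents)
        self.ratios = tuple(int(r) for r in self.ratios)
        if any(not (0 < x <= 100) for x in self.top_percents):
            raise ValueError("top percents must lie in (0, 100]")
        if any(r < 1 for r in self.ratios):
            raise ValueError("ratios must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class EnrichmentResult:
    mean_ef: dict  # (X, r_DTA) -> mean EF
    per_repeat_ef: dict  # (X, r_DTA) -> list of EF values
    rdta_max: int


@dataclass
class SimilarityFilterConfig:
    protein_threshold: float = 0.3
    ligand_threshold: float = 0.7

    def __post_init__(self) -> None:
        for t in (self.protein_threshold, self.ligand_threshold):
            if not (0 < t <= 1):
                raise ValueError("thresholds must lie in (0, 1]")


def pearson(y_true: Sequence[float], y_pred: Sequence[float]) -> Optional[float]:
    """Sample Pearson correlation; None (with a warning) if degenerate."""
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("pearson needs two equal-length vectors of size >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance: Pearson correlation undefined")
        return None
    return float(np.corrcoef(a, b)[0, 1])


def rmse(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def evaluate_scores(y_true, y_pred) -> MetricsReport:
    return MetricsReport(pc=pearson(y_true, y_pred), rmse=rmse(y_true, y_pred), n=len(y_true))


def similarity_filter(
    train_ids: Sequence[str],
    eval_ids: Sequence[str],
    protein_sim: Callable[[str, str], float],
    ligand_sim: Callable[[str, str], float],
    cfg: SimilarityFilterConfig = SimilarityFilterConfig(),
) -> tuple[list[str], list[dict]]:
    """Remove evaluation complexes too similar to any training complex.

    A pair passes when protein similarity < protein_threshold OR ligand
    similarity < ligand_threshold (strict); an evaluation complex failing
    against any training complex is removed.  Returns the retained ids and
    a removal report naming each offending pair.
    """
    retained, removals = [], []
    for e in eval_ids:
        offender = None
        for t in train_ids:
            ps = float(protein_sim(e, t))
            ls = float(ligand_sim(e, t))
            if not (0.0 <= ps <= 1.0 and 0.0 <= ls <= 1.0):
                raise ValueError(
                    f"similarity outside [0,1] for pair ({e}, {t}): {ps}, {ls}"
                )
            if ps >= cfg.protein_threshold and ls >= cfg.ligand_threshold:
                offender = {"eval_id": e, "train_id": t, "protein_sim": ps, "ligand_sim": ls}
                break
        if offender is None:
            retained.append(e)
        else:
            removals.append(offender)
    return retained, removals


def enrichment_factor(
    labels_ranked: Sequence[int], X: float, mode: str = "recall"
) -> float:
    """EF of a ranked library (1 = active, 0 = decoy, best score first).

    ``n_top = round(N * X / 100)`` with a floor of one ligand.  In the
    default ``recall`` reading, the "percentage of actives found in the
    top X%" is measured against all actives: EF = (hits / total_actives)
    / (n_top / N).  The alternative ``precision`` reading measures the
    active fraction of the top block itself: EF = (hits / n_top) / (X /
    100).  The recall reading is the default because its ceiling is the
    library's total/active ratio, which matches how screening EF values
    are reported in practice.
    """
    labels = np.asarray(labels_ranked, dtype=int)
    N = labels.size
    if N == 0:
        raise ValueError("empty ranked list")
    total_actives = int(labels.sum())
    if total_actives == 0:
        raise ValueError("EF undefined: no actives in the library")
    n_top = max(1, int(round(N * X / 100.0)))
    hits = int(labels[:n_top].sum())
    if mode == "recall":
        return (hits / total_actives) / (n_top / N)
    if mode == "precision":
        return (hits / n_top) / (X / 100.0)
    raise ValueError("mode must be 'recall' or 'precision'")


def rdta_max(n_actives: int, n_decoys: int) -> int:
    """Nearest-integer decoy-to-active ratio of a full library."""
    if n_actives < 1:
        raise ValueError("need at least one active")
    return int(round(n_decoys / n_actives))


def screening_protocol(
    scores: Sequence[float],
    labels: Sequence[int],
    cfg: ScreeningConfig,
) -> EnrichmentResult:
    """Decoy-subsampled EF sweep.

    For each requested ratio r: keep all actives, draw ``n_actives * r``
    decoys without replacement, rank the union by score (descending,
    stable ties), compute EF at each top-X%, and average over
    ``cfg.repeats`` draws.  Deterministic for a fixed seed.  Ratios the
    decoy pool cannot support are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    active_idx = np.nonzero(labels == 1)[0]
    decoy_idx = np.nonzero(labels == 0)[0]
    if active_idx.size == 0:
        raise ValueError("EF undefined: no actives")
    rng = np.random.default_rng(cfg.seed)
    mean_ef: dict = {}
    per_repeat: dict = {}
    for r in cfg.ratios:
        n_draw = active_idx.size * r
        if n_draw > decoy_idx.size:
            warnings.warn(
                f"ratio {r} skipped: needs {n_draw} decoys, pool has {decoy_idx.size}"
            )
            continue
        for rep in range(cfg.repeats):
            chosen = rng.choice(decoy_idx, size=n_draw, replace=False)
            subset = np.concatenate([active_idx, chosen])
            sub_scores = scores[subset]
            sub_labels = labels[subset]
            order = np.argsort(-sub_scores, kind="stable")
            ranked = sub_labels[order]
            for X in cfg.top_percents:
                ef = enrichment_factor(ranked, X)
                per_repeat.setdefault((X, r), []).append(ef)
        for X in cfg.top_percents:
            mean_ef[(X, r)] = float(np.mean(per_repeat[(X, r)]))
    return EnrichmentResult(
        mean_ef=mean_ef,
        per_repeat_ef=per_repeat,
        rdta_max=rdta_max(active_idx.size, decoy_idx.size),
    )


# -- default similarity functions (injected into similarity_filter) ---------

def protein_sequence_identity(seq1: str, seq2: str) -> float:
    """Global-alignment sequence identity in [0, 1] (BLOSUM62, Biopython)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq1, seq2)[0]
    matches = sum(
        1
        for a, b in zip(str(aln[0]), str(aln[1]))
        if a == b and a != "-"
    )
    length = max(len(str(aln[0])), 1)
    return matches / length


def ligand_tanimoto(mol1, mol2) -> float:
    """Tanimoto similarity of hashed atom-pair fingerprints (RDKit)."""
    from rdkit.Chem import rdFingerprintGenerator
    from rdkit.DataStructs import TanimotoSimilarity

    gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=2048)
    return float(TanimotoSimilarity(gen.GetFingerprint(mol1), gen.GetFingerprint(mol2)))
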