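"""Cross-validation protocols, ROC/AUC, and per-disease candidate ranking.

Two protocols are implemented over the known-association entries of the
binary matrix Y:

* global leave-one-out: each known pair is zeroed in turn, the whole
  pipeline (GIP kernels, similarity integration, WKNKN, factorization) is
  re-run on the masked matrix, and the held-out pair's score is pooled into
  a single ROC against the scores of all never-observed pairs taken from one
  full-data fit;
* repeated 5-fold: known pairs are partitioned into five near-equal folds
  per repeat; each fold is zeroed, the pipeline re-run, and the fold's
  positives are pooled with the unknown candidates scored by the same fold's
  fit into one ROC per repeat; the mean AUC over repeats is reported.

Everything derived from Y (GIP profiles, WKNKN neighbor sets) is recomputed
inside every fold so no information from held-out entries reaches training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import AssociationMatrix
from .factorization import NMFConfig, fit_grl21nmf
from .similarity import (
    gip_kernel_from_associations,
    integrate_disease_similarity,
    integrate_mirna_similarity,
)
from .wknkn import WknknConfig, wknkn_update

__all__ = [
    "CvPlan",
    "EvaluationReport",
    "roc_auc",
    "run_pipeline",
    "global_loocv",
    "five_fold_cv",
    "top_candidates",
]


@dataclass
class CvPlan:
    scheme: str  # "loocv" | "fivefold"
    repeats: int
    seed: int
    fold_assignments: list[np.ndarray] = field(default_factory=list)


@dataclass
class EvaluationReport:
    auc: float
    roc_points: np.ndarray  # (n_points, 2) of (FPR, TPR)
    per_fold_auc: list[float]
    plan: CvPlan
    manifest: dict = field(default_factory=dict)


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """ROC by threshold sweep and its trapezoidal AUC.

    Tied scores are grouped into a single threshold step, which makes the
    trapezoidal area equal to the Mann-Whitney statistic with ties counted
    as one half.  Requires at least one positive and one negative label.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int(np.count_nonzero(labels == 1))
    n_neg = int(np.count_nonzero(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # end-of-group positions for runs of equal score
    boundaries = np.nonzero(np.diff(s))[0]
    idx = np.r_[boundaries, len(s) - 1]
    tp = np.cumsum(y == 1)[idx]
    fp = np.cumsum(y == 0)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


@dataclass(frozen=True)
class PipelineConfig:
    """Similarity-integration weights plus the WKNKN and NMF settings."""

    theta1: float = 1.0
    theta2: float = 0.0
    gamma1: float = 1.0
    gamma2: float = 0.0
    beta_prime_m: float = 1.0
    beta_prime_d: float = 1.0
    wknkn: WknknConfig = field(default_factory=WknknConfig)
    nmf: NMFConfig = field(default_factory=NMFConfig)
    apply_wknkn: bool = True


def run_pipeline(Y_train: np.ndarray, mirna_functional: np.ndarray,
                 disease_semantic: np.ndarray,
                 config: PipelineConfig | None = None) -> np.ndarray:
    """Full scoring pipeline on a (possibly CV-masked) binary matrix.

    Recomputes the GIP kernels from ``Y_train``, integrates them with the
    functional/semantic similarities, runs WKNKN, fits the factorization and
    returns the score matrix W @ H.T.  Nothing derived from held-out (zeroed)
    entries enters training.
    """
    config = config or PipelineConfig()
    Y_train = np.asarray(Y_train, float)
    GM = gip_kernel_from_associations(Y_train, "mirna", config.beta_prime_m)
    GD = gip_kernel_from_associations(Y_train, "disease", config.beta_prime_d)
    SM = integrate_mirna_similarity(mirna_functional, GM, config.theta1, config.theta2)
    SD = integrate_disease_similarity(disease_semantic, GD, config.gamma1, config.gamma2)
    Y_aug = wknkn_update(Y_train, SM, SD, config.wknkn) if config.apply_wknkn else Y_train
    result = fit_grl21nmf(Y_aug, SM, SD, config.nmf)
    return result.scores


def _known_pairs(Y: np.ndarray) -> np.ndarray:
    return np.argwhere(Y == 1)


def global_loocv(Y: np.ndarray, mirna_functional: np.ndarray,
                 disease_semantic: np.ndarray,
                 config: PipelineConfig | None = None,
                 subsample: int | None = None, seed: int = 0) -> EvaluationReport:
    """Global leave-one-out over the known associations.

    Each (optionally subsampled) known pair is zeroed and re-scored by its
    own pipeline run; candidate (negative) scores come from one fit on the
    complete data.  ``subsample`` caps the number of leave-out refits for
    desk-scale runs; the pairs are chosen by the given seed.
    """
    config = config or PipelineConfig()
    Y = np.asarray(Y, float)
    pairs = _known_pairs(Y)
    if len(pairs) < 2:
        raise ValueError("need at least two known associations")
    if subsample is not None:
        if subsample > len(pairs):
            raise ValueError(f"subsample {subsample} exceeds {len(pairs)} known pairs")
        rng = np.random.default_rng(seed)
        pairs = pairs[rng.choice(len(pairs), size=subsample, replace=False)]

    full_scores = run_pipeline(Y, mirna_functional, disease_semantic, config)
    candidate_mask = Y == 0
    neg_scores = full_scores[candidate_mask]

    pos_scores = np.empty(len(pairs))
    for t, (i, j) in enumerate(pairs):
        Y_train = Y.copy()
        Y_train[i, j] = 0.0
        scores = run_pipeline(Y_train, mirna_functional, disease_semantic, config)
        pos_scores[t] = scores[i, j]

    auc, roc = roc_auc(
        np.r_[pos_scores, neg_scores],
        np.r_[np.ones(len(pos_scores), int), np.zeros(len(neg_scores), int)],
    )
    plan = CvPlan(scheme="loocv", repeats=1, seed=seed,
                  fold_assignments=[np.arange(len(pairs))])
    manifest = {"subsample": subsample, "n_known": int(len(_known_pairs(Y))),
                "n_tested": int(len(pairs))}
    return EvaluationReport(auc=auc, roc_points=roc, per_fold_auc=[auc],
                            plan=plan, manifest=manifest)


def five_fold_cv(Y: np.ndarray, mirna_functional: np.ndarray,
                 disease_semantic: np.ndarray,
                 config: PipelineConfig | None = None,
                 repeats: int = 100, seed: int = 0, n_folds: int = 5,
                 refold: bool = True) -> EvaluationReport:
    """Repeated five-fold cross-validation over the known associations.

    Per repeat the known pairs are split into ``n_folds`` folds whose sizes
    differ by at most one; per fold the pipeline is re-run on the masked
    matrix and fold positives are pooled with the unknown candidates (scored
    by the same fold's fit) into one ROC.  The reported AUC is the mean over
    repeats.  ``refold=False`` is the laxer variant that reuses the full-data
    GIP kernels inside folds (for sensitivity analysis only).
    """
    config = config or PipelineConfig()
    Y = np.asarray(Y, float)
    pairs = _known_pairs(Y)
    if len(pairs) < n_folds:
        raise ValueError(f"need at least {n_folds} known associations")
    rng = np.random.default_rng(seed)
    candidate_mask = Y == 0

    lax_sm = lax_sd = None
    if not refold:
        GM = gip_kernel_from_associations(Y, "mirna", config.beta_prime_m)
        GD = gip_kernel_from_associations(Y, "disease", config.beta_prime_d)
        lax_sm = integrate_mirna_similarity(mirna_functional, GM, config.theta1, config.theta2)
        lax_sd = integrate_disease_similarity(disease_semantic, GD, config.gamma1, config.gamma2)

    per_repeat_auc: list[float] = []
    assignments: list[np.ndarray] = []
    for _ in range(repeats):
        perm = rng.permutation(len(pairs))
        fold_of = np.empty(len(pairs), dtype=int)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            fold_of[chunk] = f
        assignments.append(fold_of)

        all_scores: list[np.ndarray] = []
        all_labels: list[np.ndarray] = []
        for f in range(n_folds):
            test = pairs[fold_of == f]
            Y_train = Y.copy()
            Y_train[test[:, 0], test[:, 1]] = 0.0
            if refold:
                scores = run_pipeline(Y_train, mirna_functional, disease_semantic, config)
            else:
                Y_aug = (wknkn_update(Y_train, lax_sm, lax_sd, config.wknkn)
                         if config.apply_wknkn else Y_train)
                scores = fit_grl21nmf(Y_aug, lax_sm, lax_sd, config.nmf).scores
            all_scores.append(scores[test[:, 0], test[:, 1]])
            all_labels.append(np.ones(len(test), int))
            all_scores.append(scores[candidate_mask])
            all_labels.append(np.zeros(int(candidate_mask.sum()), int))
        auc, _ = roc_auc(np.concatenate(all_scores), np.concatenate(all_labels))
        per_repeat_auc.append(auc)

    mean_auc = float(np.mean(per_repeat_auc))
    # ROC points of the last repeat are representative; the headline number
    # is the mean AUC across repeats.
    plan = CvPlan(scheme="fivefold", repeats=repeats, seed=seed,
                  fold_assignments=assignments)
    manifest = {"n_known": int(len(pairs)), "n_folds": n_folds, "refold": refold}
    return EvaluationReport(auc=mean_auc, roc_points=np.empty((0, 2)),
                            per_fold_auc=per_repeat_auc, plan=plan, manifest=manifest)


def top_candidates(scores: np.ndarray, assoc: AssociationMatrix,
                   disease_id: str, k: int = 50) -> list[tuple[str, float]]:
    """Top-k unconfirmed miRNAs for one disease, by score then id.

    Candidates are the miRNAs with no known association to the disease; ties
    in score are broken by ascending miRNA identifier.
    """
    try:
        j = assoc.disease_ids.index(disease_id)
    except ValueError:
        raise KeyError(f"unknown disease id {disease_id!r}") from None
    scores = np.asarray(scores, float)
    ranked = sorted(
        ((assoc.mirna_ids[i], float(scores[i, j]))
         for i in range(assoc.n_mirnas) if assoc.values[i, j] == 0),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:k]
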