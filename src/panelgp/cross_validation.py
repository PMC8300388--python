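"""Repeated k-fold cross-validation of GEBV accuracy.

Accuracy is the Pearson correlation between the phenotypes (EBVs) and the
held-out GEBVs of all individuals, pooled over the k validation folds of one
repeat — one accuracy value per repeat.  Variance components are estimated
fresh on every training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeDataset, PhenotypeTable, subset_markers
from .gblup_engine import VarianceComponents, ai_reml, build_grm, solve_mme
from .marker_pruning import PanelSelection


@dataclass
class CVResult:
    """Accuracies and per-fold variance components of a repeated k-fold CV."""

    accuracies: np.ndarray                 # one pooled correlation per repeat
    fold_assignments: list[np.ndarray]     # per repeat: fold label per individual
    variance_components: list[list[VarianceComponents]]  # [repeat][fold]
    n_excluded_folds: int = 0
    seed: int | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 \
            else 0.0


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random partition of n individuals into k folds of near-equal size.

    Returns a length-n array of fold labels in [0, k); fold sizes differ by
    at most one.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} individuals into {k} folds")
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(k), n // k + 1)[:n]
    rng.shuffle(labels)
    return labels


def cv_accuracy(
    dataset: GenotypeDataset,
    phenotypes: PhenotypeTable,
    panel: PanelSelection | None = None,
    trait: str | None = None,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold CV accuracy of GBLUP on one panel.

    Per repeat: individuals are split into ``n_folds`` folds; for each fold
    the model (AI-REML variance components + MME) is fitted on the other
    folds and the held-out individuals' GEBVs are collected; the repeat's
    accuracy is the Pearson correlation of the pooled held-out GEBVs with the
    phenotype vector.  Repeat r uses seed ``seed + r``.  Folds whose REML did
    not converge are recorded and excluded from pooling with a warning.
    """
    if panel is not None:
        dataset = subset_markers(dataset, panel.indices)
    trait = trait or phenotypes.traits[0]
    y = phenotypes.values_for(trait, dataset.samples)
    n = dataset.n_individuals

    grm = build_grm(dataset)
    accuracies = np.empty(n_repeats)
    assignments: list[np.ndarray] = []
    vcs: list[list[VarianceComponents]] = []
    n_excluded = 0

    for rep in range(n_repeats):
        folds = make_folds(n, n_folds, seed + rep)
        assignments.append(folds)
        gebv = np.full(n, np.nan)
        rep_vcs: list[VarianceComponents] = []
        for f in range(n_folds):
            val = np.flatnonzero(folds == f)
            train = np.flatnonzero(folds != f)
            grm_train = _subset_grm(grm, train)
            vc = ai_reml(y[train], grm_train)
            rep_vcs.append(vc)
            if not vc.converged:
                n_excluded += 1
                warnings.warn(
                    f"REML did not converge (repeat {rep}, fold {f}); "
                    "fold excluded from pooling"
                )
                continue
            fit = solve_mme(y[train], grm, vc, train_indices=train)
            gebv[val] = fit.g_hat[val]
        ok = ~np.isnan(gebv)
        accuracies[rep] = float(np.corrcoef(gebv[ok], y[ok])[0, 1])
        vcs.append(rep_vcs)

    return CVResult(accuracies, assignments, vcs, n_excluded, seed)


def _subset_grm(grm, indices):
    from .gblup_engine import GRM

    return GRM(grm.matrix[np.ix_(indices, indices)],
               [grm.samples[i] for i in indices], grm.denominator)
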