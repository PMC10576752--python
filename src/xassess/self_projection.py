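"""Self-projection accuracy, the ALCS overcorrection metric, and label transfer.

Self-projection trains a multinomial logistic classifier on half of a
labelled dataset and measures accuracy on the held-out half: a proxy for
how distinguishable the cell-type labels are on a given representation.

ALCS (accuracy loss of cell-type self-projection) is, per species, the
drop in self-projection accuracy from that species' own unintegrated
representation to the integrated one:

    ALCS = test_accuracy(original) − test_accuracy(integrated)

A large positive ALCS means integration blended cell types that were
distinguishable before — the signature of overcorrection. Cross-species
label transfer trains the same classifier on one species' integrated
coordinates and predicts another's, scored by ARI against the target's
own annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from xassess.errors import MetricNotApplicableError, ValidationError
from xassess.metrics import IntegrationOutput, standard_reduce

#: classifier hyperparameters, fixed for reproducibility
LOGREG_PARAMS = dict(penalty="l2", C=1.0, max_iter=1000, solver="lbfgs")


@dataclass(frozen=True)
class SelfProjectionResult:
    test_accuracy: float
    representation_id: str
    seed: int
    split_fraction: float = 0.5
    n_labels_dropped: int = 0


@dataclass
class AlcsReport:
    """Per-species ALCS values plus the accuracies they difference."""

    per_species: dict[str, float]
    accuracy_original: dict[str, float]
    accuracy_integrated: dict[str, float]


def _fit_logreg(X: np.ndarray, y: np.ndarray, seed: int) -> LogisticRegression:
    clf = LogisticRegression(random_state=seed, **LOGREG_PARAMS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def self_projection_accuracy(
    rep: np.ndarray,
    labels: Sequence,
    seed: int = 0,
    representation_id: str = "",
) -> SelfProjectionResult:
    """Held-out accuracy of a multinomial logistic self-projection.

    Cells are split 50/50 stratified by label with the given seed; labels
    with a single cell are dropped (they cannot be stratified) with a
    warning. A single surviving label is not a classification problem.
    """
    X = np.asarray(rep, dtype=np.float64)
    y = np.asarray(labels, dtype=object)
    uniq, counts = np.unique(y, return_counts=True)
    singletons = uniq[counts < 2]
    if len(singletons):
        warnings.warn(
            f"dropping labels with a single cell: {sorted(singletons)}",
            stacklevel=2,
        )
        keep = ~np.isin(y, singletons)
        X, y = X[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise MetricNotApplicableError("self-projection needs at least two labels")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=0.5, stratify=y, random_state=seed
    )
    clf = _fit_logreg(X_train, y_train, seed)
    accuracy = float(np.mean(clf.predict(X_test) == y_test))
    return SelfProjectionResult(
        test_accuracy=accuracy,
        representation_id=representation_id,
        seed=seed,
        n_labels_dropped=int(len(singletons)),
    )


def alcs(
    originals: Mapping[str, ad.AnnData],
    integrated: IntegrationOutput,
    seed: int = 0,
    celltype_key: str = "cell_type",
    n_dims: int = 20,
) -> AlcsReport:
    """Accuracy loss of cell-type self-projection, per species.

    ``originals`` maps species id to that species' raw count matrix; the
    original accuracy is measured on its own standard reduction (first
    ``n_dims`` PCs) and the integrated accuracy on that species' rows of
    the integrated representation. Graph-only outputs are not applicable.
    """
    rep_int = integrated.representation(n_dims)  # raises for knn_graph
    species_col = integrated.cell_meta["species"].to_numpy()
    labels_int = integrated.cell_meta[celltype_key].to_numpy()
    per_species: dict[str, float] = {}
    acc_orig: dict[str, float] = {}
    acc_int: dict[str, float] = {}
    for sp_id, adata in originals.items():
        rows = np.flatnonzero(species_col == sp_id)
        if len(rows) != adata.n_obs:
            raise ValidationError(
                f"integrated output covers {len(rows)} cells of species {sp_id!r}, "
                f"original has {adata.n_obs}"
            )
        rep_orig = standard_reduce(adata)[:, :n_dims]
        res_orig = self_projection_accuracy(
            rep_orig, adata.obs[celltype_key].to_numpy(), seed=seed,
            representation_id=f"original:{sp_id}",
        )
        res_int = self_projection_accuracy(
            rep_int[rows], labels_int[rows], seed=seed,
            representation_id=f"integrated:{integrated.strategy}:{sp_id}",
        )
        acc_orig[sp_id] = res_orig.test_accuracy
        acc_int[sp_id] = res_int.test_accuracy
        per_species[sp_id] = res_orig.test_accuracy - res_int.test_accuracy
    return AlcsReport(
        per_species=per_species,
        accuracy_original=acc_orig,
        accuracy_integrated=acc_int,
    )


def transfer_labels(
    integrated: IntegrationOutput,
    src_species: str,
    tgt_species: str,
    seed: int = 0,
    celltype_key: str = "cell_type",
    n_dims: int = 20,
) -> tuple[np.ndarray, float, bool]:
    """Cross-species annotation transfer on the integrated representation.

    Trains the multinomial logistic classifier on all source-species cells
    and predicts every target-species cell; returns the predicted labels,
    the ARI against the target's original annotation, and a coverage flag
    (True iff every cell type shared by both species appears among the
    predictions).
    """
    from xassess.metrics import ari as _ari

    rep = integrated.representation(n_dims)
    species = integrated.cell_meta["species"].to_numpy()
    labels = integrated.cell_meta[celltype_key].to_numpy()
    src_rows = np.flatnonzero(species == src_species)
    tgt_rows = np.flatnonzero(species == tgt_species)
    if len(src_rows) == 0 or len(tgt_rows) == 0:
        raise ValidationError(
            f"species {src_species!r} or {tgt_species!r} absent from the output"
        )
    clf = _fit_logreg(rep[src_rows], labels[src_rows], seed)
    predicted = clf.predict(rep[tgt_rows])
    score = _ari(labels[tgt_rows], predicted)
    shared = set(labels[src_rows]) & set(labels[tgt_rows])
    covered = shared <= set(predicted)
    return predicted, score, covered


def transfer_all_pairs(
    integrated: IntegrationOutput,
    seed: int = 0,
    celltype_key: str = "cell_type",
    n_dims: int = 20,
) -> tuple[float, dict[tuple[str, str], float]]:
    """Mean transfer ARI over all ordered species pairs, plus per-pair values."""
    species = sorted(set(integrated.cell_meta["species"]))
    if len(species) < 2:
        raise MetricNotApplicableError("annotation transfer needs at least two species")
    per_pair: dict[tuple[str, str], float] = {}
    for src, tgt in permutations(species, 2):
        _, score, _ = transfer_labels(
            integrated, src, tgt, seed=seed, celltype_key=celltype_key, n_dims=n_dims
        )
        per_pair[(src, tgt)] = score
    return float(np.mean(list(per_pair.values()))), per_pair
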