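"""HI-gene expression signatures: clustering, scoring, minimal search.

Samples are clustered on a candidate gene set (per-gene z-scores,
hierarchical clustering, tree cut at two clusters).  The default is
Ward linkage on euclidean distance between z-score profiles: the class
signal of a dosage signature is a shared downshift across all its
genes, which a correlation distance would subtract away with the
per-sample mean (1 - Pearson with average linkage remains available
for pattern-shaped signatures).  Each cluster takes the karyotype
of its majority; per-class error rates count samples landing in a
cluster mapped to the opposite class.  A minimal signature is searched
by greedy forward selection minimizing the summed class error rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .hi_expression import DELETED, DIPLOID

#: minimal four-gene signature reported for distinguishing -7/del7q from
#: diploid myeloid neoplasms; shipped for scoring user cohorts.
PRESET_SIGNATURES: dict[str, tuple[str, ...]] = {
    "min4": ("AGK", "ARPC1A", "ZNF277", "ZNF398"),
}


class ConstantGeneWarning(UserWarning):
    """A zero-variance gene was dropped before clustering."""


@dataclass(frozen=True)
class SignatureReport:
    genes: tuple[str, ...]
    linkage: str
    metric: str
    assignments: pd.Series  # cluster id (1/2) per sample
    cluster_classes: Mapping[int, str]  # majority karyotype per cluster
    error_rate_deleted: float
    error_rate_diploid: float

    @property
    def total_error(self) -> float:
        return self.error_rate_deleted + self.error_rate_diploid

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "linkage": self.linkage,
            "metric": self.metric,
            "cluster_classes": {str(k): v for k, v in self.cluster_classes.items()},
            "error_rate_deleted": self.error_rate_deleted,
            "error_rate_diploid": self.error_rate_diploid,
            "total_error": self.total_error,
        }


def _zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each gene across samples; return (scored, dropped constants)."""
    sd = values.std(axis=1, ddof=1)
    constant = list(values.index[(sd == 0) | sd.isna()])
    kept = values.drop(index=constant)
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[kept.index], axis=0)
    return z, constant


def cluster_and_score(
    values: pd.DataFrame,
    labels: pd.Series,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> SignatureReport:
    """Cluster samples on a gene set and score against karyotype labels.

    ``values`` is genes x samples restricted to the signature genes;
    ``labels`` maps samples to ``deleted`` / ``diploid_NK``.  With a
    single usable gene the correlation distance is undefined and
    euclidean distance on the z-scores is used instead.

    When both clusters share the same majority karyotype, every sample
    of the minority class is counted as misclassified.
    """
    values = values[sorted(values.columns)]  # order-invariant scoring
    values = values.loc[sorted(values.index)]
    lab = labels[values.columns]
    for cls in (DELETED, DIPLOID):
        if (lab == cls).sum() < 2:
            raise ValueError(f"need >= 2 samples of class {cls!r}")
    z, constant = _zscore_rows(values)
    if constant:
        warnings.warn(
            f"dropped {len(constant)} constant gene(s): {constant[:5]}",
            ConstantGeneWarning,
            stacklevel=2,
        )
    if len(values) >= 2 and len(z) < 2:
        raise ValueError("fewer than 2 usable (non-constant) genes")
    if len(z) < 1:
        raise ValueError("no usable (non-constant) gene")
    used_metric = metric
    if len(z) < 2 and metric == "correlation":
        used_metric = "euclidean"  # correlation needs >= 2 features
    X = z.to_numpy().T  # samples x genes
    dist = pdist(X, metric=used_metric)
    tree = scipy_linkage(dist, method=linkage)
    clusters = pd.Series(
        fcluster(tree, t=2, criterion="maxclust"), index=values.columns
    )
    cluster_classes: dict[int, str] = {}
    for cid in sorted(clusters.unique()):
        members = lab[clusters == cid]
        n_del = int((members == DELETED).sum())
        n_dip = int((members == DIPLOID).sum())
        cluster_classes[int(cid)] = DELETED if n_del > n_dip else DIPLOID

    def _error(cls: str) -> float:
        in_class = lab == cls
        predicted = clusters.map(cluster_classes)
        return float((predicted[in_class] != cls).mean())

    return SignatureReport(
        genes=tuple(z.index),
        linkage=linkage,
        metric=used_metric,
        assignments=clusters,
        cluster_classes=cluster_classes,
        error_rate_deleted=_error(DELETED),
        error_rate_diploid=_error(DIPLOID),
    )


def minimal_signature(
    candidates: Sequence[str],
    values: pd.DataFrame,
    labels: pd.Series,
    max_size: int = 10,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> SignatureReport:
    """Greedy forward search for a small signature with minimal total error.

    Starting from the empty set, repeatedly add the candidate gene that
    most reduces ``error_rate_deleted + error_rate_diploid`` (ties
    broken alphabetically); stop when no addition reduces the total
    error or ``max_size`` is reached.
    """
    if not candidates:
        raise ValueError("candidate gene set is empty")
    pool = sorted(set(candidates) & set(values.index))
    if not pool:
        raise ValueError("no candidate gene present in the expression matrix")
    selected: list[str] = []
    best_report: SignatureReport | None = None
    best_error = np.inf
    while len(selected) < max_size:
        round_best: tuple[float, str, SignatureReport] | None = None
        for gene in pool:
            if gene in selected:
                continue
            trial = selected + [gene]
            try:
                report = cluster_and_score(
                    values.loc[trial], labels, linkage=linkage, metric=metric
                )
            except ValueError:
                continue  # e.g. all trial genes constant
            key = (report.total_error, gene)
            if round_best is None or key < (round_best[0], round_best[1]):
                round_best = (report.total_error, gene, report)
        if round_best is None or round_best[0] >= best_error:
            break
        best_error, gene, best_report = round_best[0], round_best[1], round_best[2]
        selected.append(gene)
        if best_error == 0.0:
            break
    if best_report is None:
        raise ValueError("no usable signature could be formed from the candidates")
    return best_report
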