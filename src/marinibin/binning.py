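"""Population-genome bin construction.

SAG signatures are reduced to three principal components and clustered
hierarchically (Euclidean distance, average linkage) into clade-level
SAG-clusters; metagenome contigs that align to a SAG at high identity over a
substantial summed length are then classified among the SAG-clusters by
linear discriminant analysis on all 256 tetranucleotide z-scores.

The discriminant is Gaussian with shared covariance: class means and a
pooled within-class covariance Sigma estimated from the per-contig training
rows, regularised as Sigma + eps*I with eps = reg_factor * trace(Sigma)/256
so the 256-dimensional fit stays invertible with few SAG contigs.  Priors
are equal across classes — SAG counts per clade reflect sampling effort, not
abundance.  Exact score ties break to the lexicographically smallest class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger("marinibin")

DEFAULT_MIN_IDENTITY = 95.0     # percent nucleotide identity to a SAG contig
DEFAULT_MIN_ALN_LEN = 5_000     # summed alignment bp per contig-SAG pair
# eps = reg_factor * trace(Sigma) / n_features.  With p=256 features and a
# few hundred training contigs the pooled scatter is singular, so the ridge
# must be large enough to damp its null space, not merely make the solve
# succeed; 1e-2 of the average eigenvalue is on the order of what
# Ledoit-Wolf shrinkage selects on such data.
DEFAULT_REG_FACTOR = 1e-2


# ---------------------------------------------------------------------------
# PCA


@dataclass
class Pca3Result:
    projection: np.ndarray          # (n, n_components), n_components <= 3
    loadings: np.ndarray            # (p, n_components)
    explained_variance: np.ndarray  # (n_components,)
    low_rank: bool = False          # fewer than 3 usable components


def pca3(z_matrix) -> Pca3Result:
    """Project signature rows onto the first three principal components.

    Components are ordered by decreasing explained variance, with the sign
    convention that each loading vector's largest-magnitude coordinate is
    positive.  Rank-deficient input yields fewer components and sets
    ``low_rank``.
    """
    X = check_array(np.asarray(z_matrix, dtype=float))
    if X.shape[0] < 4:
        raise ValueError("pca3 requires at least 4 rows")
    n_comp = min(3, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    proj = pca.fit_transform(X)
    # drop numerically-zero components (rank < 3)
    ev = pca.explained_variance_
    tol = max(ev[0], 1.0) * 1e-12
    keep = ev > tol
    proj, ev = proj[:, keep], ev[keep]
    loadings = pca.components_[keep].T  # (p, m)
    low_rank = proj.shape[1] < 3
    if low_rank:
        logger.warning("pca3: input rank %d < 3", proj.shape[1])
    # deterministic sign: largest-|loading| coordinate positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            proj[:, j] *= -1
    return Pca3Result(projection=proj, loadings=loadings,
                      explained_variance=ev, low_rank=low_rank)


# ---------------------------------------------------------------------------
# SAG clustering


@dataclass
class SagCluster:
    """One clade-level training group of SAGs."""

    cluster_id: str
    members: list[str]
    centroid: np.ndarray
    clade_label: str | None = None


class SagClusterer(ClusterMixin, BaseEstimator):
    """Agglomerative clustering of SAG signatures in 3-D PC space.

    Euclidean distance, average linkage, dendrogram cut to exactly
    ``n_clusters``.  Cluster labels are re-numbered in order of first
    appearance, so the labelling is deterministic in the row order.
    """

    def __init__(self, n_clusters: int = 2, use_pca: bool = True):
        self.n_clusters = n_clusters
        self.use_pca = use_pca

    def fit(self, X, y=None):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        X = check_array(np.asarray(X, dtype=float))
        if self.n_clusters > X.shape[0]:
            raise ValueError("n_clusters cannot exceed the number of points")
        pts = pca3(X).projection if self.use_pca and X.shape[1] > 3 else X
        if X.shape[0] == 1:
            raw = np.array([1])
        else:
            Z = linkage(pts, method="average", metric="euclidean")
            raw = fcluster(Z, t=self.n_clusters, criterion="maxclust")
        # renumber by first appearance
        order: dict[int, int] = {}
        labels = np.empty(len(raw), dtype=int)
        for i, r in enumerate(raw):
            order.setdefault(r, len(order))
            labels[i] = order[r]
        self.labels_ = labels
        self.points_ = pts
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_sags(
    projected: np.ndarray,
    n_clusters: int,
    sag_ids: list[str] | None = None,
) -> list[SagCluster]:
    """Cluster already-projected SAG points into ``n_clusters`` SAG-clusters."""
    projected = np.asarray(projected, dtype=float)
    if sag_ids is None:
        sag_ids = [f"sag{i}" for i in range(projected.shape[0])]
    labels = SagClusterer(n_clusters=n_clusters, use_pca=False).fit_predict(projected)
    clusters = []
    for lab in range(labels.max() + 1):
        idx = np.flatnonzero(labels == lab)
        clusters.append(SagCluster(
            cluster_id=f"cluster{lab}",
            members=[sag_ids[i] for i in idx],
            centroid=projected[idx].mean(axis=0),
        ))
    return clusters


# ---------------------------------------------------------------------------
# prefilter


def prefilter_contigs(
    hits: pd.DataFrame,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    sag_of: pd.Series | dict | None = None,
    min_contig_len: int | None = DEFAULT_MIN_ALN_LEN,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Eligible (contig, SAG) pairs for supervised binning.

    A pair qualifies when the summed alignment length of its hits at
    >= ``min_identity`` percent identity reaches ``min_aln_len`` bp; the
    contig itself must additionally be at least ``min_contig_len`` bp when a
    ``qlen`` column is present.  Bounds are inclusive unless
    ``inclusive=False`` (strict >).  Rows with unusable pident/length are
    skipped with a logged count; more than 10% malformed rows is an error.
    """
    df = hits.copy()
    n0 = len(df)
    for col in ("pident", "length"):
        if col not in df.columns:
            raise ValueError(f"hits table lacks required column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["pident"].isna() | df["length"].isna() | (df["pident"] < 0) | (
        df["pident"] > 100) | (df["length"] <= 0)
    if bad.sum() > 0.10 * max(n0, 1):
        raise ValueError(f"{bad.sum()} of {n0} hit rows malformed (> 10%)")
    if bad.any():
        logger.warning("prefilter_contigs: skipped %d malformed rows", int(bad.sum()))
        df = df[~bad]

    keep = df["pident"] >= min_identity if inclusive else df["pident"] > min_identity
    df = df[keep]
    if sag_of is not None:
        df = df.assign(sag_id=df["sseqid"].map(dict(sag_of)))
        if df["sag_id"].isna().any():
            missing = sorted(df.loc[df["sag_id"].isna(), "sseqid"].unique()[:5])
            raise ValueError(f"sseqid(s) not in sag_of mapping: {missing}")
    else:
        df = df.assign(sag_id=df["sseqid"])
    summed = (
        df.groupby(["qseqid", "sag_id"], sort=True)["length"].sum().reset_index()
    )
    ok = (summed["length"] >= min_aln_len if inclusive
          else summed["length"] > min_aln_len)
    summed = summed[ok]
    if min_contig_len is not None and "qlen" in hits.columns:
        qlen = hits.groupby("qseqid")["qlen"].first()
        summed = summed[summed["qseqid"].map(qlen) >= min_contig_len]
    return summed.rename(columns={"qseqid": "contig_id", "length": "summed_aln_len"}
                         ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# LDA


class LinearDiscriminantBinner(ClassifierMixin, BaseEstimator):
    """Linear discriminant classifier with pooled regularised covariance and
    equal priors, for assigning contig z-vectors to SAG-clusters.

    Fitted attributes: ``classes_``, ``means_`` (k, p), ``covariance_``
    (p, p, regularised), ``priors_``, ``coef_``/``intercept_`` for the linear
    scores, and ``confusion_`` (training confusion matrix).
    """

    def __init__(self, reg_factor: float = DEFAULT_REG_FACTOR):
        self.reg_factor = reg_factor

    def fit(self, X, y):
        X = check_array(np.asarray(X, dtype=float))
        y = np.asarray(y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_idx)
        small = [str(classes[i]) for i in np.flatnonzero(counts < 2)]
        if small:
            raise ValueError(f"class(es) with fewer than 2 training rows: {small}")
        n, p = X.shape
        means = np.vstack([X[y_idx == i].mean(axis=0) for i in range(len(classes))])
        resid = X - means[y_idx]
        cov = resid.T @ resid / (n - len(classes))
        eps = self.reg_factor * np.trace(cov) / p
        cov = cov + eps * np.eye(p)
        # symmetric PD solve for the linear discriminant weights
        w = np.linalg.solve(cov, means.T).T            # (k, p)
        b = -0.5 * np.einsum("ij,ij->i", w, means)     # (k,)
        self.classes_ = classes
        self.means_ = means
        self.covariance_ = cov
        self.priors_ = np.full(len(classes), 1.0 / len(classes))
        self.coef_ = w
        self.intercept_ = b
        self.n_features_in_ = p
        pred = self.predict(X)
        self.confusion_ = pd.crosstab(
            pd.Series(y, name="true"), pd.Series(pred, name="predicted"),
            dropna=False,
        ).reindex(index=classes, columns=classes, fill_value=0)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(np.asarray(X, dtype=float))
        return X @ self.coef_.T + self.intercept_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        # argmax returns the first (lexicographically smallest, since
        # classes_ is sorted) class on exact ties
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass
class LdaModel:
    """Fitted discriminant packaged with its training confusion matrix."""

    estimator: LinearDiscriminantBinner
    confusion: pd.DataFrame

    @property
    def classes(self) -> np.ndarray:
        return self.estimator.classes_


def train_lda(z_matrix, labels, reg_factor: float = DEFAULT_REG_FACTOR) -> LdaModel:
    est = LinearDiscriminantBinner(reg_factor=reg_factor).fit(z_matrix, labels)
    return LdaModel(estimator=est, confusion=est.confusion_)


# ---------------------------------------------------------------------------
# contig assignment


@dataclass
class PopulationBin:
    """A clade-level composite of training SAGs plus assigned contigs."""

    bin_id: str
    training_sags: list[str] = field(default_factory=list)
    contigs: dict[str, float] = field(default_factory=dict)  # contig -> score
    total_length: int = 0


def assign_contigs(
    model: LdaModel | LinearDiscriminantBinner,
    contig_z: pd.DataFrame,
    eligible: pd.DataFrame,
    contig_lengths: dict | pd.Series | None = None,
    training_sags: dict[str, list[str]] | None = None,
) -> tuple[list[PopulationBin], pd.DataFrame]:
    """Assign prefilter-eligible contigs to population bins.

    ``contig_z`` is indexed by contig id (256 z-score columns); ``eligible``
    is the prefilter output — only its contigs are classified, each going to
    the class with the highest discriminant score (ties already break
    lexicographically).  Returns the bins and a per-contig assignment table.
    """
    est = model.estimator if isinstance(model, LdaModel) else model
    wanted = sorted(pd.unique(eligible["contig_id"])) if len(eligible) else []
    missing = [c for c in wanted if c not in contig_z.index]
    if missing:
        raise ValueError(f"contig(s) absent from signature matrix: {missing[:10]}")
    bins = {
        str(c): PopulationBin(
            bin_id=str(c),
            training_sags=(training_sags or {}).get(str(c), []),
        )
        for c in est.classes_
    }
    if not wanted:
        return list(bins.values()), pd.DataFrame(
            columns=["contig_id", "bin_id", "score"])
    Z = contig_z.loc[wanted].to_numpy(dtype=float)
    scores = est.decision_function(Z)
    pred_idx = np.argmax(scores, axis=1)
    rows = []
    for cid, k, sc in zip(wanted, pred_idx, scores):
        bin_id = str(est.classes_[k])
        bins[bin_id].contigs[cid] = float(sc[k])
        if contig_lengths is not None:
            bins[bin_id].total_length += int(contig_lengths[cid])
        rows.append((cid, bin_id, float(sc[k])))
    table = pd.DataFrame(rows, columns=["contig_id", "bin_id", "score"])
    return list(bins.values()), table
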