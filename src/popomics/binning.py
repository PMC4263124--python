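"""Composite-genome binning of contigs.

The binning chain is: canonical-pentamer CLR signatures -> Barnes-Hut
t-SNE projection to two dimensions -> expectation-maximisation on a
Gaussian mixture in the embedded plane (means user-initialised or
seeded automatically, covariances initialised as small-diagonal
matrices) -> per-contig arg-max-responsibility bin labels, with an
"unbinned" label below a posterior cutoff.  A second, within-bin pass
over contigs >= 1 kb refines the groups, and a 1-D mixture on log10
read depth can split a bin that merges populations of very different
abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.manifold import TSNE

from .errors import ConsistencyError, DegeneracyError, ParameterError
from .signatures import signature_matrix

logger = logging.getLogger(__name__)

UNBINNED = "unbinned"


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def embed(clr: np.ndarray, perplexity: float = 30.0, seed: int = 0,
          n_iter: int = 1000) -> np.ndarray:
    """Barnes-Hut t-SNE projection of CLR signatures to 2-D.

    Requires at least ``3 * perplexity`` points; identical inputs and seed
    reproduce identical coordinates.
    """
    X = np.asarray(clr, dtype=float)
    if X.ndim != 2:
        raise ParameterError("clr must be a 2-D matrix")
    if X.shape[0] < 3 * perplexity:
        raise ParameterError(
            f"{X.shape[0]} points are too few for perplexity {perplexity} "
            f"(need >= {3 * perplexity:.0f})"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        method="barnes_hut",
        init="pca",
        max_iter=n_iter,
        random_state=seed,
        n_jobs=1,
    )
    return tsne.fit_transform(X)


# ---------------------------------------------------------------------------
# Gaussian mixture via EM
# ---------------------------------------------------------------------------

@dataclass
class MixtureModel:
    """A fitted Gaussian mixture with its EM log-likelihood trace."""

    means: np.ndarray             # (K, d)
    covariances: np.ndarray       # (K, d, d)
    weights: np.ndarray           # (K,)
    log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def _log_prob_components(self, X: np.ndarray) -> np.ndarray:
        """log [ w_k * N(x | mu_k, Sigma_k) ] for every point/component."""
        n, d = X.shape
        out = np.empty((n, self.n_components))
        for k in range(self.n_components):
            cov = self.covariances[k]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise DegeneracyError(k, f"component {k} covariance is singular")
            diff = X - self.means[k]
            maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
            out[:, k] = (
                np.log(self.weights[k])
                - 0.5 * (d * np.log(2 * np.pi) + logdet + maha)
            )
        return out

    def log_likelihood(self, X: np.ndarray) -> float:
        return float(logsumexp(self._log_prob_components(X), axis=1).sum())

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_prob_components(X)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def bic(self, X: np.ndarray) -> float:
        """Bayesian information criterion (lower is better); free parameters
        count means, symmetric covariances and K-1 weights."""
        n, d = X.shape
        k = self.n_components
        n_params = k * d + k * d * (d + 1) // 2 + (k - 1)
        return -2.0 * self.log_likelihood(X) + n_params * np.log(n)


def fit_gmm(points: np.ndarray,
            n_components: int | None = None,
            init_means: np.ndarray | None = None,
            tol: float = 1e-6,
            max_iter: int = 500,
            seed: int = 0,
            init_cov: float = 1.0,
            cov_floor: float = 1e-6) -> MixtureModel:
    """Fit a Gaussian mixture by EM.

    Means are either supplied (``init_means``, one row per component, the
    human-in-the-loop mode) or seeded by k-means++ for a given
    ``n_components``.  Covariances start as ``init_cov * I`` ("small positive
    entries"); a floor of ``cov_floor`` on the diagonal prevents collapse.
    Iteration stops when the relative log-likelihood change drops below
    ``tol`` or after ``max_iter`` EM steps; the trace of the total
    log-likelihood after each step is retained and is non-decreasing.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ParameterError("points must be a 2-D array (n, d)")
    n, d = X.shape
    if init_means is None and n_components is not None and n < n_components:
        raise DegeneracyError(int(n_components) - 1,
                              f"{n} points cannot support {n_components} components")

    if init_means is not None:
        means = np.atleast_2d(np.asarray(init_means, dtype=float)).copy()
        if means.shape[1] != d:
            raise ParameterError("init_means dimensionality does not match points")
        K = means.shape[0]
    else:
        if n_components is None:
            raise ParameterError("provide init_means or n_components")
        K = int(n_components)
        if K < 1:
            raise ParameterError("n_components must be >= 1")
        if K == 1:
            means = X.mean(axis=0, keepdims=True).copy()
        else:
            means, _ = kmeans_plusplus(X, n_clusters=K,
                                       random_state=np.random.RandomState(seed))
            means = np.asarray(means, dtype=float)
    if n < K:
        raise DegeneracyError(K - 1, f"{n} points cannot support {K} components")

    covs = np.tile(np.eye(d) * init_cov, (K, 1, 1))
    weights = np.full(K, 1.0 / K)
    model = MixtureModel(means=means, covariances=covs, weights=weights)

    prev_ll = -np.inf
    for it in range(max_iter):
        resp = model.responsibilities(X)           # E step
        nk = resp.sum(axis=0)
        for k in range(K):
            if nk[k] < 1e-12:
                raise DegeneracyError(k, f"component {k} lost all responsibility")
        model.weights = nk / n                     # M step
        model.means = (resp.T @ X) / nk[:, None]
        for k in range(K):
            diff = X - model.means[k]
            cov = (resp[:, k, None] * diff).T @ diff / nk[k]
            cov.flat[:: d + 1] += cov_floor
            model.covariances[k] = cov
        ll = model.log_likelihood(X)
        model.log_likelihood_trace.append(ll)
        model.n_iter = it + 1
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            model.converged = True
            break
        prev_ll = ll
    return model


def fit_gmm_bic(points: np.ndarray, k_max: int = 10, k_min: int = 1,
                **kwargs) -> MixtureModel:
    """Scan component counts ``k_min..k_max`` and keep the lowest-BIC fit."""
    best: MixtureModel | None = None
    best_bic = np.inf
    X = np.asarray(points, dtype=float)
    for k in range(k_min, k_max + 1):
        if k > X.shape[0]:
            break
        try:
            m = fit_gmm(X, n_components=k, **kwargs)
        except DegeneracyError:
            continue
        b = m.bic(X)
        if b < best_bic:
            best, best_bic = m, b
    if best is None:
        raise DegeneracyError(0, "no mixture size could be fitted")
    return best


# ---------------------------------------------------------------------------
# bin assignment and read recruitment
# ---------------------------------------------------------------------------

def assign_bins(model: MixtureModel, points: np.ndarray, contig_ids: list[str],
                min_posterior: float = 0.5,
                label_prefix: str = "CG") -> pd.DataFrame:
    """Label every contig with its arg-max-responsibility component.

    Contigs whose maximal posterior falls below ``min_posterior`` receive the
    ``unbinned`` label.  Returns columns contig_id, cg_id, posterior.
    """
    resp = model.responsibilities(np.asarray(points, dtype=float))
    comp = resp.argmax(axis=1)
    post = resp.max(axis=1)
    labels = [
        f"{label_prefix}{c + 1}" if p >= min_posterior else UNBINNED
        for c, p in zip(comp, post)
    ]
    return pd.DataFrame({"contig_id": contig_ids, "cg_id": labels, "posterior": post})


def recruit_reads(assignments: pd.DataFrame,
                  counts: pd.DataFrame) -> tuple[pd.Series, int]:
    """Sum per-contig read counts into per-bin totals c_i.

    ``counts`` needs columns ``contig_id`` and ``count``.  Returns
    ``(c_i series indexed by cg_id, residual)`` where the residual is the
    count on unbinned contigs; totals are conserved exactly.
    """
    lab = assignments.set_index("contig_id")["cg_id"]
    unknown = set(counts["contig_id"]) - set(lab.index)
    if unknown:
        raise ConsistencyError(
            f"{len(unknown)} counted contigs unknown to the assignment "
            f"(e.g. {sorted(unknown)[:3]})"
        )
    joined = counts.assign(cg_id=lab.loc[counts["contig_id"]].to_numpy())
    per_cg = joined.groupby("cg_id")["count"].sum()
    residual = int(per_cg.get(UNBINNED, 0))
    return per_cg.drop(index=UNBINNED, errors="ignore"), residual


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class CompositeGenomeBinner(BaseEstimator, ClusterMixin):
    """Cluster contigs into composite genomes from their CLR signatures.

    A scikit-learn style clusterer: ``fit(X)`` takes the (n_contigs, 512)
    CLR signature matrix, embeds it with Barnes-Hut t-SNE and fits a 2-D
    Gaussian mixture by EM.  Exactly one of ``init_means`` (user-picked
    cluster centres in the embedded plane) and ``n_components`` drives the
    mixture size; with both unset the size is chosen by a BIC scan over
    ``2..k_max``.

    Parameters
    ----------
    n_components : int or None
        Number of expected populations (one Gaussian each).
    init_means : array (K, 2) or None
        User-supplied component means in embedding coordinates.
    k_max : int
        Upper bound of the BIC scan in automatic mode.
    perplexity : float
        t-SNE perplexity; at least ``3 * perplexity`` contigs are required.
    min_posterior : float
        Contigs below this maximal posterior are labelled ``-1`` (unbinned).
    tol, max_iter, init_cov : EM controls, see :func:`fit_gmm`.
    random_state : int
        Seed for both the embedding and the mixture initialisation.

    Attributes
    ----------
    embedding_ : (n, 2) t-SNE coordinates.
    mixture_ : fitted :class:`MixtureModel`.
    labels_ : int component index per contig, -1 for unbinned.
    posterior_ : maximal responsibility per contig.
    """

    def __init__(self, n_components=None, init_means=None, k_max=10,
                 perplexity=30.0, n_iter_embed=1000, min_posterior=0.5,
                 tol=1e-6, max_iter=500, init_cov=1.0, random_state=0):
        self.n_components = n_components
        self.init_means = init_means
        self.k_max = k_max
        self.perplexity = perplexity
        self.n_iter_embed = n_iter_embed
        self.min_posterior = min_posterior
        self.tol = tol
        self.max_iter = max_iter
        self.init_cov = init_cov
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.embedding_ = embed(X, perplexity=self.perplexity,
                                seed=self.random_state, n_iter=self.n_iter_embed)
        if self.init_means is not None:
            self.mixture_ = fit_gmm(self.embedding_, init_means=self.init_means,
                                    tol=self.tol, max_iter=self.max_iter,
                                    seed=self.random_state, init_cov=self.init_cov)
        elif self.n_components is not None:
            self.mixture_ = fit_gmm(self.embedding_, n_components=self.n_components,
                                    tol=self.tol, max_iter=self.max_iter,
                                    seed=self.random_state, init_cov=self.init_cov)
        else:
            self.mixture_ = fit_gmm_bic(self.embedding_, k_max=self.k_max, k_min=2,
                                        tol=self.tol, max_iter=self.max_iter,
                                        seed=self.random_state, init_cov=self.init_cov)
        resp = self.mixture_.responsibilities(self.embedding_)
        self.posterior_ = resp.max(axis=1)
        labels = resp.argmax(axis=1)
        labels[self.posterior_ < self.min_posterior] = -1
        self.labels_ = labels
        return self

    def assignments(self, contig_ids: list[str], label_prefix: str = "CG") -> pd.DataFrame:
        """Fitted labels as a tidy (contig_id, cg_id, posterior) table."""
        labels = [
            f"{label_prefix}{l + 1}" if l >= 0 else UNBINNED for l in self.labels_
        ]
        return pd.DataFrame({"contig_id": contig_ids, "cg_id": labels,
                             "posterior": self.posterior_})


# ---------------------------------------------------------------------------
# iterative refinement
# ---------------------------------------------------------------------------

def iterate_binning(sequences: dict[str, str],
                    assignments: pd.DataFrame,
                    round2_min_length: int = 1000,
                    perplexity: float = 30.0,
                    k_max: int = 3,
                    seed: int = 0,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Second binning pass within each first-round group.

    Each group is re-profiled (signature -> embedding -> BIC-chosen mixture)
    using only its contigs of at least ``round2_min_length`` bases; if the
    scan prefers more than one component, the group is split into
    ``<cg>.1, <cg>.2, ...``.  Contigs below the length threshold, and groups
    with too few eligible contigs for the embedding, keep their first-round
    label, so the final labels cover every contig.
    """
    out = assignments.copy()
    out = out.set_index("contig_id")
    for cg, grp in assignments.groupby("cg_id"):
        if cg == UNBINNED:
            continue
        eligible = [c for c in grp["contig_id"] if len(sequences[c]) >= round2_min_length]
        if len(eligible) < 3 * perplexity:
            logger.warning(
                "group %s has %d contigs >= %d bp (< 3*perplexity); passed through",
                cg, len(eligible), round2_min_length,
            )
            continue
        ids, clr, _ = signature_matrix({c: sequences[c] for c in eligible},
                                       pseudocount=pseudocount)
        pts = embed(clr, perplexity=perplexity, seed=seed)
        model = fit_gmm_bic(pts, k_min=1, k_max=k_max, seed=seed)
        if model.n_components == 1:
            continue
        sub = assign_bins(model, pts, ids, min_posterior=0.0,
                          label_prefix=f"{cg}.")
        out.loc[sub["contig_id"].to_numpy(), "cg_id"] = sub["cg_id"].to_numpy()
        out.loc[sub["contig_id"].to_numpy(), "posterior"] = sub["posterior"].to_numpy()
        logger.info("group %s split into %d sub-groups", cg, model.n_components)
    return out.reset_index()


def split_by_coverage(contig_ids: list[str], depths: np.ndarray,
                      cg_id: str = "CG", delta_bic: float = 10.0,
                      min_separation: float = 2.0, min_weight: float = 0.05,
                      seed: int = 0) -> pd.DataFrame:
    """Split one bin by read-depth bimodality.

    Fits 1- and 2-component Gaussian mixtures to log10 depth; the bin is
    split iff ``BIC(2) + delta_bic < BIC(1)`` and the two components
    describe a genuine second coverage mode: means bimodally separated
    (Ashman's D >= ``min_separation``) and both mixture weights at least
    ``min_weight``.  Without these guards a better-BIC two-component fit
    can arise from mere heavy tails (length-dependent depth noise of
    short contigs) or from a near-singular component spiked on a single
    outlier contig.  Sub-bins are labelled ``<cg>a`` (lower mean depth)
    and ``<cg>b`` (higher).  Returns a (contig_id, cg_id) table; with
    fewer than 4 contigs the bin is returned unchanged.
    """
    depths = np.asarray(depths, dtype=float)
    if np.any(depths <= 0):
        raise ParameterError("depths must be strictly positive")
    if len(contig_ids) != depths.size:
        raise ParameterError("contig_ids and depths length mismatch")
    if depths.size < 4:
        logger.warning("bin %s has < 4 contigs; coverage split skipped", cg_id)
        return pd.DataFrame({"contig_id": contig_ids, "cg_id": cg_id})
    x = np.log10(depths)[:, None]
    m1 = fit_gmm(x, n_components=1, seed=seed, init_cov=x.var() + 1e-3)
    m2 = fit_gmm(x, n_components=2, seed=seed, init_cov=x.var() + 1e-3)
    mu = m2.means[:, 0]
    var = m2.covariances[:, 0, 0]
    ashman_d = abs(mu[0] - mu[1]) / np.sqrt((var[0] + var[1]) / 2.0)
    if (m2.bic(x) + delta_bic < m1.bic(x) and ashman_d >= min_separation
            and m2.weights.min() >= min_weight):
        comp = m2.responsibilities(x).argmax(axis=1)
        order = np.argsort(m2.means[:, 0])          # low depth first -> 'a'
        suffix = {order[0]: "a", order[1]: "b"}
        labels = [f"{cg_id}{suffix[c]}" for c in comp]
        return pd.DataFrame({"contig_id": contig_ids, "cg_id": labels})
    return pd.DataFrame({"contig_id": contig_ids, "cg_id": cg_id})
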