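"""Topic-coherence and clustering-agreement metrics.

Coherence of a ranked term list is scored from document co-occurrence
statistics of a reference corpus: NPMI (normalized pointwise mutual
information, the UCI measure) and the UMass measure, both smoothed with
eps = 1/N where N is the reference corpus size. Clustering agreement
uses normalized mutual information (log base 2, normalized by the
larger entropy) and best-overlap accuracy; cluster labels are evaluated
against per-document controlled-vocabulary terms via hypergeometric
enrichment precision/recall/F.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "CoherenceConfig",
    "EnrichmentResult",
    "npmi",
    "umass",
    "nmi",
    "accuracy",
    "hypergeom_pvalue",
    "enrichment_prf",
]


@dataclass
class Partition:
    """Assignment of document ids to cluster labels.

    ``labels`` may include empty clusters (e.g. a selected theme that
    attracted no documents); it defaults to the assigned labels.
    """

    assignments: dict[str, object]
    labels: set | None = None

    def __post_init__(self) -> None:
        assigned = set(self.assignments.values())
        if self.labels is None:
            self.labels = assigned
        elif not assigned <= self.labels:
            raise ValueError("assignments use labels outside the declared label set")

    @property
    def n_docs(self) -> int:
        return len(self.assignments)

    def clusters(self) -> dict[object, set[str]]:
        out: dict[object, set[str]] = {lab: set() for lab in self.labels}
        for doc, lab in self.assignments.items():
            out[lab].add(doc)
        return out


class _Postings:
    """Inverted index: term -> set of reference-document indices."""

    def __init__(self, doc_term_sets: Sequence[Iterable[str]]):
        self.n_docs = len(doc_term_sets)
        self.index: dict[str, frozenset[int]] = {}
        tmp: dict[str, set[int]] = {}
        for i, terms in enumerate(doc_term_sets):
            for t in set(terms):
                tmp.setdefault(t, set()).add(i)
        self.index = {t: frozenset(s) for t, s in tmp.items()}

    def df(self, term: str) -> int:
        return len(self.index.get(term, ()))

    def co_df(self, a: str, b: str) -> int:
        return len(self.index.get(a, frozenset()) & self.index.get(b, frozenset()))


@dataclass
class CoherenceConfig:
    """Reference corpus for co-occurrence counts plus the top-K cut.

    The smoothing factor is eps = 1/N with N the reference corpus size.
    Counts D(t) and D(t,t') are over the full reference corpus.
    """

    K: int
    doc_term_sets: Sequence[Iterable[str]]
    _postings: _Postings = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if len(self.doc_term_sets) == 0:
            raise ValueError("reference corpus is empty")
        self._postings = _Postings(self.doc_term_sets)

    @property
    def n_docs(self) -> int:
        return self._postings.n_docs

    @property
    def eps(self) -> float:
        return 1.0 / self.n_docs


def npmi(top_terms: Sequence[str], cfg: CoherenceConfig) -> float:
    """Sum of normalized PMI over all pairs of the top-K terms.

    Each pair contributes log[(p(t_k,t_l)+eps) / (p(t_k) p(t_l))]
    divided by -log(p(t_k,t_l)+eps). Natural log; marginal
    probabilities are floored at eps so terms absent from the reference
    corpus (D = 0) stay finite.
    """
    terms = list(top_terms)[: cfg.K]
    if len(terms) < 2:
        raise ValueError("npmi needs at least two terms")
    post, N, eps = cfg._postings, cfg.n_docs, cfg.eps
    total = 0.0
    for k in range(1, len(terms)):
        for l in range(k):
            p_joint = post.co_df(terms[k], terms[l]) / N + eps
            p_k = max(post.df(terms[k]) / N, eps)
            p_l = max(post.df(terms[l]) / N, eps)
            total += math.log(p_joint / (p_k * p_l)) / (-math.log(p_joint))
    return total


def umass(top_terms: Sequence[str], cfg: CoherenceConfig) -> float:
    """UMass coherence: sum over pairs of log[(D(t_k,t_l)+eps)/D(t_k)].

    ``k`` ranges over the lower-ranked term of each pair; a zero
    document frequency in the denominator is surfaced as an error
    rather than smoothed.
    """
    terms = list(top_terms)[: cfg.K]
    if len(terms) < 2:
        raise ValueError("umass needs at least two terms")
    post, eps = cfg._postings, cfg.eps
    total = 0.0
    for k in range(1, len(terms)):
        d_k = post.df(terms[k])
        if d_k == 0:
            raise ValueError(f"term {terms[k]!r} has document frequency 0: UMass denominator undefined")
        for l in range(k):
            total += math.log((post.co_df(terms[k], terms[l]) + eps) / d_k)
    return total


def _contingency(C: Partition, Cprime: Partition) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if set(C.assignments) != set(Cprime.assignments):
        raise ValueError("partitions cover different document universes")
    labs_c = sorted(C.labels, key=repr)
    labs_p = sorted(Cprime.labels, key=repr)
    ic = {lab: i for i, lab in enumerate(labs_c)}
    ip = {lab: j for j, lab in enumerate(labs_p)}
    M = np.zeros((len(labs_c), len(labs_p)), dtype=np.int64)
    for doc, lab in C.assignments.items():
        M[ic[lab], ip[Cprime.assignments[doc]]] += 1
    return M, M.sum(axis=1), M.sum(axis=0)


def _entropy2(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def nmi(C: Partition, Cprime: Partition) -> float:
    """Normalized mutual information, MI / max(H(C), H(C')), log base 2.

    0·log 0 is taken as 0; two trivial single-cluster partitions agree
    perfectly and score 1.
    """
    M, rows, cols = _contingency(C, Cprime)
    n = int(M.sum())
    mi = 0.0
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            nij = M[i, j]
            if nij > 0:
                mi += (nij / n) * math.log2(nij * n / (rows[i] * cols[j]))
    h = max(_entropy2(rows, n), _entropy2(cols, n))
    if h == 0.0:
        return 1.0
    return mi / h


def accuracy(C: Partition, Cref: Partition) -> float:
    """Best-overlap accuracy: sum_i max_j |c_i ∩ c'_j| / N.

    ``c_i`` ranges over computed clusters, ``c'_j`` over reference
    clusters; no one-to-one matching is enforced, so a partition into
    singletons scores 1 against any reference — comparisons are only
    meaningful at a fixed cluster count.
    """
    if set(C.assignments) != set(Cref.assignments):
        raise ValueError("partitions cover different document universes")
    ref_clusters = Cref.clusters()
    total = 0
    for docs in C.clusters().values():
        if docs:
            total += max(len(docs & ref) for ref in ref_clusters.values())
    return total / C.n_docs


def hypergeom_pvalue(k: int, n: int, K_t: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K_t, n).

    ``k`` successes in a cluster of size ``n`` drawn from a collection
    of ``N`` documents of which ``K_t`` carry the term. Summed in log
    space for stability.
    """
    if not (0 <= k <= min(n, K_t) <= N) or n > N:
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K_t={K_t}, N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K_t) + 1)
    logp = hypergeom.logpmf(support, N, K_t, n)
    return float(min(1.0, math.exp(logsumexp(logp))))


@dataclass
class EnrichmentResult:
    """Per-cluster top enriched terms and macro-averaged P/R/F."""

    per_cluster: dict
    precision: float
    recall: float
    fscore: float


def enrichment_prf(clusters: Partition, term_sets: Mapping[str, Iterable[str]]) -> EnrichmentResult:
    """Precision/recall/F from the 3 most enriched terms per cluster.

    Per cluster, candidate terms are ranked by ascending hypergeometric
    p-value (ties: higher in-cluster count, then lexicographic); for
    each of the top 3, precision is the in-cluster fraction carrying
    the term and recall the fraction of all carriers inside the
    cluster. The three are macro-averaged per cluster, then averaged
    over clusters; F is the harmonic mean of the averaged P and R.
    Clusters whose documents carry no terms are excluded and logged.
    """
    doc_terms = {d: set(term_sets.get(d, ())) for d in clusters.assignments}
    N = len(doc_terms)
    collection_count: dict[str, int] = {}
    for terms in doc_terms.values():
        for t in terms:
            collection_count[t] = collection_count.get(t, 0) + 1

    per_cluster: dict = {}
    precisions: list[float] = []
    recalls: list[float] = []
    for lab, docs in clusters.clusters().items():
        if not docs:
            continue
        in_count: dict[str, int] = {}
        for d in docs:
            for t in doc_terms[d]:
                in_count[t] = in_count.get(t, 0) + 1
        if not in_count:
            logger.info("enrichment_prf: cluster %r has no terms, excluded from averaging", lab)
            continue
        scored = sorted(
            ((hypergeom_pvalue(c, len(docs), collection_count[t], N), -c, t) for t, c in in_count.items()),
        )
        top = scored[:3]
        ps, rs = [], []
        for p_val, neg_c, t in top:
            c = -neg_c
            ps.append(c / len(docs))
            rs.append(c / collection_count[t])
        P, R = float(np.mean(ps)), float(np.mean(rs))
        f = 2 * P * R / (P + R) if P + R > 0 else 0.0
        per_cluster[lab] = {
            "terms": [(t, p_val) for p_val, _, t in top],
            "precision": P,
            "recall": R,
            "fscore": f,
        }
        precisions.append(P)
        recalls.append(R)
    if not precisions:
        raise ValueError("no cluster carries any controlled-vocabulary terms")
    P, R = float(np.mean(precisions)), float(np.mean(recalls))
    F = 2 * P * R / (P + R) if P + R > 0 else 0.0
    return EnrichmentResult(per_cluster=per_cluster, precision=P, recall=R, fscore=F)
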