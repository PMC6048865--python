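"""Theme discovery: seed-driven interleaving of consensus updates and
top-m document re-selection.

A theme is a dual object: a ranked document set and a consensus term
vector, each the best summary of the other. Starting from a single
seed document's normalized tf-idf vector, the theme algorithm
alternates (i) scoring every document in the collection against the
current consensus vector and keeping the top m, with (ii) re-running
the projection algorithm on those m documents, until the document set
is stable. The final theme is expanded to every document scoring at
least ``expansion_ratio`` times the top score. Each theme depends only
on its seed and the matrix, so the sweep over all seeds is order-free
and trivially parallel; redundant themes (half-or-more overlap with a
larger one) are pruned greedily from the largest down.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import CorpusMatrix
from .metrics import Partition
from .projection import ConsensusVector, DegenerateStartError, ProjectionConfig, objective, run_projection

logger = logging.getLogger(__name__)

__all__ = [
    "ThemeConfig",
    "Theme",
    "ThemeSet",
    "score_all",
    "select_top_m",
    "run_theme",
    "discover_all",
    "prune_redundant",
    "greedy_partition",
    "within_theme_similarity",
]


@dataclass(frozen=True)
class ThemeConfig:
    """Knobs of the theme algorithm.

    ``m`` is the core size (documents per consensus update);
    ``expansion_ratio`` the score fraction of the top document required
    for membership; ``overlap_threshold`` the member-overlap fraction
    (of the smaller theme) at or above which a theme is pruned.
    """

    m: int = 10
    min_theme_size: int = 10
    expansion_ratio: float = 0.5
    max_outer_iter: int = 100
    overlap_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not 0 < self.expansion_ratio <= 1:
            raise ValueError("expansion_ratio must be in (0, 1]")
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")


@dataclass
class Theme:
    """A discovered theme: core documents, expanded members, consensus."""

    seed_id: str
    core_ids: list[str]
    member_ids: list[str]
    scores: dict[str, float]
    consensus: ConsensusVector
    outer_iterations: int
    converged: bool

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def top_terms(self, vocab_terms: Sequence[str], k: int = 10) -> list[tuple[str, float]]:
        """Top-k vocabulary terms by |consensus weight|."""
        w = self.consensus.weights
        order = np.argsort(-np.abs(w), kind="stable")[:k]
        return [(vocab_terms[j], float(w[j])) for j in order if w[j] != 0.0]


@dataclass
class ThemeSet:
    """Canonically ordered themes (size descending, then seed id)."""

    themes: list[Theme]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.themes.sort(key=lambda t: (-t.size, t.seed_id))

    def __len__(self) -> int:
        return len(self.themes)

    def __iter__(self):
        return iter(self.themes)


def score_all(matrix: CorpusMatrix, phi: ConsensusVector | np.ndarray) -> np.ndarray:
    """Score every document: (u_d, phi) with unit-normalized u_d."""
    w = phi.weights if isinstance(phi, ConsensusVector) else np.asarray(phi, dtype=float)
    if w.shape[0] != matrix.n_terms:
        raise ValueError("consensus vector does not match matrix vocabulary")
    return np.asarray(matrix.unit() @ w).ravel()


def _top_m_indices(scores: np.ndarray, doc_ids: np.ndarray, m: int) -> np.ndarray:
    # primary key: score descending; tie-break: doc_id ascending
    order = np.lexsort((doc_ids, -scores))
    return order[:m]


def select_top_m(scores: Mapping[str, float], m: int) -> list[str]:
    """The m highest-scoring document ids, ties broken by ascending id."""
    if len(scores) < m:
        raise ValueError(f"need at least m={m} documents, have {len(scores)}")
    ids = np.array(sorted(scores))
    vals = np.array([scores[d] for d in ids], dtype=float)
    return [str(ids[i]) for i in _top_m_indices(vals, ids, m)]


def run_theme(
    matrix: CorpusMatrix,
    seed_id: str,
    theme_cfg: ThemeConfig | None = None,
    proj_cfg: ProjectionConfig | None = None,
) -> Theme:
    """Grow one theme from a seed document.

    The outer loop stops when the top-m set repeats the previous
    iteration's set; if a set recurs from >=2 iterations back (a
    cycle), the cycle member with the larger projection objective is
    kept. The expanded member set is every document scoring at least
    ``expansion_ratio`` times the top score, plus the core.
    """
    theme_cfg = theme_cfg or ThemeConfig()
    proj_cfg = proj_cfg or ProjectionConfig()
    if matrix.n_docs < theme_cfg.m:
        raise ValueError(f"collection has {matrix.n_docs} documents, fewer than m={theme_cfg.m}")
    Xu = matrix.unit()
    i = matrix.index(seed_id)
    phi = np.asarray(Xu.getrow(i).todense()).ravel()
    if not np.any(phi):
        raise DegenerateStartError(f"seed {seed_id!r} has an empty vector after vocabulary filtering")
    ids_arr = np.array(matrix.doc_ids)

    seen: dict[frozenset, tuple[int, float, np.ndarray]] = {}
    prev_set: frozenset | None = None
    converged = False
    outer = 0
    for outer in range(1, theme_cfg.max_outer_iter + 1):
        scores = np.asarray(Xu @ phi).ravel()
        top_idx = _top_m_indices(scores, ids_arr, theme_cfg.m)
        cur = frozenset(int(j) for j in top_idx)
        if cur == prev_set:
            converged = True
            break
        if cur in seen:
            # cycle of length >= 2: keep the member with the larger objective
            first_it, first_obj, first_phi = seen[cur]
            rows = Xu[top_idx]
            res = run_projection(rows, phi, proj_cfg)
            obj_now = objective(rows, res.weights)
            best = max(
                [(first_obj, first_phi)]
                + [(o, p) for (it, o, p) in seen.values() if it >= first_it]
                + [(obj_now, res.weights)],
                key=lambda t: t[0],
            )
            phi = best[1]
            converged = True
            logger.info("run_theme(%s): cycle detected at outer iteration %d, resolved by objective", seed_id, outer)
            break
        rows = Xu[top_idx]
        res = run_projection(rows, phi, proj_cfg)
        phi = res.weights
        seen[cur] = (outer, objective(rows, phi), phi)
        prev_set = cur

    scores = np.asarray(Xu @ phi).ravel()
    top_idx = _top_m_indices(scores, ids_arr, theme_cfg.m)
    core_ids = [str(ids_arr[j]) for j in top_idx]
    top_score = float(scores[top_idx[0]])
    member_mask = scores >= theme_cfg.expansion_ratio * top_score
    member_idx = np.flatnonzero(member_mask)
    member_idx = np.union1d(member_idx, top_idx)
    order = np.lexsort((ids_arr[member_idx], -scores[member_idx]))
    member_ids = [str(ids_arr[member_idx[k]]) for k in order]
    return Theme(
        seed_id=seed_id,
        core_ids=core_ids,
        member_ids=member_ids,
        scores={str(d): float(s) for d, s in zip(ids_arr, scores)},
        consensus=ConsensusVector(weights=phi, iteration_count=outer, converged=converged),
        outer_iterations=outer,
        converged=converged,
    )


def discover_all(
    matrix: CorpusMatrix,
    theme_cfg: ThemeConfig | None = None,
    proj_cfg: ProjectionConfig | None = None,
    n_jobs: int = 1,
) -> ThemeSet:
    """Run the theme algorithm from every document as a seed.

    Themes smaller than ``min_theme_size`` are discarded. Each seed's
    theme is a pure function of (matrix, config), so the sweep may run
    concurrently; the canonical sort makes the output independent of
    execution or document order. Per-seed failures are logged, never
    fatal to the sweep.
    """
    theme_cfg = theme_cfg or ThemeConfig()
    proj_cfg = proj_cfg or ProjectionConfig()
    seeds = sorted(matrix.doc_ids)

    def one(seed: str) -> Theme | None:
        try:
            t = run_theme(matrix, seed, theme_cfg, proj_cfg)
        except DegenerateStartError as exc:
            logger.warning("discover_all: seed %r skipped: %s", seed, exc)
            return None
        # keep only member scores: full per-seed score maps are quadratic
        # in the collection size across a whole-corpus sweep
        t.scores = {d: t.scores[d] for d in t.member_ids}
        return t

    if n_jobs == 1:
        results = [one(s) for s in seeds]
    else:
        with ThreadPoolExecutor(max_workers=n_jobs) as pool:
            results = list(pool.map(one, seeds))
    themes = [t for t in results if t is not None and t.size >= theme_cfg.min_theme_size]
    prov = {"m": theme_cfg.m, "min_theme_size": theme_cfg.min_theme_size,
            "expansion_ratio": theme_cfg.expansion_ratio, "overlap_threshold": theme_cfg.overlap_threshold,
            "tol": proj_cfg.tol, "max_iter": proj_cfg.max_iter, "max_outer_iter": theme_cfg.max_outer_iter}
    return ThemeSet(themes=themes, provenance=prov)


def prune_redundant(themes: ThemeSet, overlap_threshold: float = 0.5) -> ThemeSet:
    """Drop themes overlapping a larger kept theme by >= the threshold.

    Greedy scan in canonical (largest-first) order; the overlap
    fraction is measured against the smaller (candidate) theme and the
    threshold is inclusive on the drop side: exactly half overlap drops.
    """
    kept: list[Theme] = []
    kept_sets: list[set[str]] = []
    for theme in themes:
        members = set(theme.member_ids)
        redundant = any(
            len(a & members) / len(members) >= overlap_threshold for a in kept_sets
        )
        if not redundant:
            kept.append(theme)
            kept_sets.append(members)
    return ThemeSet(themes=kept, provenance=dict(themes.provenance))


def greedy_partition(
    themes: ThemeSet | Sequence[Theme],
    matrix: CorpusMatrix,
    K: int,
    seed: int = 0,
) -> Partition:
    """Partition the collection into K clusters via greedy theme selection.

    Documents affiliate with the selected theme where they score
    highest. The first pick is the theme with the highest sum of
    scores; each subsequent pick maximizes the increment in the sum
    over documents of their best affiliated score. Ties are broken
    randomly (``seed``). Documents scoring zero against every selected
    theme go to the selected theme of highest total score.
    """
    theme_list = list(themes)
    if K > len(theme_list):
        raise ValueError(f"K={K} exceeds the number of themes ({len(theme_list)})")
    rng = np.random.default_rng(seed)
    S = np.vstack([score_all(matrix, t.consensus) for t in theme_list])
    totals = S.sum(axis=1)

    def argmax_tie(vals: np.ndarray, candidates: np.ndarray) -> int:
        best = vals[candidates].max()
        ties = candidates[vals[candidates] == best]
        return int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])

    remaining = np.arange(len(theme_list))
    first = argmax_tie(totals, remaining)
    selected = [first]
    best_scores = S[first].copy()
    while len(selected) < K:
        remaining = np.array([j for j in range(len(theme_list)) if j not in selected])
        gains = np.full(len(theme_list), -np.inf)
        for j in remaining:
            gains[j] = np.maximum(best_scores, S[j]).sum() - best_scores.sum()
        pick = argmax_tie(gains, remaining)
        selected.append(pick)
        best_scores = np.maximum(best_scores, S[pick])

    sel = np.array(selected)
    sub = S[sel]  # selection order preserved: earlier picks win exact ties
    aff = np.argmax(sub, axis=0)
    fallback = int(np.argmax(totals[sel]))
    labels = [theme_list[j].seed_id for j in selected]
    assignments = {}
    for d, doc_id in enumerate(matrix.doc_ids):
        k = int(aff[d]) if sub[:, d].max() > 0 else fallback
        assignments[doc_id] = labels[k]
    return Partition(assignments=assignments, labels=set(labels))


def within_theme_similarity(theme: Theme, matrix: CorpusMatrix) -> float:
    """Mean raw tf-idf dot product over all unordered member pairs."""
    if theme.size < 2:
        raise ValueError("within-theme similarity needs at least two members")
    idx = [matrix.index(d) for d in theme.member_ids]
    rows = matrix.X[idx]
    G = (rows @ rows.T).toarray()
    n = len(idx)
    off_diag_sum = G.sum() - np.trace(G)
    return float(off_diag_sum / (n * (n - 1)))


def themes_to_json(themes: ThemeSet, vocab_terms: Sequence[str]) -> str:
    """Canonical JSON serialization (stable across runs and platforms)."""
    payload = {
        "provenance": themes.provenance,
        "themes": [
            {
                "seed_id": t.seed_id,
                "size": t.size,
                "outer_iterations": t.outer_iterations,
                "converged": t.converged,
                "members": [{"doc_id": d, "score": t.scores[d]} for d in t.member_ids],
                "top_terms": [{"term": term, "weight": w} for term, w in t.top_terms(vocab_terms, 10)],
                "consensus": {
                    vocab_terms[j]: float(t.consensus.weights[j])
                    for j in np.flatnonzero(t.consensus.weights)
                },
            }
            for t in themes
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
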