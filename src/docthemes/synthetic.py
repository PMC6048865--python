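"""Planted-theme synthetic corpora with exact ground truth.

Each document belongs to one block and draws its tokens from the block
vocabulary with probability 1 - noise_rate and from a shared background
vocabulary otherwise; draws within each vocabulary are Zipf-weighted so
document frequencies show the skew tf-idf expects. The "ideal" variant
post-checks the separation condition that guarantees a seed-grown theme
stays inside its block: every within-block pairwise similarity of the
normalized tf-idf vectors strictly exceeds every block-to-outside
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus import CorpusMatrix, RawDocument, TokenConfig, build_matrix
from .metrics import Partition

__all__ = [
    "PlantedSpec",
    "GroundTruth",
    "generate",
    "generate_ideal",
    "audit_separation",
    "labeled_partition",
]

#: tokenization under which ideal-case separation is audited
AUDIT_TOKENS = TokenConfig(use_unigrams=True, min_df=1)


@dataclass(frozen=True)
class PlantedSpec:
    """Recipe for a corpus with planted document blocks.

    ``block_sizes`` may be a single int (all blocks equal) or one size
    per block. ``noise_rate`` is the per-token probability of drawing
    from the background instead of the block vocabulary;
    ``overlap_rate`` the fraction of each block's vocabulary shared
    with the previous block. ``cv_rate`` controls how often a document
    carries its block's controlled-vocabulary label term.
    """

    n_blocks: int = 4
    block_sizes: int | tuple[int, ...] = 50
    block_vocab_size: int = 60
    background_vocab_size: int = 120
    doc_length_mean: float = 40.0
    noise_rate: float = 0.1
    overlap_rate: float = 0.0
    cv_rate: float = 0.9
    zipf_exponent: float = 1.0
    rng_seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.block_sizes, int):
            return [self.block_sizes] * self.n_blocks
        if len(self.block_sizes) != self.n_blocks:
            raise ValueError("block_sizes length must equal n_blocks")
        return list(self.block_sizes)

    def validate(self) -> None:
        if self.n_blocks < 1 or self.block_vocab_size < 1 or self.background_vocab_size < 1:
            raise ValueError("all sizes must be >= 1")
        if any(s < 1 for s in self.sizes()):
            raise ValueError("block sizes must be >= 1")
        if not (0 <= self.noise_rate < 1 and 0 <= self.overlap_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.doc_length_mean < 1:
            raise ValueError("doc_length_mean must be >= 1")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        shared = int(self.overlap_rate * self.block_vocab_size)
        if shared >= self.block_vocab_size:
            raise ValueError("overlap_rate leaves no block-specific vocabulary")


@dataclass
class GroundTruth:
    """Exact bookkeeping of the generated corpus."""

    labels: dict[str, str]
    block_vocab: dict[str, set[str]]
    expected_theme_count: int
    token_bags: dict[str, dict[str, int]] = field(default_factory=dict)


def _zipf_probs(n: int, exponent: float = 1.0) -> np.ndarray:
    # exponent 1 is classic Zipf; 0 is uniform. Flatter draws avoid the
    # ultra-rare, idf-dominant terms that break the ideal-case separation.
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def generate(spec: PlantedSpec) -> tuple[list[RawDocument], GroundTruth]:
    """Draw a corpus from the planted-block recipe; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    sizes = spec.sizes()
    background = [f"bg{j:04d}" for j in range(spec.background_vocab_size)]

    shared = int(spec.overlap_rate * spec.block_vocab_size)
    vocabs: list[list[str]] = []
    for b in range(spec.n_blocks):
        vocab = [f"b{b:02d}w{j:04d}" for j in range(spec.block_vocab_size)]
        if shared and b > 0:
            vocab[:shared] = vocabs[b - 1][-shared:]
        vocabs.append(vocab)

    bg_probs = _zipf_probs(spec.background_vocab_size, spec.zipf_exponent)
    blk_probs = _zipf_probs(spec.block_vocab_size, spec.zipf_exponent)
    docs: list[RawDocument] = []
    labels: dict[str, str] = {}
    bags: dict[str, dict[str, int]] = {}
    for b in range(spec.n_blocks):
        label = f"block{b}"
        blk_vocab = np.array(vocabs[b])
        bg_vocab = np.array(background)
        for i in range(sizes[b]):
            doc_id = f"b{b:02d}d{i:04d}"
            length = max(3, int(rng.poisson(spec.doc_length_mean)))
            from_bg = rng.random(length) < spec.noise_rate
            n_bg = int(from_bg.sum())
            tokens = np.empty(length, dtype=object)
            if n_bg:
                tokens[from_bg] = rng.choice(bg_vocab, size=n_bg, p=bg_probs)
            if length - n_bg:
                tokens[~from_bg] = rng.choice(blk_vocab, size=length - n_bg, p=blk_probs)
            token_list = [str(t) for t in tokens]
            vocab_terms = [label] if rng.random() < spec.cv_rate else []
            if rng.random() < 0.3:
                vocab_terms.append("common")
            docs.append(
                RawDocument(
                    doc_id=doc_id,
                    text=" ".join(token_list),
                    vocab_terms=vocab_terms or None,
                    ref_label=label,
                )
            )
            labels[doc_id] = label
            bag: dict[str, int] = {}
            for t in token_list:
                bag[t] = bag.get(t, 0) + 1
            bags[doc_id] = bag
    truth = GroundTruth(
        labels=labels,
        block_vocab={f"block{b}": set(vocabs[b]) for b in range(spec.n_blocks)},
        expected_theme_count=spec.n_blocks,
        token_bags=bags,
    )
    return docs, truth


def audit_separation(matrix: CorpusMatrix, labels: dict[str, str]) -> bool:
    """Check the ideal-case separation on the actual normalized vectors.

    True iff for every block the minimum within-block pairwise
    similarity strictly exceeds the maximum similarity between a block
    member and any outside document.
    """
    Xu = matrix.unit()
    G = (Xu @ Xu.T).toarray()
    lab = np.array([labels[d] for d in matrix.doc_ids])
    for block in np.unique(lab):
        inside = lab == block
        sub = G[np.ix_(inside, inside)]
        n_in = int(inside.sum())
        if n_in < 2:
            continue
        min_within = (sub + np.eye(n_in) * 2).min()
        max_cross = G[np.ix_(inside, ~inside)].max() if n_in < len(lab) else -np.inf
        if not min_within > max_cross:
            return False
    return True


def generate_ideal(
    spec: PlantedSpec, max_attempts: int = 20
) -> tuple[list[RawDocument], GroundTruth]:
    """Generate until the corpus passes the separation audit.

    Retries with derived seeds up to ``max_attempts`` times; failing
    that, raise with advice to lower the noise rate.
    """
    for attempt in range(max_attempts):
        derived = (spec.rng_seed + 9973 * attempt) % (2**31)
        docs, truth = generate(replace(spec, rng_seed=derived))
        matrix = build_matrix(docs, AUDIT_TOKENS)
        if audit_separation(matrix, truth.labels):
            return docs, truth
    raise RuntimeError(
        f"separation audit failed {max_attempts} times; lower noise_rate (currently {spec.noise_rate})"
    )


def labeled_partition(truth: GroundTruth) -> Partition:
    """Reference partition from the ground-truth block labels."""
    if not truth.labels:
        raise ValueError("ground truth is empty")
    return Partition(assignments=dict(truth.labels))
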