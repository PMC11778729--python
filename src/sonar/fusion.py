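"""Embedding fusion and supervised alignment.

Fusion: each of a variable's vectors (two semantic embeddings and the
distribution vector) is divided by its own maximum absolute component, bounding
every entry to [-1, 1], and the normalized segments are concatenated in the
fixed order (coder, sapbert, dist) into one vector of dimension ``d``.
Similarity between variables is the cosine of their fused vectors.

Alignment: a supervised d x d matrix ``M`` (identity-initialized, applied as
``x @ M`` with row vectors) is trained by full-batch gradient descent on a
margin contrastive loss over gold-standard pairs: every positive pair's cosine
is pushed above the cosines of seeded negative pairs by a margin.  "Rotation"
here means an unconstrained linear map; an optional orthogonality penalty
``lambda * ||M^T M - I||_F^2`` is available (default off).  Evaluation uses
2-fold cross-validation split by concept: each fold's matrix scores the other
fold's positive pairs, and non-gold pair scores are the average of the two
matrices' scores.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

_EPS = 1e-12


def derive_seed(root_seed: int, *tokens: str) -> int:
    """A stable named substream seed below 2**31, derived from a root seed."""
    h = zlib.crc32(("/".join(tokens)).encode("utf-8"))
    return int((root_seed * 0x9E3779B1 + h) % (2**31 - 1))


def maxabs_normalize(vector: np.ndarray) -> np.ndarray:
    """Divide by the maximum absolute component; all-zero input is unchanged.

    Idempotent and invariant to positive rescaling of the input; output
    components lie in [-1, 1] with at least one equal to +/-1 unless the
    input is all zero.
    """
    v = np.asarray(vector, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("cannot normalize a vector with NaN/inf components")
    m = np.abs(v).max() if v.size else 0.0
    return v if m == 0 else v / m


@dataclass(frozen=True)
class ConcatEmbedding:
    """One variable's fused vector with its segment spans recorded."""

    variable_accession: str
    vector: np.ndarray
    boundaries: dict[str, tuple[int, int]]

    @property
    def dimension(self) -> int:
        return self.vector.shape[0]


def concatenate(
    coder: np.ndarray,
    sapbert: np.ndarray,
    dist: np.ndarray | None = None,
    accession: str = "",
) -> ConcatEmbedding:
    """Concatenate already-normalized segments in the fixed (coder, sapbert,
    dist) order; an empty/absent dist segment yields the semantic-only vector."""
    segments = [("coder", np.asarray(coder, float)), ("sapbert", np.asarray(sapbert, float))]
    if dist is not None and np.asarray(dist).size:
        segments.append(("dist", np.asarray(dist, float)))
    boundaries: dict[str, tuple[int, int]] = {}
    start = 0
    for name, seg in segments:
        boundaries[name] = (start, start + seg.shape[0])
        start += seg.shape[0]
    return ConcatEmbedding(
        accession, np.concatenate([s for _, s in segments]), boundaries
    )


@dataclass
class TaskEmbeddings:
    """Fused embeddings for every variable of one side of a comparison.

    Rows of ``X`` follow ``accessions``; all rows share the task dimension
    ``d`` and every component is in [-1, 1].
    """

    accessions: tuple[str, ...]
    X: np.ndarray
    boundaries: dict[str, tuple[int, int]]

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.accessions)}

    @property
    def dimension(self) -> int:
        return self.X.shape[1]

    def row(self, accession: str) -> int:
        return self._index[accession]


def build_task_embeddings(
    accessions: Sequence[str],
    segments: Sequence[tuple[str, Mapping[str, np.ndarray]]],
) -> TaskEmbeddings:
    """Normalize each segment per variable (max-abs) and concatenate.

    ``segments`` is an ordered list of ``(name, accession -> vector)``; every
    accession must appear in every segment with a consistent dimension.
    """
    if not segments:
        raise ValidationError("at least one embedding segment is required")
    boundaries: dict[str, tuple[int, int]] = {}
    start = 0
    blocks = []
    for name, vectors in segments:
        dims = {np.asarray(vectors[a]).shape[0] for a in accessions}
        if len(dims) != 1:
            raise ValidationError(
                f"segment {name!r} has inconsistent dimensions across variables: {dims}"
            )
        (dim,) = dims
        block = np.stack(
            [maxabs_normalize(np.asarray(vectors[a], float)) for a in accessions]
        )
        boundaries[name] = (start, start + dim)
        start += dim
        blocks.append(block)
    return TaskEmbeddings(tuple(accessions), np.hstack(blocks), boundaries)


@dataclass
class TrainingConfig:
    """Hyperparameters of the supervised alignment step.

    ``learning_rate`` applies to the gradient of the mean hinge loss (the loss
    is averaged over positive pairs, so the step size is insensitive to the
    number of gold pairs).
    """

    epochs: int = 100
    learning_rate: float = 0.5
    margin: float = 0.2
    n_negatives: int = 5
    seed: int = 0
    ortho_penalty: float = 0.0
    n_folds: int = 2


@dataclass
class AlignmentMatrix:
    """A trained d x d alignment map with its training metadata."""

    M: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def dimension(self) -> int:
        return self.M.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return apply_alignment(X, self)


def apply_alignment(x: np.ndarray, matrix: AlignmentMatrix | np.ndarray) -> np.ndarray:
    """Row-vector application ``x @ M`` (works on single vectors and stacks)."""
    M = matrix.M if isinstance(matrix, AlignmentMatrix) else np.asarray(matrix)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != M.shape[0]:
        raise ValidationError(
            f"embedding dimension {x.shape[-1]} does not match matrix {M.shape}"
        )
    return x @ M


def _loss_and_grad(
    M: np.ndarray,
    X: np.ndarray,
    I: np.ndarray,
    J: np.ndarray,
    K: np.ndarray,
    margin: float,
    ortho_penalty: float = 0.0,
):
    """Mean hinge loss over positives and its gradient with respect to M.

    ``I, J`` index positive pairs into rows of ``X``; ``K`` has shape
    ``(n_pos, n_neg)`` holding negative partners for each anchor ``I``.
    """
    n_pos, n_neg = K.shape
    U = X @ M
    norms = np.linalg.norm(U, axis=1)
    norms = np.where(norms < _EPS, _EPS, norms)
    Un = U / norms[:, None]

    cos_pos = np.einsum("ij,ij->i", Un[I], Un[J])
    anchors = np.repeat(I, n_neg)
    negs = K.reshape(-1)
    cos_neg = np.einsum("ij,ij->i", Un[anchors], Un[negs])
    hinge = cos_neg - np.repeat(cos_pos, n_neg) + margin
    active = hinge > 0
    loss = float(hinge[active].sum() / n_pos)

    # d cos(u_a, u_b) / d u_a = (un_b - cos * un_a) / ||u_a||
    A = np.zeros_like(U)
    if active.any():
        a_idx = anchors[active]
        k_idx = negs[active]
        c_ak = cos_neg[active]
        # + d cos(anchor, negative)
        np.add.at(A, a_idx, (Un[k_idx] - c_ak[:, None] * Un[a_idx]) / norms[a_idx, None])
        np.add.at(A, k_idx, (Un[a_idx] - c_ak[:, None] * Un[k_idx]) / norms[k_idx, None])
        # - d cos(anchor, positive); one subtraction per active hinge term
        p_of_term = np.repeat(np.arange(n_pos), n_neg)[active]
        i_idx = I[p_of_term]
        j_idx = J[p_of_term]
        c_ij = cos_pos[p_of_term]
        np.add.at(A, i_idx, -(Un[j_idx] - c_ij[:, None] * Un[i_idx]) / norms[i_idx, None])
        np.add.at(A, j_idx, -(Un[i_idx] - c_ij[:, None] * Un[j_idx]) / norms[j_idx, None])
    grad = (X.T @ A) / n_pos

    if ortho_penalty:
        gram = M.T @ M - np.eye(M.shape[0])
        loss += float(ortho_penalty * np.sum(gram**2))
        grad = grad + 4.0 * ortho_penalty * (M @ gram)
    return loss, grad


def _positive_partners(positives: Sequence[tuple[int, int]]) -> dict[int, set[int]]:
    partners: dict[int, set[int]] = {}
    for i, j in positives:
        partners.setdefault(i, set()).add(j)
        partners.setdefault(j, set()).add(i)
    return partners


def _sample_negatives(
    positives: Sequence[tuple[int, int]],
    candidates_of,
    n_negatives: int,
    rng: np.random.Generator,
) -> np.ndarray:
    partners = _positive_partners(positives)
    K = np.empty((len(positives), n_negatives), dtype=np.int64)
    for p, (i, _j) in enumerate(positives):
        pool = [
            c for c in candidates_of(i) if c != i and c not in partners.get(i, ())
        ]
        if not pool:
            raise ValidationError(
                f"no negative candidates available for training anchor row {i}"
            )
        replace = len(pool) < n_negatives
        K[p] = rng.choice(pool, size=n_negatives, replace=replace)
    return K


def train_alignment(
    embeddings: TaskEmbeddings,
    positives: Sequence[tuple[str, str]],
    config: TrainingConfig,
    candidate_rows: Sequence[int] | None = None,
) -> AlignmentMatrix:
    """Train the alignment matrix on gold-standard positive pairs.

    ``positives`` are accession pairs; negatives are seeded draws from
    ``candidate_rows`` (default: all task rows) excluding each anchor's gold
    partners, fixed once so the descent runs on a fixed objective.  With
    ``epochs=0`` the identity is returned, reproducing the unsupervised
    method exactly.
    """
    if len(positives) < 1:
        raise ValidationError("supervised training requires at least one positive pair")
    X = embeddings.X
    d = embeddings.dimension
    pairs = [(embeddings.row(a), embeddings.row(b)) for a, b in positives]
    rng = np.random.default_rng(config.seed)
    rows = list(candidate_rows) if candidate_rows is not None else list(range(len(X)))

    M = np.eye(d)
    trace: list[float] = []
    if config.epochs > 0:
        K = _sample_negatives(pairs, lambda _i: rows, config.n_negatives, rng)
        I = np.array([p[0] for p in pairs], dtype=np.int64)
        J = np.array([p[1] for p in pairs], dtype=np.int64)
        for _ in range(config.epochs):
            loss, grad = _loss_and_grad(
                M, X, I, J, K, config.margin, config.ortho_penalty
            )
            if not np.isfinite(loss):
                raise ValidationError(
                    f"non-finite training loss at epoch {len(trace)}; "
                    "reduce the learning rate"
                )
            trace.append(loss)
            M = M - config.learning_rate * grad
    meta = {
        "seed": config.seed,
        "epochs": config.epochs,
        "learning_rate": config.learning_rate,
        "margin": config.margin,
        "n_negatives": config.n_negatives,
        "ortho_penalty": config.ortho_penalty,
        "loss_trace": trace,
        "n_positives": len(pairs),
    }
    return AlignmentMatrix(M, meta)


@dataclass
class CrossvalResult:
    """Pooled similarity scores from 2-fold supervised cross-validation."""

    scores: np.ndarray  # (n_a, n_b) pooled cosine similarities
    fold_of_concept: dict[str, int]
    matrices: list[AlignmentMatrix]


def cosine_matrix(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between row stacks (zero rows score 0)."""
    na = np.linalg.norm(Xa, axis=1)
    nb = np.linalg.norm(Xb, axis=1)
    na = np.where(na < _EPS, _EPS, na)
    nb = np.where(nb < _EPS, _EPS, nb)
    return (Xa / na[:, None]) @ (Xb / nb[:, None]).T


def crossval_scores(
    emb_a: TaskEmbeddings,
    emb_b: TaskEmbeddings,
    pairs_by_concept: Mapping[str, Sequence[tuple[str, str]]],
    config: TrainingConfig,
    intracohort: bool,
) -> CrossvalResult:
    """2-fold concept-split cross-validated similarity scores.

    Concepts are shuffled (seeded) into two folds.  The matrix trained on one
    fold's positive pairs scores the other fold's positive pairs; non-gold
    pair scores are the average of the two matrices' scores.  For intracohort
    comparisons ``emb_a is emb_b``.
    """
    if config.n_folds != 2:
        raise ValidationError("the evaluation protocol uses exactly 2 folds")
    concepts = sorted(pairs_by_concept)
    if len(concepts) < 2:
        raise ValidationError(
            "2-fold cross-validation needs at least 2 concepts with positive "
            "pairs; use a different seed or fold count"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(concepts))
    fold_of_concept = {
        concepts[idx]: (0 if rank < len(concepts) / 2 else 1)
        for rank, idx in enumerate(order)
    }
    for fold in (0, 1):
        if not any(f == fold for f in fold_of_concept.values()):
            raise ValidationError(
                f"fold {fold} received no positive pairs; use a different seed"
            )

    if intracohort:
        stack = emb_a
        offset_b = 0
    else:
        stack = TaskEmbeddings(
            emb_a.accessions + emb_b.accessions,
            np.vstack([emb_a.X, emb_b.X]),
            emb_a.boundaries,
        )
        offset_b = len(emb_a.accessions)

    matrices: list[AlignmentMatrix] = []
    fold_scores: list[np.ndarray] = []
    for fold in (0, 1):
        train_pairs: list[tuple[str, str]] = []
        for concept in concepts:
            if fold_of_concept[concept] == fold:
                train_pairs.extend(pairs_by_concept[concept])
        # accession collisions cannot occur: intracohort shares one stack and
        # intercohort accessions are globally unique
        fold_config = dataclasses.replace(
            config, seed=derive_seed(config.seed, "train", str(fold))
        )
        matrix = _train_on_stack(
            stack, train_pairs, fold_config, intracohort, offset_b
        )
        matrix.meta["fold"] = fold
        matrices.append(matrix)
        Ua = emb_a.X @ matrix.M
        Ub = Ua if intracohort else emb_b.X @ matrix.M
        fold_scores.append(cosine_matrix(Ua, Ub))

    pooled = (fold_scores[0] + fold_scores[1]) / 2.0
    for concept, fold in fold_of_concept.items():
        held_out = fold_scores[1 - fold]
        for a, b in pairs_by_concept[concept]:
            ia, ib = emb_a.row(a), (emb_a if intracohort else emb_b).row(b)
            pooled[ia, ib] = held_out[ia, ib]
            if intracohort:
                pooled[ib, ia] = held_out[ib, ia]
    return CrossvalResult(pooled, fold_of_concept, matrices)


def _train_on_stack(
    stack: TaskEmbeddings,
    pairs: Sequence[tuple[str, str]],
    config: TrainingConfig,
    intracohort: bool,
    offset_b: int,
) -> AlignmentMatrix:
    """Train on a (possibly stacked A+B) embedding matrix.

    Negative partners for an anchor are drawn from the opposite cohort's rows
    for intercohort tasks and from all rows for intracohort tasks, matching
    the scope of pairs being scored.
    """
    if not pairs:
        raise ValidationError(
            "a cross-validation fold received no positive pairs; "
            "use a different seed"
        )
    if intracohort:
        return train_alignment(stack, pairs, config)
    # anchor side decides the candidate pool; anchors of (a, b) pairs are in A
    rows_b = list(range(offset_b, len(stack.accessions)))
    return train_alignment(stack, pairs, config, candidate_rows=rows_b)
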