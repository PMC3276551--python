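"""Per-pocket selectivity spaces trained by Fisher's Linear Discriminant.

For each of the four pockets, binary interaction records are turned into 20
two-class training sets (pockets whose domains bind at least one peptide
carrying amino acid *a* at that ligand position, versus the remainder). An
FLD axis is trained per amino acid; the 20 unit axes assemble into a
projection matrix defining a 20-dimensional selectivity space in which
nearby pockets have similar amino-acid preferences. A query pocket is
projected into the space and the preference multisets of its nearest
training pockets are pooled to transfer specificity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .features import AMINO_ACIDS, LIGAND_POSITIONS, PocketFeatureVector

#: number of training pockets pooled for preference transfer
DEFAULT_NEIGHBORS = 40

#: shrinkage weight for the within-class scatter, relative to trace/dim
SCATTER_SHRINKAGE = 1e-3


class SelectivityError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionRecord:
    """One binary domain-peptide interaction assay outcome.

    ``peptide`` is a C-terminal sequence; its last four residues define
    ligand positions -3, -2, -1, 0 with position 0 the very C-terminus.
    """

    domain_id: str
    peptide: str
    binder: bool
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.peptide) < 4:
            raise SelectivityError(
                f"peptide {self.peptide!r} shorter than the 4-residue motif"
            )
        bad = set(self.peptide.upper()) - set(AMINO_ACIDS)
        if bad:
            raise SelectivityError(f"non-standard residue(s) {sorted(bad)} in peptide")

    def residue_at(self, position: int) -> str:
        """Residue of this peptide at ligand position 0, -1, -2 or -3."""
        if position not in LIGAND_POSITIONS:
            raise SelectivityError(f"position must be one of {LIGAND_POSITIONS}")
        return self.peptide.upper()[position - 1]


def preference_profiles(
    interactions: list[InteractionRecord], position: int
) -> dict[str, Counter]:
    """Multiset of amino acids each domain's bound peptides show at one position."""
    prefs: dict[str, Counter] = {}
    for rec in interactions:
        if not rec.binder:
            continue
        prefs.setdefault(rec.domain_id, Counter())[rec.residue_at(position)] += 1
    return prefs


def build_training_sets(
    interactions: list[InteractionRecord],
    pockets: dict[str, PocketFeatureVector],
    pocket_id: int,
) -> dict[str, tuple[list[str], list[str]]]:
    """Split training pockets into positive/negative sets per amino acid.

    A domain is positive for amino acid *a* if at least one of its bound
    peptides carries *a* at the pocket's ligand position; every other
    training pocket is negative. Only domains with a feature vector for
    this pocket participate.
    """
    binders = [r for r in interactions if r.binder and r.domain_id in pockets]
    if not any(r.binder for r in interactions):
        raise SelectivityError("no binder records: training sets are undefined")
    prefs = preference_profiles(binders, pocket_id)
    trainable = sorted(prefs)  # domains with >=1 bound peptide and a vector
    sets = {}
    for aa in AMINO_ACIDS:
        pos = [d for d in trainable if aa in prefs[d]]
        neg = [d for d in trainable if aa not in prefs[d]]
        sets[aa] = (pos, neg)
    return sets


def train_fld_axis(
    positives: np.ndarray, negatives: np.ndarray
) -> tuple[np.ndarray, float]:
    """Train one two-class Fisher discriminant axis.

    The axis is the classical closed form ``w ∝ S_W⁻¹ (μ₊ − μ₋)`` with the
    within-class scatter shrunk toward a scaled identity,
    ``S_W + λ (tr S_W / d) I`` with λ = 1e-3, so few-sample classes with
    singular scatter remain trainable. The returned axis has unit norm.

    The Fisher score is the squared between-class mean separation along the
    axis divided by the pooled within-class variance along the axis.
    """
    pos = np.atleast_2d(np.asarray(positives, dtype=float))
    neg = np.atleast_2d(np.asarray(negatives, dtype=float))
    if pos.shape[0] < 1 or neg.shape[0] < 1:
        raise SelectivityError("each class needs at least one vector")
    if pos.shape[1] != neg.shape[1]:
        raise SelectivityError("class vectors have different dimensionality")
    d = pos.shape[1]
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    delta = mu_p - mu_n
    if not np.any(np.abs(delta) > 1e-12):
        raise SelectivityError("degenerate discriminant: identical class means")
    sw = np.zeros((d, d))
    for cls, mu in ((pos, mu_p), (neg, mu_n)):
        centered = cls - mu
        sw += centered.T @ centered
    lam = SCATTER_SHRINKAGE * (np.trace(sw) / d if np.trace(sw) > 0 else 1.0)
    lam = lam if lam > 0 else SCATTER_SHRINKAGE
    w = np.linalg.solve(sw + lam * np.eye(d), delta)
    w = w / np.linalg.norm(w)

    n = pos.shape[0] + neg.shape[0]
    within = float(w @ sw @ w) / max(n - 2, 1)
    sep = float(w @ delta) ** 2
    fisher = sep / within if within > 0 else np.inf
    return w, fisher


@dataclass
class SelectivitySpace:
    """A pocket's 20-axis discriminant space plus its training pockets.

    ``projection`` is feature_dim x 20 (one unit-norm column per amino
    acid; zero columns mark amino acids with no positive training pocket).
    ``training_coords`` are the training feature vectors projected into the
    space; ``training_prefs`` carries each training pocket's amino-acid
    preference multiset at this ligand position.
    """

    pocket_id: int
    projection: np.ndarray = field(repr=False)
    training_ids: list[str] = field(default_factory=list)
    training_coords: np.ndarray = field(default=None, repr=False)
    training_prefs: dict[str, Counter] = field(default_factory=dict)
    fisher_scores: dict[str, float] = field(default_factory=dict)
    untrainable: tuple[str, ...] = ()

    @property
    def n_training(self) -> int:
        return len(self.training_ids)


def build_selectivity_space(
    interactions: list[InteractionRecord],
    pockets: dict[str, PocketFeatureVector],
    pocket_id: int,
    max_untrainable: int = 10,
) -> SelectivitySpace:
    """Assemble the 20 FLD axes of one pocket into a selectivity space.

    Amino acids with no positive (or no negative) training pocket get a
    zero axis and are flagged; more than ``max_untrainable`` such axes is
    an error because the space no longer discriminates.
    """
    sets = build_training_sets(interactions, pockets, pocket_id)
    prefs = preference_profiles(
        [r for r in interactions if r.domain_id in pockets], pocket_id
    )
    training_ids = sorted(prefs)
    if not training_ids:
        raise SelectivityError(f"no trainable pockets for pocket {pocket_id}")
    vectors = {d: pockets[d].values for d in training_ids}
    dim = len(next(iter(vectors.values())))

    projection = np.zeros((dim, 20))
    fisher: dict[str, float] = {}
    untrainable: list[str] = []
    for j, aa in enumerate(AMINO_ACIDS):
        pos_ids, neg_ids = sets[aa]
        if not pos_ids or not neg_ids:
            untrainable.append(aa)
            continue
        try:
            axis, fs = train_fld_axis(
                np.array([vectors[d] for d in pos_ids]),
                np.array([vectors[d] for d in neg_ids]),
            )
        except SelectivityError:
            untrainable.append(aa)
            continue
        projection[:, j] = axis
        fisher[aa] = fs
    if len(untrainable) > max_untrainable:
        raise SelectivityError(
            f"{len(untrainable)} of 20 axes untrainable for pocket {pocket_id}"
        )

    coords = np.array([vectors[d] for d in training_ids]) @ projection
    return SelectivitySpace(
        pocket_id=pocket_id,
        projection=projection,
        training_ids=training_ids,
        training_coords=coords,
        training_prefs={d: Counter(prefs[d]) for d in training_ids},
        fisher_scores=fisher,
        untrainable=tuple(untrainable),
    )


def project_pocket(vector: PocketFeatureVector, space: SelectivitySpace) -> np.ndarray:
    """Project a pocket feature vector onto the 20 selectivity axes."""
    v = vector.values if isinstance(vector, PocketFeatureVector) else np.asarray(vector)
    if v.shape[0] != space.projection.shape[0]:
        raise SelectivityError(
            f"dimension mismatch: vector {v.shape[0]} vs space {space.projection.shape[0]}"
        )
    return v @ space.projection


@dataclass(frozen=True)
class Neighbor:
    domain_id: str
    distance: float
    prefs: Counter


def nearest_neighbors(
    coords: np.ndarray, space: SelectivitySpace, k: int = DEFAULT_NEIGHBORS
) -> list[Neighbor]:
    """The k nearest training pockets by Euclidean distance in the space.

    Ties are broken by domain_id lexicographic order so ranked output is
    reproducible regardless of training-set input order.
    """
    if k < 1:
        raise SelectivityError("k must be >= 1")
    if k > space.n_training:
        raise SelectivityError(
            f"k={k} exceeds the {space.n_training} training pockets; reduce k"
        )
    dists = np.linalg.norm(space.training_coords - np.asarray(coords), axis=1)
    order = sorted(range(space.n_training), key=lambda i: (dists[i], space.training_ids[i]))
    return [
        Neighbor(space.training_ids[i], float(dists[i]), space.training_prefs[space.training_ids[i]])
        for i in order[:k]
    ]


def build_all_spaces(
    interactions: list[InteractionRecord],
    pockets_by_position: dict[int, dict[str, PocketFeatureVector]],
) -> dict[int, SelectivitySpace]:
    """One selectivity space per ligand position."""
    return {
        p: build_selectivity_space(interactions, pockets_by_position[p], p)
        for p in LIGAND_POSITIONS
    }
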