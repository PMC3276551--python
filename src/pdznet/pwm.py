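"""Position weight matrices for C-terminal motif scoring.

The preference pool gathered from a pocket's nearest neighbors is turned
into per-position amino-acid frequencies, compared against background
frequencies of C-termini in the target proteome, and expressed as affinity
contributions

    PWM(a, i) = log2(f_a,i / p_a,i) + k

with add-one pseudocounts on both the pool and the background. The binding
score of a peptide is the sum of the contributions of its four C-terminal
residues; the offset constant ``k`` is calibrated so that every
experimentally confirmed interaction in the training corpus scores
positive (the published corpus-scale value is 1.921).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import AMINO_ACIDS, LIGAND_POSITIONS
from .selectivity import (
    DEFAULT_NEIGHBORS,
    InteractionRecord,
    SelectivitySpace,
    nearest_neighbors,
    project_pocket,
)

#: corpus-scale offset reported for the published training set (provenance)
PUBLISHED_K = 1.921


class PwmError(ValueError):
    pass


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Per-position amino-acid probabilities of proteome C-termini.

    ``probs`` is a 20 x 4 DataFrame (rows = amino acids, columns = ligand
    positions -3..0); each column sums to 1 and is strictly positive after
    add-one smoothing.
    """

    probs: pd.DataFrame = field(repr=False)

    def p(self, aa: str, position: int) -> float:
        return float(self.probs.at[aa, position])

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        df = pd.DataFrame(0.05, index=list(AMINO_ACIDS), columns=list(LIGAND_POSITIONS))
        return cls(df)


def background_frequencies(ctermini: list[str]) -> BackgroundFrequencies:
    """Tally the last four residues of each proteome sequence.

    Counts are add-one smoothed per position so every amino acid has
    positive probability even in small proteomes.
    """
    if not ctermini:
        raise PwmError("empty proteome: background frequencies are undefined")
    counts = pd.DataFrame(0, index=list(AMINO_ACIDS), columns=list(LIGAND_POSITIONS))
    for seq in ctermini:
        s = seq.upper()
        if len(s) < 4:
            raise PwmError(f"sequence {seq!r} shorter than the 4-residue window")
        for pos in LIGAND_POSITIONS:
            aa = s[pos - 1]
            if aa not in counts.index:
                raise PwmError(f"non-standard residue {aa!r} in {seq!r}")
            counts.at[aa, pos] += 1
    smoothed = counts + 1
    return BackgroundFrequencies(smoothed / smoothed.sum(axis=0))


@dataclass
class PWM:
    """Affinity-contribution table of one PDZ domain.

    ``matrix`` is 20 amino acids x 4 ligand positions (-3, -2, -1, 0) in
    bits-plus-offset units. ``others_value`` gives the per-position
    fallback contribution used for amino acids absent from a loaded table
    (for tables built here it equals the per-position minimum, which the
    pseudocount places at or below every preferred amino acid).
    """

    domain_id: str
    matrix: pd.DataFrame = field(repr=False)
    k: float = 0.0
    others_value: dict[int, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(LIGAND_POSITIONS):
            self.matrix = self.matrix[list(LIGAND_POSITIONS)]
        if not np.all(np.isfinite(self.matrix.to_numpy(dtype=float))):
            raise PwmError("PWM contains non-finite entries")
        if not self.others_value:
            self.others_value = {
                p: float(self.matrix[p].min()) for p in LIGAND_POSITIONS
            }

    def contribution(self, aa: str, position: int) -> float:
        """PWM(a, i), falling back to the position's "others" value."""
        aa = aa.upper()
        if aa in self.matrix.index:
            return float(self.matrix.at[aa, position])
        if aa in AMINO_ACIDS:
            return self.others_value[position]
        raise PwmError(f"non-standard residue {aa!r}")

    def shifted(self, delta: float) -> "PWM":
        """A copy with ``delta`` added to every cell (and to k)."""
        return PWM(
            self.domain_id,
            self.matrix + delta,
            self.k + delta,
            {p: v + delta for p, v in self.others_value.items()},
            dict(self.provenance),
        )


def build_pwm(
    neighbor_prefs: dict[int, Counter],
    background: BackgroundFrequencies,
    k: float = 0.0,
    domain_id: str = "query",
    provenance: dict | None = None,
) -> PWM:
    """Convert per-position preference pools into a PWM.

    ``neighbor_prefs`` maps each ligand position to the multiset of amino
    acids pooled from the neighbors' bound peptides. Pool frequencies are
    add-one smoothed over the 20-letter alphabet, so unobserved amino
    acids receive the pseudocount-implied ("others") contribution.
    """
    matrix = pd.DataFrame(
        0.0, index=list(AMINO_ACIDS), columns=list(LIGAND_POSITIONS)
    )
    for pos in LIGAND_POSITIONS:
        pool = neighbor_prefs.get(pos)
        if not pool or sum(pool.values()) == 0:
            raise PwmError(f"empty preference pool at position {pos}")
        total = sum(pool.values())
        for aa in AMINO_ACIDS:
            f = (pool.get(aa, 0) + 1) / (total + 20)
            matrix.at[aa, pos] = math.log2(f / background.p(aa, pos)) + k
    return PWM(domain_id, matrix, k, provenance=provenance or {})


def predict_pwm(
    query_vectors: dict[int, "object"],
    spaces: dict[int, SelectivitySpace],
    background: BackgroundFrequencies,
    k: float = 0.0,
    n_neighbors: int = DEFAULT_NEIGHBORS,
    domain_id: str = "query",
) -> PWM:
    """Full prediction step: project pockets, pool neighbor preferences, build PWM.

    ``n_neighbors`` is capped at the number of training pockets in each
    space so sparse corpora remain usable.
    """
    pools: dict[int, Counter] = {}
    for pos in LIGAND_POSITIONS:
        space = spaces[pos]
        coords = project_pocket(query_vectors[pos], space)
        kk = min(n_neighbors, space.n_training)
        pool: Counter = Counter()
        for nb in nearest_neighbors(coords, space, kk):
            pool.update(nb.prefs)
        pools[pos] = pool
    return build_pwm(
        pools,
        background,
        k,
        domain_id=domain_id,
        provenance={"n_neighbors": n_neighbors},
    )


def score_peptide(pwm: PWM, peptide: str) -> float:
    """Binding score: sum of PWM(S_i, i) over the last four residues."""
    s = peptide.upper()
    if len(s) < 4:
        raise PwmError(f"peptide {peptide!r} shorter than the 4-residue motif")
    return sum(pwm.contribution(s[pos - 1], pos) for pos in LIGAND_POSITIONS)


def calibrate_k(
    raw_pwms: dict[str, PWM], confirmed: list[InteractionRecord], resolution: float = 1e-3
) -> float:
    """Smallest non-negative k making every confirmed interaction score > 0.

    ``raw_pwms`` are built with k = 0; adding k to every cell raises each
    4-term score by 4k, so k = ceil(-min_raw/4) at the given resolution,
    bumped one step when the minimum would land exactly at zero.
    """
    scorable = [r for r in confirmed if r.binder and r.domain_id in raw_pwms]
    if not scorable:
        raise PwmError("no confirmed interactions to calibrate against")
    min_raw = min(score_peptide(raw_pwms[r.domain_id], r.peptide) for r in scorable)
    if min_raw > 0:
        return 0.0
    steps = math.ceil(-min_raw / 4 / resolution - 1e-9)
    k = steps * resolution
    if min_raw + 4 * k <= 0:
        k = (steps + 1) * resolution
    return round(k, 9)


def rank_proteome(pwm: PWM, proteome: dict[str, str]) -> pd.DataFrame:
    """Score every proteome C-terminus and rank descending.

    Returns a DataFrame (protein_id, motif, score, rank, percentile) with
    percentile = 100 * (1 - rank/N); equal scores are ordered by
    protein_id so ranks are deterministic.
    """
    if not proteome:
        raise PwmError("empty proteome")
    rows = [
        {
            "protein_id": pid,
            "motif": seq.upper()[-4:],
            "score": score_peptide(pwm, seq),
        }
        for pid, seq in proteome.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["score", "protein_id"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df["percentile"] = 100.0 * (1.0 - df["rank"] / len(df))
    return df.reset_index(drop=True)


def percentile_of(ranked: pd.DataFrame, protein_id: str) -> float:
    row = ranked.loc[ranked["protein_id"] == protein_id]
    if row.empty:
        raise PwmError(f"{protein_id} not in ranked proteome")
    return float(row["percentile"].iloc[0])


def loocv_evaluate(
    interactions: list[InteractionRecord],
    pockets_by_position: dict[int, dict[str, "object"]],
    proteome: dict[str, str],
    ligand_of: dict[str, list[str]],
    k: float = 0.0,
    n_neighbors: int = DEFAULT_NEIGHBORS,
    percentile_threshold: float = 90.0,
) -> tuple[float, pd.DataFrame]:
    """Domain-wise leave-one-out evaluation of ligand recovery.

    For each domain with known proteome ligands, all of its interaction
    records are withheld, the four selectivity spaces are rebuilt from the
    remaining records, its PWM is predicted, the proteome is ranked, and
    the percentile of every known ligand is recorded. Returns the fraction
    of known ligands at or above ``percentile_threshold`` plus a
    per-ligand table. Domains whose ligands are absent from the proteome
    are skipped and noted in the table.
    """
    from .selectivity import build_all_spaces

    background = background_frequencies(list(proteome.values()))
    records = []
    domains = sorted(d for d in ligand_of if all(
        d in pockets_by_position[p] for p in LIGAND_POSITIONS
    ))
    if len(domains) < 2:
        raise PwmError("leave-one-out needs at least two domains with binders")
    for dom in domains:
        ligands = [l for l in ligand_of[dom] if l in proteome]
        if not ligands:
            records.append(
                {"domain_id": dom, "ligand": None, "percentile": np.nan, "skipped": True}
            )
            continue
        held_in = [r for r in interactions if r.domain_id != dom]
        spaces = build_all_spaces(held_in, pockets_by_position)
        query = {p: pockets_by_position[p][dom] for p in LIGAND_POSITIONS}
        pwm = predict_pwm(query, spaces, background, k, n_neighbors, domain_id=dom)
        ranked = rank_proteome(pwm, proteome)
        for lig in ligands:
            records.append(
                {
                    "domain_id": dom,
                    "ligand": lig,
                    "percentile": percentile_of(ranked, lig),
                    "skipped": False,
                }
            )
    table = pd.DataFrame(records)
    scored = table.loc[~table["skipped"], "percentile"]
    if scored.empty:
        raise PwmError("no scorable ligands in the leave-one-out evaluation")
    fraction = float((scored >= percentile_threshold).mean())
    return fraction, table
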