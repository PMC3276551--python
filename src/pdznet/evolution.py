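"""Tracing C-terminal motif gain and interaction rewiring across species.

A human PDZ ligand's orthologs are followed across a ladder of species
ordered by divergence time from human. Scoring each ortholog's C-terminal
tetrapeptide against the partner domain's PWM reveals when the binding
motif was gained: the interaction is called present in a species when an
ortholog exists *and* its score clears the threshold (0 is the natural
threshold after k-calibration, which makes all confirmed binders score
positive). An interaction absent in a more distant species but present in
a closer one is rewired, and the rewiring rate normalizes rewired counts
by divergence time and by the sizes of the orthologous opportunity sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .pwm import PWM, score_peptide

ABSENT = "-"

GAIN_CATEGORIES = (
    "premetazoan-origin/vertebrate-gain",
    "invertebrate-origin/vertebrate-gain",
    "invertebrate-gain",
    "no-gain",
    "always-binder",
)


class EvolutionError(ValueError):
    pass


@dataclass(frozen=True)
class Species:
    """One rung of the species ladder.

    ``divergence_myr`` is the time to the last common ancestor with human
    (million years); ``group`` is 'premetazoan', 'invertebrate' or
    'vertebrate'.
    """

    name: str
    divergence_myr: float
    group: str = "vertebrate"

    def __post_init__(self) -> None:
        if self.divergence_myr <= 0:
            raise EvolutionError("divergence time must be positive")


def species_ladder(species: list[Species]) -> list[Species]:
    """Order species most-distant-first; reject duplicated divergence ranks."""
    if len({s.name for s in species}) != len(species):
        raise EvolutionError("duplicate species names in ladder")
    return sorted(species, key=lambda s: -s.divergence_myr)


@dataclass
class OrthologTrace:
    """Per-species presence and C-terminal tetrapeptide of one protein's orthologs.

    ``ctermini`` maps species name to the tetrapeptide, or to '-' when no
    ortholog was found in that species.
    """

    protein_id: str
    ctermini: dict[str, str] = field(default_factory=dict)

    def present(self, species_name: str) -> bool:
        seq = self.ctermini.get(species_name, ABSENT)
        return seq != ABSENT and bool(seq)

    def motif(self, species_name: str) -> str:
        if not self.present(species_name):
            raise EvolutionError(f"no ortholog of {self.protein_id} in {species_name}")
        return self.ctermini[species_name].upper()[-4:]


@dataclass(frozen=True)
class RewiringInput:
    """Inputs of the rewiring-rate calculation for one species interval."""

    n_j: int
    t: float
    p_all_i: int
    p_pdz_j: int

    def __post_init__(self) -> None:
        if min(self.n_j, self.p_all_i, self.p_pdz_j) < 0 or self.t <= 0:
            raise EvolutionError("rewiring inputs must be non-negative with t > 0")


def default_rate_formula(inp: RewiringInput) -> float:
    """Rewired interactions per Myr per (ortholog x PDZ-ortholog) opportunity."""
    return inp.n_j / (inp.t * inp.p_all_i * inp.p_pdz_j)


def rewiring_rate(
    inp: RewiringInput, formula: Callable[[RewiringInput], float] = default_rate_formula
) -> float:
    """Normalized rewiring rate; the formula hook is swappable."""
    if inp.p_all_i == 0 or inp.p_pdz_j == 0:
        raise EvolutionError("no opportunity set: zero ortholog count")
    return formula(inp)


@dataclass
class GainClassification:
    category: str
    gain_species: str | None
    scores: dict[str, float]


def classify_motif_gain(
    trace: OrthologTrace,
    pwm: PWM,
    ladder: list[Species],
    threshold: float = 0.0,
) -> GainClassification:
    """Locate the species in which a protein's PDZ-binding motif was gained.

    Present species are scored most-distant-first. The gain is called at
    the earliest (most distant) species whose score exceeds the threshold
    while every more-distant present species scores at or below it. A
    trace that binds already in its most distant species is an
    always-binder; one that never binds is no-gain. Otherwise the category
    combines the origin group (group of the most distant present species)
    with the gain species' group.
    """
    ordered = species_ladder(ladder)
    present = [s for s in ordered if trace.present(s.name)]
    if not present:
        raise EvolutionError(f"trace {trace.protein_id} has no present species")
    scores = {s.name: score_peptide(pwm, trace.motif(s.name)) for s in present}
    binder = [scores[s.name] > threshold for s in present]

    if all(binder):
        return GainClassification("always-binder", None, scores)
    if not any(binder):
        return GainClassification("no-gain", None, scores)

    # earliest binding species with no more-distant binder
    gain = None
    for i, s in enumerate(present):
        if binder[i] and not any(binder[:i]):
            gain = s
            break
    if gain is None:
        # a more distant binder always precedes: binding was present then
        # lost and regained; no clean gain event
        return GainClassification("no-gain", None, scores)

    origin_group = present[0].group
    if gain.group == "vertebrate":
        if origin_group == "premetazoan":
            category = "premetazoan-origin/vertebrate-gain"
        else:
            category = "invertebrate-origin/vertebrate-gain"
    else:
        category = "invertebrate-gain"
    return GainClassification(category, gain.name, scores)


def interaction_present(
    trace: OrthologTrace, pwm: PWM, species_name: str, threshold: float = 0.0
) -> bool:
    """Presence call: an ortholog exists and its motif scores above threshold."""
    return trace.present(species_name) and score_peptide(pwm, trace.motif(species_name)) > threshold


def detect_rewired_interactions(
    human_edges: list[tuple[str, str]],
    traces: dict[str, OrthologTrace],
    pwms: dict[str, PWM],
    ladder: list[Species],
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Count rewired interactions per adjacent species interval.

    ``human_edges`` are (pdz_protein, ligand) pairs; each ligand needs an
    ortholog trace and each PDZ protein a PWM. For every adjacent ladder
    interval (i more distant, j closer) an interaction is rewired when its
    presence call is false in i and true in j. The returned frame has one
    row per interval with the rewired count.
    """
    ordered = species_ladder(ladder)
    if len(ordered) < 2:
        raise EvolutionError("species ladder needs at least two species")
    rows = []
    for sp_i, sp_j in zip(ordered[:-1], ordered[1:]):
        count = 0
        for pdz, lig in human_edges:
            trace, pwm = traces.get(lig), pwms.get(pdz)
            if trace is None or pwm is None:
                continue
            absent_i = not interaction_present(trace, pwm, sp_i.name, threshold)
            present_j = interaction_present(trace, pwm, sp_j.name, threshold)
            if absent_i and present_j:
                count += 1
        rows.append(
            {
                "from_species": sp_i.name,
                "to_species": sp_j.name,
                "from_group": sp_i.group,
                "to_group": sp_j.group,
                "divergence_myr": sp_j.divergence_myr,
                "n_rewired": count,
            }
        )
    return pd.DataFrame(rows)


def phylo_profile(traces: list[OrthologTrace], species: list[Species]) -> pd.DataFrame:
    """Boolean proteins x species presence matrix (most distant species first)."""
    ordered = species_ladder(species)
    data = {
        t.protein_id: [t.present(s.name) for s in ordered] for t in traces
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[s.name for s in ordered]
    ).astype(bool)
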