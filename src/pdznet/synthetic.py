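"""Seeded synthetic data with planted ground truth.

Generates every input the pipeline consumes: PDZ domains whose pocket
residue physicochemistry determines planted amino-acid preferences, binder
peptides drawn from those preferences, a background proteome, a bipartite
network with paralog families and a planted paralog-fraction asymmetry,
ortholog ladders with planted motif-gain epochs, and annotation classes
with planted enrichment. Ground-truth tables are emitted alongside the
data so every downstream statistic has an independently computable
expected value.

Domains fall into latent preference classes. Each class assigns one
physicochemical residue group (hydrophobic, polar, charged, small) to each
of the four pockets; pocket residues are sampled from that group, and the
class's preferred ligand amino acids at the corresponding position come
from the same group — so pockets that look alike in feature space prefer
alike, which is the signal the selectivity spaces are built to exploit.

Emulated C-termini are length 10 with only the terminal four positions
carrying signal, matching the scoring window. All randomness flows from a
single master seed through named substreams so components can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import AMINO_ACIDS, LIGAND_POSITIONS, load_index_table
from .network import PdzNetwork
from .pockets import AlignedDomain, PdzDomainRecord, PocketDefinition
from .pwm import PWM
from .selectivity import InteractionRecord
from .evolution import ABSENT, OrthologTrace, Species

#: disjoint physicochemical residue groups used to plant preferences
RESIDUE_GROUPS = {
    "hydrophobic": ("V", "L", "I", "M", "F", "W"),
    "polar": ("S", "T", "N", "Q", "Y"),
    "positive": ("K", "R", "H"),
    "negative": ("D", "E"),
    "small": ("G", "A", "P", "C"),
}

_LINKER = "GSGS"


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions of the synthetic world.

    Defaults match the conditions the model is evaluated under: 30 domains
    in 3 latent preference classes with a 5% label-noise rate, a
    300-protein background proteome, and 12 binder / 4 non-binder records
    per domain (about the interaction density per domain of real training
    corpora).
    """

    n_domains: int = 30
    n_classes: int = 3
    noise: float = 0.05
    n_binders: int = 12
    n_nonbinders: int = 4
    n_proteome: int = 300
    n_planted_ligands_per_class: int = 4
    pocket_len: int = 4
    pocket_mutation_rate: float = 0.2
    linker_mutation_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.n_domains < 10 or self.n_proteome < 100:
            raise SyntheticError("need >= 10 domains and >= 100 proteome sequences")
        if self.n_classes > self.n_domains:
            raise SyntheticError("more latent classes than domains")
        if not 0.0 <= self.noise < 1.0:
            raise SyntheticError("noise rate must be in [0, 1)")


@dataclass
class SyntheticWorld:
    """All generated inputs plus their ground truth."""

    seed: int
    config: WorldConfig
    domains: list[PdzDomainRecord]
    aligned: list[AlignedDomain]
    pocket_definition: PocketDefinition
    class_of_domain: dict[str, int]
    preferred: dict[tuple[int, int], tuple[str, ...]]  # (class, pocket) -> aa set
    pocket_group: dict[tuple[int, int], str]
    interactions: list[InteractionRecord]
    proteome: dict[str, str]
    planted_ligands: dict[int, list[str]]
    ligand_of: dict[str, list[str]]
    network: PdzNetwork
    paralog_pairs: set[tuple[str, str]]
    species: list[Species]
    traces: dict[str, OrthologTrace]
    trace_gain_epoch: dict[str, int]
    annotation_classes: dict[str, set[str]]
    annotation_background: set[str]
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)


def _rng_streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _mutate_within(residue: str, group: tuple[str, ...], rate: float, rng) -> str:
    if rng.random() < rate:
        return str(rng.choice(group))
    return residue


def generate_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate a complete, reproducible synthetic study world."""
    config = config or WorldConfig()
    rng = _rng_streams(
        seed,
        ["classes", "domains", "binders", "proteome", "network", "orthologs", "annotations"],
    )

    group_names = sorted(RESIDUE_GROUPS)
    # class/pocket -> residue group, consensus pocket residues, preferred ligand aa
    preferred: dict[tuple[int, int], tuple[str, ...]] = {}
    pocket_group: dict[tuple[int, int], str] = {}
    consensus: dict[tuple[int, int], str] = {}
    for cls in range(config.n_classes):
        # cycle groups so classes differ at every pocket
        for idx, pocket in enumerate(LIGAND_POSITIONS):
            g = group_names[(cls + idx) % len(group_names)]
            members = RESIDUE_GROUPS[g]
            pocket_group[(cls, pocket)] = g
            # pockets are multispecific: several residues are tolerated
            pref = rng["classes"].choice(members, size=min(3, len(members)), replace=False)
            preferred[(cls, pocket)] = tuple(sorted(pref))
            consensus[(cls, pocket)] = "".join(
                rng["classes"].choice(members, size=config.pocket_len)
            )
    # binding motifs are degenerate: top up class preferences round-robin so
    # every position tolerates a broad residue repertoire across families
    for pocket in LIGAND_POSITIONS:
        union = {a for cls in range(config.n_classes) for a in preferred[(cls, pocket)]}
        remaining = [a for a in AMINO_ACIDS if a not in union]
        cls_cycle = 0
        while len(union) < 11 and remaining:
            extra = str(rng["classes"].choice(remaining))
            cls = cls_cycle % config.n_classes
            preferred[(cls, pocket)] = tuple(sorted(preferred[(cls, pocket)] + (extra,)))
            union.add(extra)
            remaining.remove(extra)
            cls_cycle += 1

    # --- domains: pocket blocks joined by linkers; trivial (gap-free) alignment
    pocket_cols: dict[int, tuple[int, ...]] = {}
    offset = 0
    layout: list[tuple[int | None, int]] = []  # (pocket or None for linker, length)
    for pocket in LIGAND_POSITIONS:
        layout.append((None, len(_LINKER)))
        offset += len(_LINKER)
        pocket_cols[pocket] = tuple(range(offset, offset + config.pocket_len))
        layout.append((pocket, config.pocket_len))
        offset += config.pocket_len
    layout.append((None, len(_LINKER)))
    definition = PocketDefinition(pocket_cols)

    domains: list[PdzDomainRecord] = []
    aligned: list[AlignedDomain] = []
    class_of: dict[str, int] = {}
    for i in range(config.n_domains):
        cls = i % config.n_classes
        protein = f"PDZP{i:03d}"
        domain_id = f"{protein}_1"
        parts = []
        pockets: dict[int, str] = {}
        for pocket_or_none, length in layout:
            if pocket_or_none is None:
                parts.append(
                    "".join(
                        str(rng["domains"].choice(list(AMINO_ACIDS)))
                        if rng["domains"].random() < config.linker_mutation_rate
                        else c
                        for c in _LINKER[:length]
                    )
                )
            else:
                g = RESIDUE_GROUPS[pocket_group[(cls, pocket_or_none)]]
                residues = "".join(
                    _mutate_within(c, g, config.pocket_mutation_rate, rng["domains"])
                    for c in consensus[(cls, pocket_or_none)]
                )
                pockets[pocket_or_none] = residues
                parts.append(residues)
        seq = "".join(parts)
        domains.append(PdzDomainRecord(domain_id, protein, "synthetic", seq))
        aligned.append(AlignedDomain(domain_id, seq, pockets))
        class_of[domain_id] = cls

    # --- interaction records
    aa_list = list(AMINO_ACIDS)
    interactions: list[InteractionRecord] = []
    for dom in domains:
        cls = class_of[dom.domain_id]
        for _ in range(config.n_binders):
            prefix = "".join(rng["binders"].choice(aa_list, size=6))
            tetra = []
            for pocket in LIGAND_POSITIONS:
                if rng["binders"].random() < config.noise:
                    tetra.append(str(rng["binders"].choice(aa_list)))
                else:
                    tetra.append(str(rng["binders"].choice(preferred[(cls, pocket)])))
            interactions.append(
                InteractionRecord(dom.domain_id, prefix + "".join(tetra), True, "synthetic-assay")
            )
        for _ in range(config.n_nonbinders):
            tetra = []
            for pocket in LIGAND_POSITIONS:
                avoid = set(preferred[(cls, pocket)])
                choices = [a for a in aa_list if a not in avoid]
                tetra.append(str(rng["binders"].choice(choices)))
            prefix = "".join(rng["binders"].choice(aa_list, size=6))
            interactions.append(
                InteractionRecord(dom.domain_id, prefix + "".join(tetra), False, "synthetic-assay")
            )

    # --- background proteome + planted ligand proteins
    proteome: dict[str, str] = {}
    for i in range(config.n_proteome):
        proteome[f"BG{i:04d}"] = "".join(rng["proteome"].choice(aa_list, size=10))
    planted: dict[int, list[str]] = {c: [] for c in range(config.n_classes)}
    for cls in range(config.n_classes):
        for j in range(config.n_planted_ligands_per_class):
            pid = f"LIG{cls}{j:02d}"
            prefix = "".join(rng["proteome"].choice(aa_list, size=6))
            tetra = "".join(
                str(rng["proteome"].choice(preferred[(cls, pocket)]))
                for pocket in LIGAND_POSITIONS
            )
            proteome[pid] = prefix + tetra
            planted[cls].append(pid)
    ligand_of = {
        d.domain_id: list(planted[class_of[d.domain_id]]) for d in domains
    }

    # --- bipartite network with paralog families (classes) and planted
    # PDZ-side > ligand-side paralog-fraction asymmetry
    net = PdzNetwork()
    for dom in domains:
        cls = class_of[dom.domain_id]
        for lig in planted[cls]:
            net.add_interaction(
                dom.protein_id,
                lig,
                motif=proteome[lig][-4:],
                evidence=("synthetic",),
                domain_id=dom.domain_id,
            )
    paralog_pairs: set[tuple[str, str]] = set()
    proteins_by_class: dict[int, list[str]] = {}
    for dom in domains:
        proteins_by_class.setdefault(class_of[dom.domain_id], []).append(dom.protein_id)
    for members in proteins_by_class.values():
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                paralog_pairs.add(tuple(sorted((members[a_idx], members[b_idx]))))
    # a thin minority of ligand pairs are paralogous
    for cls, ligands in planted.items():
        if len(ligands) >= 2 and rng["network"].random() < 0.5:
            pair = rng["network"].choice(len(ligands), size=2, replace=False)
            paralog_pairs.add(tuple(sorted((ligands[pair[0]], ligands[pair[1]]))))

    # --- ortholog ladder with gains concentrated at the
    # invertebrate -> vertebrate boundary
    species = default_species_ladder()
    vertebrate_epoch = next(
        i for i, s in enumerate(species) if s.group == "vertebrate"
    )
    traces: dict[str, OrthologTrace] = {}
    gain_epochs: dict[str, int] = {}
    for cls, ligands in planted.items():
        for lig in ligands:
            # most gains at the vertebrate boundary, a few earlier
            if rng["orthologs"].random() < 0.8:
                epoch = vertebrate_epoch
            else:
                epoch = int(rng["orthologs"].integers(1, vertebrate_epoch))
            ctermini: dict[str, str] = {}
            for s_idx, sp in enumerate(species):
                if s_idx == 0 and rng["orthologs"].random() < 0.2:
                    ctermini[sp.name] = ABSENT
                    continue
                if s_idx >= epoch:
                    ctermini[sp.name] = proteome[lig][-4:]
                else:
                    tetra = []
                    for pocket in LIGAND_POSITIONS:
                        avoid = set(preferred[(cls, pocket)])
                        tetra.append(
                            str(rng["orthologs"].choice([a for a in aa_list if a not in avoid]))
                        )
                    ctermini[sp.name] = "".join(tetra)
            traces[lig] = OrthologTrace(lig, ctermini)
            gain_epochs[lig] = epoch

    # --- annotation classes with planted enrichment of network members
    background = set(proteome) | {d.protein_id for d in domains}
    net_nodes = sorted(net.graph.nodes)
    non_members = sorted(background - set(net_nodes))
    enriched = set(
        rng["annotations"].choice(net_nodes, size=max(3, len(net_nodes) // 2), replace=False)
    ) | set(rng["annotations"].choice(non_members, size=5, replace=False))
    flat = set(rng["annotations"].choice(non_members, size=30, replace=False))
    annotation_classes = {"neurological": enriched, "metabolic": flat}

    truth = {
        "preferences": pd.DataFrame(
            [
                {"class": cls, "pocket": pocket, "group": pocket_group[(cls, pocket)],
                 "preferred": "".join(preferred[(cls, pocket)])}
                for cls in range(config.n_classes)
                for pocket in LIGAND_POSITIONS
            ]
        ),
        "domain_classes": pd.DataFrame(
            [{"domain_id": d, "class": c} for d, c in sorted(class_of.items())]
        ),
        "gain_epochs": pd.DataFrame(
            [{"protein_id": p, "gain_epoch": e, "gain_species": species[e].name}
             for p, e in sorted(gain_epochs.items())]
        ),
    }

    return SyntheticWorld(
        seed=seed,
        config=config,
        domains=domains,
        aligned=aligned,
        pocket_definition=definition,
        class_of_domain=class_of,
        preferred=preferred,
        pocket_group=pocket_group,
        interactions=interactions,
        proteome=proteome,
        planted_ligands=planted,
        ligand_of=ligand_of,
        network=net,
        paralog_pairs=paralog_pairs,
        species=species,
        traces=traces,
        trace_gain_epoch=gain_epochs,
        annotation_classes=annotation_classes,
        annotation_background=background,
        truth=truth,
    )


def default_species_ladder() -> list[Species]:
    """An 8-rung ladder from yeast to mouse, most distant first."""
    return [
        Species("yeast", 1100.0, "premetazoan"),
        Species("amoeba", 950.0, "premetazoan"),
        Species("choanoflagellate", 750.0, "premetazoan"),
        Species("nematode", 650.0, "invertebrate"),
        Species("fly", 620.0, "invertebrate"),
        Species("seaurchin", 580.0, "invertebrate"),
        Species("zebrafish", 430.0, "vertebrate"),
        Species("mouse", 90.0, "vertebrate"),
    ]


def world_pocket_vectors(world: SyntheticWorld, table=None):
    """Encode the world's domain pockets with the (default) property table."""
    from .pockets import pocket_vectors

    table = table or load_index_table()
    return pocket_vectors(world.aligned, table)


def generate_ortholog_ladder(
    n_proteins: int, n_species: int, gain_epoch: int, seed: int = 0
) -> tuple[dict[str, OrthologTrace], PWM, list[Species], pd.DataFrame]:
    """Ortholog traces with one planted gain epoch plus a reference PWM.

    The reference PWM gives +2 to two preferred amino acids per position
    and -2 to the rest, so a motif drawn from the preferred sets scores +8
    while pre-gain tetrapeptides (sampled entirely outside the preferred
    sets) score -8. Traces bind from ``gain_epoch`` (0-based rung of the
    most-distant-first ladder) onward and not before.
    """
    if not 0 <= gain_epoch < n_species:
        raise SyntheticError("gain_epoch must lie within the species ladder")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    aa_list = list(AMINO_ACIDS)
    preferred = {
        pos: tuple(sorted(rng.choice(aa_list, size=2, replace=False)))
        for pos in LIGAND_POSITIONS
    }
    matrix = pd.DataFrame(-2.0, index=aa_list, columns=list(LIGAND_POSITIONS))
    for pos, prefs in preferred.items():
        for aa in prefs:
            matrix.at[aa, pos] = 2.0
    pwm = PWM("reference", matrix, k=0.0, provenance={"synthetic": True})

    if n_species < 2:
        raise SyntheticError("need at least two species")
    times = np.linspace(1000.0, 50.0, n_species)
    groups = ["invertebrate"] * n_species
    for i in range(gain_epoch, n_species):
        groups[i] = "vertebrate"
    species = [Species(f"sp{i:02d}", float(times[i]), groups[i]) for i in range(n_species)]

    traces: dict[str, OrthologTrace] = {}
    rows = []
    for p in range(n_proteins):
        pid = f"ORTH{p:03d}"
        ctermini = {}
        motif = "".join(str(rng.choice(preferred[pos])) for pos in LIGAND_POSITIONS)
        for s_idx, sp in enumerate(species):
            if s_idx >= gain_epoch:
                ctermini[sp.name] = motif
            else:
                ctermini[sp.name] = "".join(
                    str(rng.choice([a for a in aa_list if a not in preferred[pos]]))
                    for pos in LIGAND_POSITIONS
                )
        traces[pid] = OrthologTrace(pid, ctermini)
        rows.append({"protein_id": pid, "gain_epoch": gain_epoch, "motif": motif})
    return traces, pwm, species, pd.DataFrame(rows)
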