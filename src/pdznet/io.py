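"""Readers and writers for the package's plain-text formats.

Sequence formats (FASTA, aligned FASTA, Stockholm) go through Biopython.
Everything else is tab-separated text with '#' comment lines: interaction
records, PWM tables (including the published 21-row layout with an
"others" row), pocket definitions, edge lists, paralog pairs, species
ladders, ortholog traces and annotation maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import AlignIO, SeqIO

from .enrichment import AnnotationMap
from .evolution import ABSENT, OrthologTrace, Species
from .features import AMINO_ACIDS, LIGAND_POSITIONS
from .network import PpiEdge
from .pwm import PWM, PwmError
from .selectivity import InteractionRecord

logger = logging.getLogger("pdznet")


class IoError(ValueError):
    pass


# ---------------------------------------------------------------- sequences

def read_sequences(path, fmt: str = "fasta") -> dict[str, str]:
    """Read id -> sequence records; 'fasta', 'aligned-fasta' or 'stockholm'.

    Aligned formats preserve gap characters (and thus column structure).
    Duplicate ids and empty files are errors.
    """
    path = Path(path)
    if fmt in ("fasta", "aligned-fasta"):
        records = list(SeqIO.parse(path, "fasta"))
    elif fmt == "stockholm":
        records = list(AlignIO.read(path, "stockholm"))
    else:
        raise IoError(f"unknown sequence format {fmt!r}")
    if not records:
        raise IoError(f"no sequences in {path}")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise IoError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")


# ------------------------------------------------------------- interactions

def read_interactions(path) -> list[InteractionRecord]:
    """Interaction TSV: domain_id, peptide, binder, source."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"domain_id", "peptide", "binder"}
    missing = required - set(df.columns)
    if missing:
        raise IoError(f"interaction table missing column(s): {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        binder = str(row.binder).strip().lower() in ("1", "true", "yes")
        source = getattr(row, "source", "") or ""
        records.append(InteractionRecord(row.domain_id, row.peptide, binder, source))
    return records


def write_interactions(records: list[InteractionRecord], path) -> None:
    pd.DataFrame(
        [
            {"domain_id": r.domain_id, "peptide": r.peptide,
             "binder": int(r.binder), "source": r.source}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- PWMs

_POSITION_LABELS = {str(p): p for p in LIGAND_POSITIONS}


def read_pwm_table(path) -> PWM:
    """Load a PWM TSV: 20 amino-acid rows (+ optional 'others') x 4 positions.

    Header comment lines may carry ``# domain_id:`` and ``# k:`` metadata.
    The layout matches published PWM tables exported to TSV. A table
    without an "others" row loads with the per-position minimum as the
    fallback contribution (a warning is logged); unknown amino-acid rows
    and malformed numeric cells are errors naming the offending cell.
    """
    path = Path(path)
    domain_id, k = path.stem, 0.0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if text.lower().startswith("domain_id:"):
                domain_id = text.split(":", 1)[1].strip()
            elif text.lower().startswith("k:"):
                k = float(text.split(":", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    missing = [s for s in _POSITION_LABELS if s not in df.columns]
    if missing:
        raise IoError(f"PWM table missing position column(s): {missing}")
    df = df[[str(p) for p in LIGAND_POSITIONS]]

    unknown = set(df.index) - set(AMINO_ACIDS) - {"others"}
    if unknown:
        raise IoError(f"unknown amino-acid row(s): {sorted(unknown)}")
    values = pd.DataFrame(index=df.index, columns=list(LIGAND_POSITIONS), dtype=float)
    for row in df.index:
        for label, pos in _POSITION_LABELS.items():
            cell = df.at[row, label]
            try:
                values.at[row, pos] = float(cell)
            except (TypeError, ValueError):
                raise IoError(f"malformed numeric cell at row {row!r}, column {label}")

    others = None
    if "others" in values.index:
        others = {p: float(values.at["others", p]) for p in LIGAND_POSITIONS}
        values = values.drop(index="others")
    missing_aa = set(AMINO_ACIDS) - set(values.index)
    matrix = values.reindex(list(AMINO_ACIDS)).dropna(how="all")
    if others is None:
        others = {p: float(matrix[p].min()) for p in LIGAND_POSITIONS}
        logger.warning("PWM table %s has no 'others' row; using per-position minima", path)
    if missing_aa:
        matrix = matrix.loc[[a for a in AMINO_ACIDS if a in matrix.index]]
    return PWM(domain_id, matrix, k, others)


def write_pwm_table(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# domain_id: {pwm.domain_id}\n")
        fh.write(f"# k: {pwm.k!r}\n")
        fh.write("aa\t" + "\t".join(str(p) for p in LIGAND_POSITIONS) + "\n")
        for aa in pwm.matrix.index:
            cells = "\t".join(repr(float(pwm.matrix.at[aa, p])) for p in LIGAND_POSITIONS)
            fh.write(f"{aa}\t{cells}\n")
        cells = "\t".join(repr(float(pwm.others_value[p])) for p in LIGAND_POSITIONS)
        fh.write(f"others\t{cells}\n")


# ------------------------------------------------------------------ network

def read_edge_list(path) -> list[PpiEdge]:
    """Edge-list TSV: protein_a, protein_b, evidence, direct_flag."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    edges, bad = [], 0
    for row in df.itertuples(index=False):
        try:
            evidence = frozenset(
                t for t in str(getattr(row, "evidence", "") or "").split(",") if t
            )
            direct = str(getattr(row, "direct_flag", "1")).strip().lower() in ("1", "true", "yes")
            edges.append(PpiEdge(row.protein_a, row.protein_b, evidence, direct))
        except (AttributeError, TypeError):
            bad += 1
    if bad:
        logger.warning("skipped %d malformed edge rows in %s", bad, path)
    return edges


def write_edge_list(net, path) -> None:
    rows = [
        {
            "pdz": pdz, "ligand": lig, "score": d.get("score", float("nan")),
            "motif": d.get("motif", ""), "evidence": ",".join(sorted(d.get("evidence", ()))),
        }
        for pdz, lig, d in net.edges()
    ]
    pd.DataFrame(rows).sort_values(["pdz", "ligand"]).to_csv(path, sep="\t", index=False)


def read_paralog_pairs(path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return {tuple(sorted((r.protein_a, r.protein_b))) for r in df.itertuples(index=False)}


def write_paralog_pairs(pairs: set[tuple[str, str]], path) -> None:
    pd.DataFrame(
        sorted(pairs), columns=["protein_a", "protein_b"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- evolution

def read_species_ladder(path) -> list[Species]:
    """Species ladder TSV: species, divergence_myr, group."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        Species(str(r.species), float(r.divergence_myr), str(getattr(r, "group", "vertebrate")))
        for r in df.itertuples(index=False)
    ]


def write_species_ladder(species: list[Species], path) -> None:
    pd.DataFrame(
        [{"species": s.name, "divergence_myr": s.divergence_myr, "group": s.group}
         for s in species]
    ).to_csv(path, sep="\t", index=False)


def read_ortholog_traces(path) -> dict[str, OrthologTrace]:
    """Ortholog-trace TSV: protein_id, species, present, tetrapeptide."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    traces: dict[str, OrthologTrace] = {}
    for row in df.itertuples(index=False):
        trace = traces.setdefault(row.protein_id, OrthologTrace(row.protein_id, {}))
        present = str(row.present).strip().lower() in ("1", "true", "yes")
        trace.ctermini[row.species] = row.tetrapeptide if present else ABSENT
    return traces


def write_ortholog_traces(traces: dict[str, OrthologTrace], path) -> None:
    rows = []
    for pid in sorted(traces):
        for sp, tet in traces[pid].ctermini.items():
            present = tet != ABSENT
            rows.append(
                {"protein_id": pid, "species": sp,
                 "present": int(present), "tetrapeptide": tet if present else ABSENT}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- annotation

def read_annotations(path, background: set[str]) -> AnnotationMap:
    """Annotation TSV: class, protein_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    classes: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        classes.setdefault(getattr(row, "_0", None) or row[0], set()).add(row.protein_id)
    return AnnotationMap(classes, background)


def write_annotations(classes: dict[str, set[str]], path) -> None:
    rows = [
        {"class": label, "protein_id": pid}
        for label in sorted(classes)
        for pid in sorted(classes[label])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Validated run configuration loaded from a YAML key-value file.

    ``inputs`` maps input names to existing paths; ``k`` is a non-negative
    offset or the string 'calibrate'; the config echoes itself into the
    output directory for provenance.
    """

    inputs: dict[str, Path] = field(default_factory=dict)
    k: float | str = 0.0
    n_neighbors: int = 40
    threshold: float = 0.0
    seed: int = 0
    outdir: Path = Path("out")

    def __post_init__(self) -> None:
        for name, path in self.inputs.items():
            path = Path(path)
            if not path.exists():
                raise IoError(f"input {name!r}: path {path} does not exist")
            self.inputs[name] = path
        if self.n_neighbors < 1:
            raise IoError("n_neighbors must be >= 1")
        if not (self.k == "calibrate" or (isinstance(self.k, (int, float)) and self.k >= 0)):
            raise IoError("k must be >= 0 or 'calibrate'")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        stray = set(data) - known
        if stray:
            raise IoError(f"unknown config key(s): {sorted(stray)}")
        return cls(**data)

    def echo(self) -> Path:
        """Write the resolved parameters into the output directory."""
        self.outdir.mkdir(parents=True, exist_ok=True)
        out = self.outdir / "run_config.yaml"
        out.write_text(
            yaml.safe_dump(
                {
                    "inputs": {k: str(v) for k, v in self.inputs.items()},
                    "k": self.k,
                    "n_neighbors": self.n_neighbors,
                    "threshold": self.threshold,
                    "seed": self.seed,
                    "outdir": str(self.outdir),
                },
                sort_keys=True,
            )
        )
        return out


# -------------------------------------------------------------------- world

def write_world(world, outdir) -> None:
    """Write every synthetic-world input and truth table under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta({d.domain_id: d.sequence for d in world.domains}, outdir / "domains.fasta")
    world.pocket_definition.to_tsv(outdir / "pocket_definition.tsv")
    write_interactions(world.interactions, outdir / "interactions.tsv")
    write_fasta(world.proteome, outdir / "proteome.fasta")
    write_edge_list(world.network, outdir / "network_edges.tsv")
    write_paralog_pairs(world.paralog_pairs, outdir / "paralog_pairs.tsv")
    write_species_ladder(world.species, outdir / "species_ladder.tsv")
    write_ortholog_traces(world.traces, outdir / "ortholog_traces.tsv")
    write_annotations(world.annotation_classes, outdir / "annotations.tsv")
    for name, df in world.truth.items():
        df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
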