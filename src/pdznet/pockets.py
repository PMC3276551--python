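"""PDZ domain curation, alignment and binding-pocket residue extraction.

A PDZ domain recognizes the four C-terminal residues of its ligand through
four pockets (contacting ligand positions 0, -1, -2, -3). Pocket residues
are located as columns of a multiple alignment of the domain sequences,
anchored on the secondary structure of a reference domain (the first PDZ
domain of PSD-95); the column sets are supplied as a :class:`PocketDefinition`
and are fully configurable because they depend on the alignment used.

Alignment backends are pluggable: a precomputed alignment (aligned FASTA or
Stockholm) can be supplied, equal-length sequence sets are accepted as a
trivial alignment, or a profile HMM can be given for `pyhmmer` hmmalign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import AMINO_ACIDS, LIGAND_POSITIONS

GAP_CHARS = frozenset("-.")


class PocketError(ValueError):
    """Invalid pocket definition or alignment input."""


@dataclass(frozen=True)
class PdzDomainRecord:
    """One PDZ domain: ``domain_id`` is ``protein_id + '_' + ordinal``."""

    domain_id: str
    protein_id: str
    species: str
    sequence: str

    @property
    def ordinal(self) -> int:
        try:
            return int(self.domain_id.rsplit("_", 1)[1])
        except (IndexError, ValueError):
            return 1


@dataclass(frozen=True)
class PocketDefinition:
    """Alignment-column indices (0-based) feeding each of the four pockets."""

    columns: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        if set(self.columns) != set(LIGAND_POSITIONS):
            raise PocketError(f"pocket definition must cover pockets {LIGAND_POSITIONS}")
        for pocket, cols in self.columns.items():
            if not cols:
                raise PocketError(f"pocket {pocket} has no columns")
            if any(c < 0 for c in cols):
                raise PocketError(f"pocket {pocket} has a negative column index")

    @property
    def max_column(self) -> int:
        return max(c for cols in self.columns.values() for c in cols)

    @classmethod
    def from_tsv(cls, path) -> "PocketDefinition":
        """Read a (pocket, column, order) TSV; rows sorted by order per pocket."""
        df = pd.read_csv(path, sep="\t", comment="#")
        cols: dict[int, tuple[int, ...]] = {}
        for pocket, grp in df.groupby("pocket"):
            ordered = grp.sort_values("order")["column"].astype(int)
            cols[int(pocket)] = tuple(ordered)
        return cls(cols)

    def to_tsv(self, path) -> None:
        rows = [
            {"pocket": pocket, "column": col, "order": order}
            for pocket, cols in sorted(self.columns.items())
            for order, col in enumerate(cols)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AlignedDomain:
    """A domain row of the alignment plus its extracted pocket strings."""

    domain_id: str
    aligned_sequence: str
    pockets: dict[int, str] = field(default_factory=dict)

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.aligned_sequence if c not in GAP_CHARS)


def _hmmalign(records, hmm_path):
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    with pyhmmer.plan7.HMMFile(hmm_path) as fh:
        hmm = fh.read()
    seqs = [
        pyhmmer.easel.TextSequence(name=r.domain_id.encode(), sequence=r.sequence)
        for r in records
    ]
    msa = pyhmmer.hmmalign(hmm, [s.digitize(alphabet) for s in seqs], trim=True)
    return {
        name.decode(): aligned
        for name, aligned in zip(msa.names, msa.alignment)
    }


def align_domains(
    records: list[PdzDomainRecord],
    alignment: dict[str, str] | None = None,
    hmm_path=None,
) -> tuple[list[AlignedDomain], list[tuple[str, str]]]:
    """Place each domain in a shared column space.

    Exactly one backend applies: an explicit ``alignment`` mapping
    domain_id -> aligned row (from an aligned FASTA/Stockholm file), an
    ``hmm_path`` for pyhmmer hmmalign, or — when the input sequences all
    have equal length — the trivial identity alignment.

    Returns the aligned rows plus a list of ``(domain_id, reason)`` for
    records that failed to align (missing from the supplied alignment, or
    rows whose ungapped form does not round-trip to the input sequence).
    """
    if not records:
        return [], []
    if alignment is None and hmm_path is not None:
        alignment = _hmmalign(records, hmm_path)
    if alignment is None:
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise PocketError(
                "sequences of unequal length: supply a precomputed alignment or an HMM"
            )
        alignment = {r.domain_id: r.sequence for r in records}

    widths = {len(row) for row in alignment.values()}
    if len(widths) > 1:
        raise PocketError("alignment rows have unequal widths")

    aligned, failed = [], []
    for rec in records:
        row = alignment.get(rec.domain_id)
        if row is None:
            failed.append((rec.domain_id, "absent from alignment"))
            continue
        ungapped = "".join(c for c in row if c not in GAP_CHARS)
        if ungapped.upper() != rec.sequence.upper():
            failed.append((rec.domain_id, "aligned row does not match input sequence"))
            continue
        aligned.append(AlignedDomain(rec.domain_id, row))
    return aligned, failed


def extract_pockets(aligned: AlignedDomain, definition: PocketDefinition) -> dict[int, str]:
    """Slice the four pocket residue strings out of an aligned row.

    Gap characters at pocket columns are preserved so curation can filter
    on them downstream.
    """
    width = len(aligned.aligned_sequence)
    if definition.max_column >= width:
        raise PocketError(
            f"pocket column {definition.max_column} out of range for alignment width {width}"
        )
    return {
        pocket: "".join(aligned.aligned_sequence[c] for c in cols)
        for pocket, cols in definition.columns.items()
    }


def attach_pockets(
    aligned: list[AlignedDomain], definition: PocketDefinition
) -> list[AlignedDomain]:
    """Return aligned rows with their pocket strings filled in."""
    return [
        AlignedDomain(a.domain_id, a.aligned_sequence, extract_pockets(a, definition))
        for a in aligned
    ]


@dataclass
class CurationReport:
    """Counts per removal class applied while curating a domain set."""

    n_input: int = 0
    n_duplicates: int = 0
    n_pocket_gapped: int = 0
    n_kept: int = 0


def curate_domains(
    records: list[PdzDomainRecord],
    aligned: list[AlignedDomain] | None = None,
    definition: PocketDefinition | None = None,
) -> tuple[list[PdzDomainRecord], CurationReport]:
    """Collapse exact duplicate sequences and drop pocket-gapped domains.

    Redundancy means exact sequence identity; among duplicates the
    lexicographically smallest domain_id survives, which makes the curation
    independent of input order. When ``aligned`` rows and a pocket
    ``definition`` are supplied, any domain with a gap in any pocket column
    is removed and reported as a pocket-alignment failure.
    """
    report = CurationReport(n_input=len(records))
    by_seq: dict[str, PdzDomainRecord] = {}
    for rec in sorted(records, key=lambda r: r.domain_id):
        key = rec.sequence.upper()
        if key in by_seq:
            report.n_duplicates += 1
        else:
            by_seq[key] = rec
    survivors = sorted(by_seq.values(), key=lambda r: r.domain_id)

    if aligned is not None and definition is not None:
        pocket_rows = {a.domain_id: a for a in aligned}
        kept = []
        for rec in survivors:
            row = pocket_rows.get(rec.domain_id)
            if row is None:
                report.n_pocket_gapped += 1
                continue
            pockets = extract_pockets(row, definition)
            if any(c in GAP_CHARS for s in pockets.values() for c in s):
                report.n_pocket_gapped += 1
                continue
            kept.append(rec)
        survivors = kept

    report.n_kept = len(survivors)
    return survivors, report


def pocket_vectors(
    aligned_with_pockets: list[AlignedDomain], table
) -> dict[int, dict[str, "object"]]:
    """Encode every domain's pockets: pocket_id -> domain_id -> feature vector.

    Domains with a gap in a pocket are skipped for that pocket.
    """
    from .features import encode_pocket

    out: dict[int, dict[str, object]] = {p: {} for p in LIGAND_POSITIONS}
    for a in aligned_with_pockets:
        for pocket, residues in a.pockets.items():
            if any(c in GAP_CHARS for c in residues):
                continue
            if any(c not in AMINO_ACIDS for c in residues.upper()):
                continue
            out[pocket][a.domain_id] = encode_pocket(residues.upper(), table, pocket)
    return out
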