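"""Physicochemical encoding of binding-pocket residues.

Each of the 20 standard amino acids is described by 10 physicochemical
indices (hydrogen-bond donor count, polarity, volume, bulkiness,
hydrophobicity, isoelectric point, positive charge, negative charge,
electron-ion interaction potential, free energy in water). Columns are
z-scored over the 20-letter alphabet so every property contributes on a
comparable scale, and a pocket residue string is encoded as the
concatenation of its residues' normalized property rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: canonical ligand positions, C-terminus = 0
LIGAND_POSITIONS = (-3, -2, -1, 0)

N_PROPERTIES = 10

_DEFAULT_TABLE_RESOURCE = "aaindex_default.tsv"


class FeatureError(ValueError):
    """Invalid residue alphabet or malformed property table."""


@dataclass(frozen=True)
class AminoAcidIndexTable:
    """Normalized 20 x 10 amino-acid property table.

    ``values`` rows are indexed by one-letter code; after normalization each
    property column has population mean 0 and standard deviation 1 over the
    20 standard amino acids.
    """

    property_names: tuple[str, ...]
    values: pd.DataFrame = field(repr=False)

    def row(self, aa: str) -> np.ndarray:
        """Return the normalized 10-value property row for one amino acid."""
        if aa not in self.values.index:
            raise FeatureError(f"non-standard amino acid {aa!r}")
        return self.values.loc[aa].to_numpy(dtype=float)


@dataclass(frozen=True)
class PocketFeatureVector:
    """Numeric encoding of one pocket's residues.

    ``pocket_id`` is the ligand position the pocket contacts (0, -1, -2 or
    -3); ``values`` has length ``10 * n_residues``.
    """

    pocket_id: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.pocket_id not in LIGAND_POSITIONS:
            raise FeatureError(f"pocket_id must be one of {LIGAND_POSITIONS}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size % N_PROPERTIES:
            raise FeatureError("feature vector length must be a multiple of 10")
        if not np.all(np.isfinite(v)):
            raise FeatureError("feature vector contains non-finite entries")
        object.__setattr__(self, "values", v)


def normalize_index_table(raw: pd.DataFrame) -> AminoAcidIndexTable:
    """Z-score each property column of a raw 20 x 10 table.

    Uses the population (n) standard deviation: the alphabet is the full,
    fixed population of 20 amino acids, not a sample. Idempotent on an
    already-normalized table.

    Raises
    ------
    FeatureError
        If the table is not 20 x 10 over the standard alphabet, has missing
        values, or a property column is constant (zero variance).
    """
    if set(raw.index) != set(AMINO_ACIDS):
        raise FeatureError("table must be keyed by exactly the 20 standard amino acids")
    if raw.shape != (20, N_PROPERTIES):
        raise FeatureError(f"expected a 20x{N_PROPERTIES} table, got {raw.shape}")
    if raw.isna().any().any():
        raise FeatureError("table contains missing values")
    values = raw.loc[list(AMINO_ACIDS)].astype(float)
    sd = values.std(axis=0, ddof=0)
    constant = sd[sd == 0.0]
    if len(constant):
        raise FeatureError(f"constant property column(s): {', '.join(constant.index)}")
    normalized = (values - values.mean(axis=0)) / sd
    return AminoAcidIndexTable(tuple(normalized.columns), normalized)


def load_index_table(path=None) -> AminoAcidIndexTable:
    """Load and normalize a property table from TSV (default: packaged table).

    The TSV has a header of property names and 20 rows keyed by one-letter
    amino-acid code; '#' lines are comments.
    """
    if path is None:
        ref = resources.files("pdznet.data").joinpath(_DEFAULT_TABLE_RESOURCE)
        with resources.as_file(ref) as p:
            raw = pd.read_csv(p, sep="\t", comment="#", index_col=0)
    else:
        raw = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return normalize_index_table(raw)


def encode_pocket(
    residues: str, table: AminoAcidIndexTable, pocket_id: int = 0
) -> PocketFeatureVector:
    """Encode a pocket residue string as concatenated property rows.

    The output length is ``10 * len(residues)``; row order follows residue
    order. Gap characters are rejected here — gapped pockets are filtered
    upstream during domain curation.
    """
    if not residues:
        raise FeatureError("empty pocket residue string")
    rows = []
    for pos, aa in enumerate(residues):
        if aa not in table.values.index:
            raise FeatureError(f"non-standard residue {aa!r} at position {pos}")
        rows.append(table.row(aa))
    return PocketFeatureVector(pocket_id, np.concatenate(rows))
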