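"""File I/O: aligned FASTA, TSV tables with schema validation, minimal PDB.

TSV is the single tabular dialect (UTF-8, '.' decimal point, '#' comment
lines skipped). PDB reading is deliberately minimal: only serial, atom name,
residue name, chain, residue number and coordinates are consumed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

log = logging.getLogger(__name__)

GAP = "-"


class TableSchemaError(ValueError):
    """A TSV file does not satisfy its declared schema."""


class AlignmentError(ValueError):
    """An alignment file violates the aligned-FASTA contract."""


@dataclass
class Alignment:
    """An ordered set of equal-length gapped sequences with unique ids."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids in alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def get(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        keep = set(keep_ids)
        pairs = [(i, s) for i, s in zip(self.ids, self.sequences) if i in keep]
        return Alignment(ids=[p[0] for p in pairs], sequences=[p[1] for p in pairs])


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; all records must have equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(
        ids=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_table(
    path: str | Path,
    required: Mapping[str, type] | None = None,
) -> pd.DataFrame:
    """Read a TSV file and validate it against a column schema.

    ``required`` maps mandatory column names to ``float``, ``int`` or ``str``.
    Non-numeric cells in numeric columns are reported with their row number.
    Unknown columns are preserved untouched. Missing values stay missing
    (NaN), never silently zero.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty and len(df.columns) == 0:
        raise TableSchemaError(f"{path}: no header line")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableSchemaError(f"{path}: missing mandatory column(s) {missing}")
        for col, typ in required.items():
            if typ in (float, int):
                converted = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[converted.isna() & df[col].notna()]
                if len(bad):
                    raise TableSchemaError(
                        f"{path}: non-numeric value in column {col!r} at data "
                        f"row(s) {[int(b) + 1 for b in bad[:5]]}"
                    )
                df[col] = converted.astype(float if typ is float else "Int64")
    if len(df) == 0:
        warnings.warn(f"{path}: table has a header but no data rows")
    log.info("read %d rows from %s", len(df), path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal PDB coordinate frames

@dataclass
class Frame:
    """One coordinate frame: parallel atom annotation arrays plus float64
    coordinates in Å.

    Double precision is kept internally (PDB text and biotite arrays are
    single precision) so downstream geometry satisfies tight invariance
    tolerances.
    """

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    coord: np.ndarray       # (n, 3) float64, Å

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=np.float64)
        n = len(self.coord)
        for arr in (self.chain_id, self.res_id, self.res_name, self.atom_name):
            if len(arr) != n:
                raise ValueError("frame annotation arrays have unequal lengths")

    def __len__(self) -> int:
        return len(self.coord)

    def copy(self) -> "Frame":
        return Frame(
            chain_id=self.chain_id.copy(),
            res_id=self.res_id.copy(),
            res_name=self.res_name.copy(),
            atom_name=self.atom_name.copy(),
            coord=self.coord.copy(),
        )

    @classmethod
    def from_atom_array(cls, arr: struc.AtomArray) -> "Frame":
        return cls(
            chain_id=np.asarray(arr.chain_id),
            res_id=np.asarray(arr.res_id),
            res_name=np.asarray(arr.res_name),
            atom_name=np.asarray(arr.atom_name),
            coord=np.asarray(arr.coord, dtype=np.float64),
        )

    def to_atom_array(self) -> struc.AtomArray:
        arr = struc.AtomArray(len(self))
        arr.chain_id = self.chain_id
        arr.res_id = self.res_id
        arr.res_name = self.res_name
        arr.atom_name = self.atom_name
        arr.element = np.array([n[0] for n in self.atom_name])
        arr.coord = self.coord.astype(np.float32)
        return arr


def read_frames(path: str | Path) -> list[Frame]:
    """Read a (multi-model) minimal PDB file into coordinate frames.

    Only ATOM/HETATM records are used; occupancy, B-factor and element
    semantics are ignored.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        return [Frame.from_atom_array(stack)]
    return [
        Frame.from_atom_array(stack[i]) for i in range(stack.stack_depth())
    ]


def write_frames(frames: Sequence[Frame], path: str | Path) -> None:
    """Write coordinate frames as a multi-model PDB file."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    stack = struc.stack([f.to_atom_array() for f in frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def build_frame(atoms: Sequence[tuple[str, int, str, str, Sequence[float]]]) -> Frame:
    """Build a frame from (chain, res_id, res_name, atom_name, xyz) tuples."""
    return Frame(
        chain_id=np.array([a[0] for a in atoms]),
        res_id=np.array([a[1] for a in atoms], dtype=int),
        res_name=np.array([a[2] for a in atoms]),
        atom_name=np.array([a[3] for a in atoms]),
        coord=np.array([a[4] for a in atoms], dtype=np.float64),
    )
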