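"""Conformations, decoy ensembles, and their file formats.

The unit of analysis throughout the package is a C-alpha trace: one 3-D
coordinate per residue, in chain order.  Decoys of a single target share
residue numbering, so structural comparison is positional — no alignment
step is needed or performed.

Two on-disk formats are supported:

* PDB (read-only): CA atoms are extracted from ``ATOM`` records, one
  conformation per ``MODEL`` block.
* A plain-text trajectory format (read/write) holding many decoys of one
  target: repeated blocks of a header line ``L energy`` followed by ``L``
  lines of ``x y z`` in Angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Optional, Union

import numpy as np

__all__ = [
    "Conformation",
    "DecoyEnsemble",
    "PDBParseError",
    "TrajectoryFormatError",
    "read_pdb_ca",
    "read_trajectory",
    "write_trajectory",
    "write_pdb_ca",
]


class PDBParseError(ValueError):
    """A PDB file could not be interpreted as CA traces."""


class TrajectoryFormatError(ValueError):
    """A trajectory file violates the block format contract."""


@dataclass(frozen=True)
class Conformation:
    """An ordered CA trace of one structural model.

    Parameters
    ----------
    id
        Label for the model (file stem, ``decoy_0001``, ...).
    coords
        ``(L, 3)`` float array of CA positions in Angstroms.
    residue_numbers
        Length-``L`` strictly increasing integer residue numbers.  Defaults
        to ``1..L`` when not given.
    """

    id: str
    coords: np.ndarray
    residue_numbers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (L, 3), got {coords.shape}")
        if coords.shape[0] < 3:
            raise ValueError(f"a conformation needs L >= 3 residues, got {coords.shape[0]}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        resnum = self.residue_numbers
        if resnum is None:
            resnum = np.arange(1, coords.shape[0] + 1)
        resnum = np.asarray(resnum, dtype=int)
        if resnum.shape != (coords.shape[0],):
            raise ValueError("residue_numbers must parallel coords")
        if np.any(np.diff(resnum) <= 0):
            raise ValueError("residue_numbers must be strictly increasing")
        object.__setattr__(self, "residue_numbers", resnum)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    id: Optional[str] = None) -> "Conformation":
        """Return a copy with ``coords @ rotation.T + translation`` applied."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return Conformation(id or self.id, new, self.residue_numbers)


@dataclass
class DecoyEnsemble:
    """A set of decoys of one target, optionally with the native structure.

    All members (and the native, if present) must have the same length and
    residue numbering: structural distances are computed between
    positionally corresponding residues.
    """

    target_id: str
    members: List[Conformation]
    native: Optional[Conformation] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        ref = self.members[0]
        for m in self.members[1:]:
            if len(m) != len(ref) or not np.array_equal(m.residue_numbers, ref.residue_numbers):
                raise ValueError(
                    f"member {m.id!r} does not share the ensemble's residue numbering"
                )
        if self.native is not None and (
            len(self.native) != len(ref)
            or not np.array_equal(self.native.residue_numbers, ref.residue_numbers)
        ):
            raise ValueError("native does not share the ensemble's residue numbering")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_residues(self) -> int:
        return len(self.members[0])

    def coords_array(self) -> np.ndarray:
        """All member coordinates stacked as an ``(N, L, 3)`` array."""
        return np.stack([m.coords for m in self.members])


# ---------------------------------------------------------------------------
# PDB reading (CA extraction)
# ---------------------------------------------------------------------------

def _parse_pdb_models(lines: Iterator[str]) -> List[List[tuple]]:
    """Split PDB text into per-model lists of (resnum_key, xyz) CA entries."""
    models: List[List[tuple]] = []
    current: List[tuple] = []
    seen_altloc: set = set()
    in_model = False
    any_model_record = False
    for lineno, raw in enumerate(lines, start=1):
        rec = raw[:6]
        if rec == "MODEL ":
            any_model_record = True
            in_model = True
            current = []
            seen_altloc = set()
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec == "ATOM  " or rec == "HETATM":
            name = raw[12:16].strip()
            if name != "CA" or rec == "HETATM":
                continue
            chain = raw[21]
            resseq = raw[22:26].strip()
            icode = raw[26]
            key = (chain, resseq, icode)
            if key in seen_altloc:
                continue  # keep the first-listed altLoc only
            seen_altloc.add(key)
            try:
                xyz = (float(raw[30:38]), float(raw[38:46]), float(raw[46:54]))
            except ValueError as exc:
                raise PDBParseError(
                    f"non-numeric coordinate field at line {lineno}: {raw.rstrip()!r}"
                ) from exc
            current.append((key, xyz))
    if current or not models:
        # trailing atoms without ENDMDL, or a file with no MODEL records
        if current or not any_model_record:
            models.append(current)
    return models


def read_pdb_ca(path: Union[str, Path], model_policy: str = "first") -> List[Conformation]:
    """Read CA traces from a PDB file.

    Parameters
    ----------
    path
        PDB-format text file.
    model_policy
        ``"first"`` returns only the first model; ``"all"`` returns one
        :class:`Conformation` per ``MODEL`` block.

    Returns
    -------
    list of Conformation
        Residue numbers are taken from the PDB residue sequence numbers;
        insertion-coded residues are kept in file order and renumbered
        sequentially if the raw numbering is not strictly increasing.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    path = Path(path)
    with open(path) as fh:
        models = _parse_pdb_models(fh)
    confs: List[Conformation] = []
    stem = path.stem
    for i, entries in enumerate(models, start=1):
        if not entries:
            raise PDBParseError(f"{path.name}: model {i} contains no CA ATOM records")
        coords = np.array([xyz for _, xyz in entries])
        raw_nums = []
        for (chain, resseq, icode), _ in entries:
            try:
                raw_nums.append(int(resseq))
            except ValueError:
                raw_nums.append(len(raw_nums) + 1)
        nums = np.asarray(raw_nums)
        if np.any(np.diff(nums) <= 0):  # insertion codes / chain breaks
            nums = np.arange(1, len(nums) + 1)
        label = stem if len(models) == 1 else f"{stem}_model{i}"
        confs.append(Conformation(label, coords, nums))
        if model_policy == "first":
            break
    return confs


def write_pdb_ca(conf: Conformation, path: Union[str, Path]) -> None:
    """Write a CA trace as a minimal single-chain PDB file."""
    with open(path, "w") as fh:
        for i, (num, (x, y, z)) in enumerate(zip(conf.residue_numbers, conf.coords), start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  ALA A{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectory format
# ---------------------------------------------------------------------------

def read_trajectory(path: Union[str, Path], target_id: Optional[str] = None) -> DecoyEnsemble:
    """Read a plain-text decoy trajectory into an ensemble.

    The format is repeated blocks of a header line ``L energy`` (energy may
    be zero and is ignored) followed by ``L`` whitespace-separated
    ``x y z`` lines.  Members are labelled ``decoy_0001`` onwards.
    """
    path = Path(path)
    members: List[Conformation] = []
    expected_L: Optional[int] = None
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln and not ln.startswith("#")]
    pos = 0
    block = 0
    while pos < len(lines):
        block += 1
        header = lines[pos].split()
        try:
            L = int(header[0])
        except (ValueError, IndexError):
            raise TrajectoryFormatError(
                f"{path.name}: block {block} header is not 'L energy': {lines[pos]!r}"
            )
        if expected_L is None:
            expected_L = L
        elif L != expected_L:
            raise TrajectoryFormatError(
                f"{path.name}: block {block} declares L={L}, expected {expected_L}"
            )
        body = lines[pos + 1 : pos + 1 + L]
        if len(body) < L or any(len(b.split()) != 3 for b in body):
            raise TrajectoryFormatError(
                f"{path.name}: block {block} is truncated (expected {L} coordinate lines)"
            )
        try:
            coords = np.array([[float(v) for v in b.split()] for b in body])
        except ValueError:
            raise TrajectoryFormatError(
                f"{path.name}: block {block} has a non-numeric coordinate"
            )
        members.append(Conformation(f"decoy_{block:04d}", coords))
        pos += 1 + L
    if not members:
        raise TrajectoryFormatError(f"{path.name}: no decoy blocks found")
    return DecoyEnsemble(target_id or path.stem, members)


def write_trajectory(ensemble: DecoyEnsemble, path: Union[str, Path]) -> None:
    """Write an ensemble in the trajectory format (coordinates to 3 dp)."""
    with open(path, "w") as fh:
        for m in ensemble.members:
            fh.write(f"{len(m)} 0.0\n")
            for x, y, z in m.coords:
                fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")
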