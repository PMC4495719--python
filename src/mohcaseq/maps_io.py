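"""Data model and serialization for proximity-mapping experiments.

The central objects are 2D fragment-count matrices ``F_ij`` indexed by the
reverse-transcription stop position *i* (rows) and the cleavage/ligation
position *j* (columns), both 1-based along the RNA.  A sequenced cDNA
fragment spans *i+1* .. *j-1*, so only the strictly upper triangle
(*i* < *j*) carries data; that convention is enforced at every boundary.

Two text dialects are supported: a plain tab-separated matrix with ``#``
comment headers, and a self-describing block format (``rdat-2d``) with one
``ROW`` line per stop position, loosely modelled on the RDAT containers used
by chemical-mapping pipelines.  3D model coordinates are read from standard
PDB ``ATOM`` records; the ribose O2'/C4' atoms may be spelled with either
the prime or the star dialect (``O2'`` / ``O2*``) and are normalized on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .errors import DimensionError, FormatError, ValidationError

logger = logging.getLogger(__name__)

_VALID_STAGES = ("raw_cohcoa", "filtered", "smoothed", "scaled")


def upper_mask(length: int) -> np.ndarray:
    """Boolean mask of the strictly upper triangle (i < j), 0-based."""
    return np.triu(np.ones((length, length), dtype=bool), k=1)


@dataclass
class RnaSequence:
    """An RNA sequence with residue numbering and a region of interest.

    ``offset`` is the sequence number of the first residue.  The region of
    interest excludes flanking reference hairpins and primer-binding sites;
    it is an inclusive 1-based *position* interval (1 = first residue).
    """

    name: str
    residues: str
    offset: int = 1
    region_of_interest: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError("sequence must contain at least one residue")
        bad = set(self.residues.upper()) - set("ACGUN")
        if bad:
            raise ValidationError(f"non-RNA characters in sequence: {sorted(bad)}")
        self.residues = self.residues.upper()
        if self.region_of_interest is None:
            self.region_of_interest = (1, len(self.residues))
        lo, hi = self.region_of_interest
        if not (1 <= lo <= hi <= len(self.residues)):
            raise ValidationError(
                f"region_of_interest {self.region_of_interest} outside sequence "
                f"positions 1..{len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        """Residue sequence numbers (offset-based), one per position."""
        return np.arange(self.offset, self.offset + len(self))

    def roi_slice(self) -> slice:
        lo, hi = self.region_of_interest
        return slice(lo - 1, hi)


def _check_matrix(values: np.ndarray, length: int, *, allow_negative: bool) -> None:
    if values.shape != (length, length):
        raise DimensionError(
            f"matrix shape {values.shape} does not match sequence length {length}"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError("matrix contains non-finite values")
    lower = np.tril(np.ones_like(values, dtype=bool))
    if np.any(values[lower] != 0):
        i, j = np.argwhere((values != 0) & lower)[0]
        raise DimensionError(
            f"entry at (i={i + 1}, j={j + 1}) violates the strict i < j convention"
        )
    if not allow_negative and np.any(values < 0):
        raise ValidationError("matrix contains negative values")


def poisson_errors(counts: np.ndarray) -> np.ndarray:
    """Default Poisson error model for raw counts: sqrt(max(F, 1)) on i < j."""
    err = np.sqrt(np.maximum(counts, 1.0))
    err[~upper_mask(counts.shape[0])] = 0.0
    return err


@dataclass
class CountMatrix:
    """Raw paired-end fragment counts ``F_ij`` with Poisson errors.

    Stored as dense L x L arrays; only the strict upper triangle is defined
    and the lower triangle (including the diagonal) is identically zero.
    """

    F: np.ndarray
    seq: RnaSequence
    F_err: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        _check_matrix(self.F, len(self.seq), allow_negative=False)
        if self.F_err is None:
            self.F_err = poisson_errors(self.F)
        else:
            self.F_err = np.asarray(self.F_err, dtype=float)
            _check_matrix(self.F_err, len(self.seq), allow_negative=False)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def mask(self) -> np.ndarray:
        return upper_mask(self.length)


@dataclass
class Profile1D:
    """Per-residue 1D profile (background or rate), with errors.

    ``values`` may contain NaN for positions where the quantity is undefined
    (e.g. a zero attenuation denominator); such entries are reported missing.
    """

    values: np.ndarray
    role: str
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.errors is None:
            self.errors = np.zeros_like(self.values)
        else:
            self.errors = np.asarray(self.errors, dtype=float)
        if self.errors.shape != self.values.shape:
            raise DimensionError("profile errors must match values in length")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < -1e-12):
            raise ValidationError(f"negative values in {self.role} profile")


@dataclass
class ProximityMap:
    """Two-point correlation map ``Q_ij`` at a named processing stage.

    Stages advance strictly raw_cohcoa -> filtered -> smoothed -> scaled.
    """

    Q: np.ndarray
    seq: RnaSequence
    Q_err: np.ndarray | None = None
    stage: str = "raw_cohcoa"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in _VALID_STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        self.Q = np.asarray(self.Q, dtype=float)
        allow_negative = self.stage != "raw_cohcoa"
        _check_matrix(self.Q, len(self.seq), allow_negative=allow_negative)
        if self.Q_err is None:
            self.Q_err = np.zeros_like(self.Q)
        else:
            self.Q_err = np.asarray(self.Q_err, dtype=float)
            _check_matrix(self.Q_err, len(self.seq), allow_negative=False)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def mask(self) -> np.ndarray:
        return upper_mask(self.length)

    def snr(self) -> np.ndarray:
        """Signal-to-noise ratio Q/Q_err on defined cells (0 where err = 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.Q_err > 0, self.Q / self.Q_err, 0.0)
        out[~self.mask] = 0.0
        return out


@dataclass
class ModelCoordinates:
    """A single 3D model: atoms keyed by (residue index, atom name)."""

    model_id: str
    atoms: list[tuple[int, str, float, float, float]]
    score: float | None = None

    def __post_init__(self) -> None:
        index: dict[tuple[int, str], np.ndarray] = {}
        for res, name, x, y, z in self.atoms:
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValidationError(f"non-finite coordinate for {name} {res}")
            key = (res, name)
            if key in index:
                logger.warning(
                    "model %s: duplicate atom %s for residue %d; keeping first",
                    self.model_id, name, res,
                )
                continue
            index[key] = np.array([x, y, z], dtype=float)
        self._index = index

    def coord(self, residue: int, atom: str) -> np.ndarray | None:
        return self._index.get((residue, atom))

    def atom_keys(self) -> list[tuple[int, str]]:
        return list(self._index)

    def coords_for(self, keys: Iterable[tuple[int, str]]) -> np.ndarray:
        return np.array([self._index[k] for k in keys])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _format_row(values: np.ndarray) -> str:
    return "\t".join(f"{v:.10g}" for v in values)


def _header_items(seq: RnaSequence, stage: str | None, meta: dict) -> list[tuple[str, str]]:
    items = [
        ("NAME", seq.name),
        ("SEQUENCE", seq.residues),
        ("OFFSET", str(seq.offset)),
        ("ROI", f"{seq.region_of_interest[0]} {seq.region_of_interest[1]}"),
    ]
    if stage is not None:
        items.append(("STAGE", stage))
    for key, value in sorted(meta.items()):
        items.append(("ANNOTATION", f"{key}:{value}"))
    return items


def _parse_header(items: dict[str, str], annotations: dict[str, str]):
    if "SEQUENCE" not in items:
        raise FormatError("header does not declare SEQUENCE")
    if "OFFSET" not in items:
        raise FormatError("header does not declare OFFSET")
    try:
        offset = int(items["OFFSET"])
    except ValueError as exc:
        raise FormatError(f"OFFSET is not an integer: {items['OFFSET']!r}") from exc
    roi = None
    if "ROI" in items:
        try:
            lo, hi = (int(tok) for tok in items["ROI"].split())
        except ValueError as exc:
            raise FormatError(f"malformed ROI field: {items['ROI']!r}") from exc
        roi = (lo, hi)
    seq = RnaSequence(
        name=items.get("NAME", "unnamed"),
        residues=items["SEQUENCE"],
        offset=offset,
        region_of_interest=roi,
    )
    return seq, items.get("STAGE"), dict(annotations)


def _write_tsv(path: Path, values: np.ndarray, errors: np.ndarray,
               seq: RnaSequence, stage: str | None, meta: dict) -> None:
    cols = seq.positions
    with open(path, "w") as fh:
        for key, value in _header_items(seq, stage, meta):
            fh.write(f"# {key} {value}\n")
        fh.write("\t" + "\t".join(str(c) for c in cols) + "\n")
        for i, row in enumerate(values):
            fh.write(f"{cols[i]}\t{_format_row(row)}\n")
        fh.write("# ERRORS\n")
        for i, row in enumerate(errors):
            fh.write(f"{cols[i]}\t{_format_row(row)}\n")


def _read_tsv(path: Path):
    header: dict[str, str] = {}
    annotations: dict[str, str] = {}
    value_lines: list[str] = []
    error_lines: list[str] = []
    target = value_lines
    col_header: str | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body == "ERRORS":
                target = error_lines
                continue
            if not body:
                continue
            key, _, value = body.partition(" ")
            if key == "ANNOTATION":
                akey, _, avalue = value.partition(":")
                annotations[akey] = avalue
            elif key:
                header[key] = value.strip()
            continue
        if col_header is None and line.startswith("\t"):
            col_header = line
            continue
        target.append(line)
    seq, stage, meta = _parse_header(header, annotations)
    length = len(seq)

    def parse_block(lines: list[str]) -> np.ndarray:
        mat = np.zeros((length, length))
        for line in lines:
            toks = line.split("\t")
            try:
                rownum = int(toks[0])
                vals = [float(t) for t in toks[1:]]
            except ValueError as exc:
                raise FormatError(f"malformed data line: {line!r}") from exc
            if len(vals) != length:
                raise DimensionError(
                    f"row {rownum} has {len(vals)} values, expected {length}"
                )
            mat[rownum - seq.offset] = vals
        return mat

    values = parse_block(value_lines)
    errors = parse_block(error_lines) if error_lines else None
    return values, errors, seq, stage, meta


def _write_rdat2d(path: Path, values: np.ndarray, errors: np.ndarray,
                  seq: RnaSequence, stage: str | None, meta: dict) -> None:
    cols = seq.positions
    with open(path, "w") as fh:
        for key, value in _header_items(seq, stage, meta):
            fh.write(f"{key}\t{value}\n")
        fh.write("ROW_TYPE\trt_stop_position\n")
        for i, row in enumerate(values):
            fh.write(f"ROW\t{cols[i]}\t{_format_row(row)}\n")
        for i, row in enumerate(errors):
            fh.write(f"ERROR\t{cols[i]}\t{_format_row(row)}\n")


def _read_rdat2d(path: Path):
    header: dict[str, str] = {}
    annotations: dict[str, str] = {}
    rows: list[tuple[int, list[float]]] = []
    errs: list[tuple[int, list[float]]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        toks = line.split("\t")
        tag = toks[0]
        if tag in ("ROW", "ERROR"):
            try:
                rownum = int(toks[1])
                vals = [float(t) for t in toks[2:]]
            except (IndexError, ValueError) as exc:
                raise FormatError(f"malformed {tag} line: {line!r}") from exc
            (rows if tag == "ROW" else errs).append((rownum, vals))
        elif tag == "ANNOTATION":
            akey, _, avalue = toks[1].partition(":")
            annotations[akey] = avalue
        elif tag == "ROW_TYPE":
            continue
        else:
            header[tag] = toks[1] if len(toks) > 1 else ""
    seq, stage, meta = _parse_header(header, annotations)
    length = len(seq)

    def fill(pairs: list[tuple[int, list[float]]]) -> np.ndarray:
        mat = np.zeros((length, length))
        for rownum, vals in pairs:
            if len(vals) != length:
                raise DimensionError(
                    f"row {rownum} has {len(vals)} values, expected {length}"
                )
            mat[rownum - seq.offset] = vals
        return mat

    values = fill(rows)
    errors = fill(errs) if errs else None
    return values, errors, seq, stage, meta


_READERS = {"tsv": _read_tsv, "rdat-2d": _read_rdat2d}
_WRITERS = {"tsv": _write_tsv, "rdat-2d": _write_rdat2d}


def _dialect(name: str):
    if name not in _READERS:
        raise FormatError(f"unknown dialect {name!r}; expected one of {sorted(_READERS)}")
    return name


def read_count_matrix(path, dialect: str = "tsv") -> CountMatrix:
    """Read a fragment-count matrix; absent errors are imputed as sqrt(max(F,1)).

    Lower-triangle entries in the file are rejected (the matrix is defined
    only for i < j) and negative counts raise a validation error.
    """
    values, errors, seq, _stage, meta = _READERS[_dialect(dialect)](Path(path))
    return CountMatrix(F=values, F_err=errors, seq=seq, meta=meta)


def write_count_matrix(matrix: CountMatrix, path, dialect: str = "tsv") -> None:
    _WRITERS[_dialect(dialect)](Path(path), matrix.F, matrix.F_err,
                                matrix.seq, None, matrix.meta)


def read_proximity_map(path, dialect: str = "tsv") -> ProximityMap:
    values, errors, seq, stage, meta = _READERS[_dialect(dialect)](Path(path))
    if stage is None:
        raise FormatError("proximity-map file does not declare a STAGE")
    return ProximityMap(Q=values, Q_err=errors, seq=seq, stage=stage, meta=meta)


def write_proximity_map(pmap: ProximityMap, path, dialect: str = "tsv") -> None:
    """Write a proximity map; values round-trip to 6 significant digits."""
    if not np.all(np.isfinite(pmap.Q)):
        raise ValidationError("proximity map contains non-finite values")
    _WRITERS[_dialect(dialect)](Path(path), pmap.Q, pmap.Q_err,
                                pmap.seq, pmap.stage, pmap.meta)


def read_model_pdb(path) -> ModelCoordinates:
    """Read one model's ATOM records from a PDB file.

    Atom names are normalized to the prime dialect (``O2*`` becomes ``O2'``);
    residue indices are taken from the PDB residue sequence numbers.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    atoms: list[tuple[int, str, float, float, float]] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.id[0].strip():
                    continue  # skip HETATM / waters
                resnum = residue.id[1]
                for atom in residue:
                    name = atom.get_name().replace("*", "'")
                    x, y, z = atom.coord
                    atoms.append((resnum, name, float(x), float(y), float(z)))
        break  # first MODEL only
    if not atoms:
        raise FormatError(f"no ATOM records found in {path}")
    return ModelCoordinates(model_id=path.stem, atoms=atoms)
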