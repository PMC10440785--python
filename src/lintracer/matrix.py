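"""Barcode matrices: N cells x L recording units over a small state alphabet.

Each cell carries a recording array of L units.  A unit starts in the ground
state and may be irreversibly edited into one of the states of the edit
alphabet S; a matrix row is the readout of one cell.  States are opaque
single-character symbols — '1'/'0'/'2' (ground/deletion/inversion) in the
three-state integrase-recorder encoding, '0'/'1' in the two-state
substitution-recorder encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MatrixFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Alphabet:
    """Ordered state alphabet: ground state first, then the edit states S."""

    ground: str
    edits: tuple[str, ...]

    def __post_init__(self):
        symbols = (self.ground,) + self.edits
        if len(set(symbols)) != len(symbols):
            raise ValueError("alphabet symbols must be distinct")
        if any(len(s) != 1 for s in symbols):
            raise ValueError("alphabet symbols must be single characters")

    @property
    def symbols(self) -> tuple[str, ...]:
        return (self.ground,) + self.edits

    @property
    def n_states(self) -> int:
        return 1 + len(self.edits)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    @classmethod
    def mouse_style(cls) -> "Alphabet":
        """Three-state integrase recorder: ground '1', deletion '0', inversion '2'."""
        return cls(ground="1", edits=("0", "2"))

    @classmethod
    def fly_style(cls) -> "Alphabet":
        """Two-state substitution recorder: ground '0', mutated '1'."""
        return cls(ground="0", edits=("1",))

    @classmethod
    def with_n_edits(cls, n_edits: int) -> "Alphabet":
        """Generic recorder with ground '0' and edit states '1'..'n'."""
        if not 1 <= n_edits <= 9:
            raise ValueError("1-9 edit states supported by the digit encoding")
        return cls(ground="0", edits=tuple(str(i) for i in range(1, n_edits + 1)))


class BarcodeMatrix:
    """Cell barcodes as an integer-coded matrix.

    ``codes[i, l]`` is the alphabet index (0 = ground) of unit ``l`` in cell
    ``i``; ``cell_ids`` gives the row labels.
    """

    def __init__(self, cell_ids: list[str], codes: np.ndarray, alphabet: Alphabet):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2:
            raise MatrixFormatError("codes must be 2-D")
        if codes.shape[0] != len(cell_ids):
            raise MatrixFormatError("one row per cell id required")
        if codes.shape[1] < 1 or codes.shape[0] < 1:
            raise MatrixFormatError("need at least one cell and one unit")
        if len(set(cell_ids)) != len(cell_ids):
            raise MatrixFormatError("duplicate cell ids")
        if codes.min() < 0 or codes.max() >= alphabet.n_states:
            raise MatrixFormatError("state code outside alphabet")
        self.cell_ids = list(cell_ids)
        self.codes = codes
        self.alphabet = alphabet
        self._row_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_cells(self) -> int:
        return self.codes.shape[0]

    @property
    def n_units(self) -> int:
        return self.codes.shape[1]

    def row(self, cell_id: str) -> np.ndarray:
        return self.codes[self._row_index[cell_id]]

    def row_string(self, cell_id: str) -> str:
        return "".join(self.alphabet.symbols[c] for c in self.row(cell_id))

    def reordered(self, cell_ids: list[str]) -> "BarcodeMatrix":
        idx = [self._row_index[c] for c in cell_ids]
        return BarcodeMatrix(list(cell_ids), self.codes[idx], self.alphabet)

    @classmethod
    def from_strings(
        cls, cell_ids: list[str], rows: list[str], alphabet: Alphabet
    ) -> "BarcodeMatrix":
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise MatrixFormatError("ragged rows: all barcodes must share length")
        lookup = {s: i for i, s in enumerate(alphabet.symbols)}
        codes = np.empty((len(rows), lengths.pop()), dtype=np.int8)
        for i, (cid, row) in enumerate(zip(cell_ids, rows)):
            for l, ch in enumerate(row):
                if ch not in lookup:
                    raise MatrixFormatError(
                        f"state {ch!r} outside alphabet {alphabet.symbols} "
                        f"(cell {cid!r}, column {l + 1})"
                    )
                codes[i, l] = lookup[ch]
        return cls(list(cell_ids), codes, alphabet)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BarcodeMatrix)
            and self.cell_ids == other.cell_ids
            and self.alphabet == other.alphabet
            and np.array_equal(self.codes, other.codes)
        )


def read_barcode_matrix(path, alphabet: Alphabet | None = None) -> BarcodeMatrix:
    """Read a plain-text barcode matrix.

    Two dialects are auto-detected: one state character per column
    (tab- or comma-separated, first column the cell id, optional header
    starting with ``cell_id``), or a single compact state string per cell.
    The alphabet is inferred from the file (symbols in sorted order, ground
    state guessed as '1' when present together with '0' and '2', else '0')
    unless supplied.
    """
    cell_ids: list[str] = []
    rows: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            sep = "\t" if "\t" in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if parts[0] == "cell_id":
                continue
            if len(parts) == 1:
                raise MatrixFormatError(f"row {parts[0]!r} has no states")
            cell_ids.append(parts[0])
            states = parts[1:]
            if len(states) == 1 and len(states[0]) > 1:
                rows.append(states[0])
            else:
                bad = [s for s in states if len(s) != 1]
                if bad:
                    raise MatrixFormatError(
                        f"multi-character state {bad[0]!r} in per-column dialect "
                        f"(cell {parts[0]!r})"
                    )
                rows.append("".join(states))
    if not rows:
        raise MatrixFormatError(f"no data rows in {path}")
    if alphabet is None:
        observed = sorted(set("".join(rows)))
        if set(observed) <= {"0", "1", "2"} and "1" in observed and len(observed) > 2:
            ground = "1"
        else:
            ground = observed[0]
        alphabet = Alphabet(ground=ground, edits=tuple(s for s in observed if s != ground))
    return BarcodeMatrix.from_strings(cell_ids, rows, alphabet)


def write_barcode_matrix(matrix: BarcodeMatrix, path) -> None:
    """Write TSV, one state character per column, header ``cell_id u1..uL``."""
    with open(path, "w") as fh:
        header = ["cell_id"] + [f"u{l + 1}" for l in range(matrix.n_units)]
        fh.write("\t".join(header) + "\n")
        for cid in matrix.cell_ids:
            fh.write(cid + "\t" + "\t".join(matrix.row_string(cid)) + "\n")
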