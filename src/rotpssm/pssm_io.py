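"""Reading, validating and writing PSSM profiles and protein-pair lists.

A Position-Specific Scoring Matrix (PSSM) summarises the evolutionary
conservation of a protein: row *i* holds the log-odds score of residue *i*
mutating into each of the 20 standard amino acids, as produced by iterative
profile search (PSI-BLAST against a large reference database). This module
speaks the PSI-BLAST ``-out_ascii_pssm`` dialect: header lines, one row per
residue (position index, residue letter, 20 integer log-odds columns, then
20 weighted-percentage columns that are ignored on input and written as
zeros on output), and trailing K/lambda statistics lines that are skipped.

Only the 20 log-odds columns are consumed downstream; the percentage
columns and gapless-match statistics carry no information used by the
descriptor pipeline.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "STANDARD_ALPHABET",
    "ProteinRecord",
    "PSSM",
    "PairDataset",
    "PSSMParseError",
    "read_pssm",
    "write_pssm",
    "read_pair_list",
    "write_pair_list",
    "run_psiblast",
]

#: Column order emitted by PSI-BLAST ASCII PSSMs.
STANDARD_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

_AA_SET = frozenset(STANDARD_ALPHABET)
#: Non-standard residue codes tolerated in input sequences.
_EXTRA_RESIDUES = frozenset("XBZUJO*-")


class PSSMParseError(ValueError):
    """Raised when a PSSM or pair-list file violates the expected dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """A raw protein: identifier plus amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence of {self.id!r} is empty")
        bad = set(self.sequence.upper()) - _AA_SET - _EXTRA_RESIDUES
        if bad:
            raise ValueError(
                f"sequence of {self.id!r} contains invalid residues {sorted(bad)}"
            )


@dataclass
class PSSM:
    """An N x 20 integer log-odds profile for one protein.

    Attributes
    ----------
    protein_id : str
        Identifier of the profiled protein.
    scores : numpy.ndarray
        Integer matrix of shape (n_residues, 20).
    column_alphabet : str
        The 20-letter amino-acid order of the score columns; a permutation
        of the standard alphabet.
    residues : str
        The residue letter of each row (the profiled sequence).
    """

    protein_id: str
    scores: np.ndarray
    column_alphabet: str = STANDARD_ALPHABET
    residues: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM {self.protein_id!r}: scores must be N x 20, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM {self.protein_id!r}: needs at least one row")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(self.scores == np.round(self.scores)):
                raise ValueError(
                    f"PSSM {self.protein_id!r}: scores must be integers"
                )
            self.scores = self.scores.astype(np.int64)
        if sorted(self.column_alphabet) != sorted(STANDARD_ALPHABET):
            raise ValueError(
                f"PSSM {self.protein_id!r}: column alphabet "
                f"{self.column_alphabet!r} is not a permutation of the 20 "
                "standard amino acids"
            )
        if not self.residues:
            self.residues = "X" * self.scores.shape[0]
        if len(self.residues) != self.scores.shape[0]:
            raise ValueError(
                f"PSSM {self.protein_id!r}: residue string length "
                f"{len(self.residues)} != row count {self.scores.shape[0]}"
            )

    @property
    def n_residues(self) -> int:
        return int(self.scores.shape[0])


@dataclass
class PairDataset:
    """Labelled protein pairs plus the PSSM lookup that resolves them.

    ``pairs`` preserves input file order; labels are binary with
    1 = interacting, 0 = non-interacting.
    """

    pairs: list[tuple[str, str, int]]
    pssm_lookup: dict[str, PSSM] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for a, b, label in self.pairs:
            if label not in (0, 1):
                raise ValueError(f"label {label!r} for pair ({a}, {b}) not in {{0,1}}")
            key = (a, b, label)
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)
        missing = sorted(
            {i for a, b, _ in self.pairs for i in (a, b)} - set(self.pssm_lookup)
        )
        if missing:
            raise ValueError(f"pairs reference proteins with no PSSM: {missing}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=int)

    def protein_ids(self) -> list[str]:
        """Unique protein ids referenced by the pairs, in first-seen order."""
        out: list[str] = []
        seen: set[str] = set()
        for a, b, _ in self.pairs:
            for i in (a, b):
                if i not in seen:
                    seen.add(i)
                    out.append(i)
        return out

    def subset(self, indices) -> "PairDataset":
        """Dataset restricted to ``pairs[indices]``; the lookup keeps only
        proteins those pairs reference (no leakage of unused profiles)."""
        pairs = [self.pairs[i] for i in indices]
        ids = {i for a, b, _ in pairs for i in (a, b)}
        lookup = {i: self.pssm_lookup[i] for i in ids}
        return PairDataset(pairs, lookup)


_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


def _is_alphabet_line(tokens: list[str]) -> bool:
    return (
        len(tokens) in (20, 40)
        and all(len(t) == 1 and t.isalpha() for t in tokens)
        and sorted(tokens[:20]) == sorted(STANDARD_ALPHABET)
    )


def read_pssm(path: str | Path, protein_id: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM file.

    Only the first 20 (log-odds) score columns of each residue row are
    consumed; the percentage columns and the trailing statistics lines are
    ignored. The protein id defaults to the file stem.

    Raises
    ------
    PSSMParseError
        On a malformed residue row (wrong column count or non-integer
        score), a missing alphabet header, or an empty matrix. The message
        names the offending line number.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    lines = path.read_text().splitlines()

    alphabet: str | None = None
    start = None
    for lineno, line in enumerate(lines):
        tokens = line.split()
        if _is_alphabet_line(tokens):
            alphabet = "".join(tokens[:20])
            start = lineno + 1
            break
    if alphabet is None:
        raise PSSMParseError(f"{path}: no amino-acid column header found")

    rows: list[list[int]] = []
    residues: list[str] = []
    for lineno in range(start, len(lines)):
        line = lines[lineno]
        tokens = line.split()
        if not tokens:
            if rows:
                break  # blank line terminates the matrix block
            continue
        if not tokens[0].isdigit():
            break  # trailing statistics (K, lambda) section
        human = lineno + 1
        if len(tokens) not in (42, 44):
            raise PSSMParseError(
                f"{path}, line {human}: expected 42 or 44 columns in residue "
                f"row, got {len(tokens)}"
            )
        if not (len(tokens[1]) == 1 and tokens[1].isalpha()):
            raise PSSMParseError(
                f"{path}, line {human}: second column {tokens[1]!r} is not a "
                "residue letter"
            )
        try:
            rows.append([int(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise PSSMParseError(
                f"{path}, line {human}: non-integer score cell ({exc})"
            ) from None
        residues.append(tokens[1].upper())

    if not rows:
        raise PSSMParseError(f"{path}: no residue rows found (empty matrix)")

    return PSSM(
        protein_id=protein_id,
        scores=np.array(rows, dtype=np.int64),
        column_alphabet=alphabet,
        residues="".join(residues),
    )


def write_pssm(pssm: PSSM, path: str | Path) -> None:
    """Write a PSSM in the same ASCII dialect :func:`read_pssm` accepts.

    The weighted-percentage columns carry no information here and are
    written as zeros; ``read_pssm(write_pssm(p))`` reproduces ``p.scores``
    and ``p.column_alphabet`` exactly.
    """
    path = Path(path)
    cols = "  ".join(f"{c:>2}" for c in pssm.column_alphabet)
    out = ["", _HEADER, f"            {cols}   {cols}"]
    for i, row in enumerate(pssm.scores):
        scores = " ".join(f"{int(v):>3}" for v in row)
        pct = " ".join(f"{0:>3}" for _ in row)
        out.append(f"{i + 1:>5} {pssm.residues[i]}  {scores}   {pct}  0.00 0.00")
    out += ["", "                      K         Lambda", ""]
    path.write_text("\n".join(out) + "\n")


def read_pair_list(path: str | Path, pssm_dir: str | Path) -> PairDataset:
    """Load a 3-column pair list and the PSSM files it references.

    Each non-empty, non-comment line is ``id_A id_B label`` (whitespace- or
    tab-delimited, label in {0,1}); protein ``X`` is read from
    ``pssm_dir/X.pssm``. File order is preserved.
    """
    path = Path(path)
    pssm_dir = Path(pssm_dir)
    pairs: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise PSSMParseError(
                f"{path}, line {lineno}: expected 'id_A id_B label', "
                f"got {len(tokens)} fields"
            )
        a, b, raw = tokens
        if raw not in ("0", "1"):
            raise PSSMParseError(
                f"{path}, line {lineno}: label {raw!r} not in {{0,1}}"
            )
        pairs.append((a, b, int(raw)))

    ids = {i for a, b, _ in pairs for i in (a, b)}
    missing = sorted(i for i in ids if not (pssm_dir / f"{i}.pssm").exists())
    if missing:
        raise FileNotFoundError(
            f"no PSSM file in {pssm_dir} for protein(s): {missing}"
        )
    lookup = {i: read_pssm(pssm_dir / f"{i}.pssm", protein_id=i) for i in sorted(ids)}
    return PairDataset(pairs, lookup)


def write_pair_list(pairs: list[tuple[str, str, int]], path: str | Path) -> None:
    """Write pairs as tab-delimited ``id_A<TAB>id_B<TAB>label`` lines."""
    Path(path).write_text(
        "".join(f"{a}\t{b}\t{lab}\n" for a, b, lab in pairs)
    )


def run_psiblast(
    records: list[ProteinRecord],
    db: str | Path,
    evalue: float = 0.001,
    iterations: int = 3,
    executable: str = "psiblast",
) -> dict[str, PSSM]:
    """Produce one PSSM per protein by shelling out to PSI-BLAST.

    Runs ``psiblast -db DB -evalue 0.001 -num_iterations 3
    -out_ascii_pssm ...`` per record — a pure subprocess wrapper, no
    alignment logic — and parses each output with :func:`read_pssm`.

    Raises
    ------
    EnvironmentError
        If the executable is not on PATH.
    RuntimeError
        If PSI-BLAST exits non-zero; the message surfaces its stderr.
    """
    if not records:
        return {}
    if shutil.which(executable) is None:
        raise EnvironmentError(
            f"PSI-BLAST executable {executable!r} not found on PATH; install "
            "the NCBI BLAST+ suite and format the reference database with "
            "makeblastdb"
        )
    out: dict[str, PSSM] = {}
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        for rec in records:
            fasta = tmpdir / f"{rec.id}.fasta"
            fasta.write_text(f">{rec.id}\n{rec.sequence}\n")
            pssm_path = tmpdir / f"{rec.id}.pssm"
            cmd = [
                executable,
                "-query", str(fasta),
                "-db", str(db),
                "-evalue", str(evalue),
                "-num_iterations", str(iterations),
                "-out_ascii_pssm", str(pssm_path),
                "-out", str(tmpdir / f"{rec.id}.out"),
            ]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(
                    f"PSI-BLAST failed for {rec.id!r} "
                    f"(exit {proc.returncode}): {proc.stderr.strip()}"
                )
            out[rec.id] = read_pssm(pssm_path, protein_id=rec.id)
    return out
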