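"""Readers and writers for the formats the tool touches.

Sequences travel as FASTA, scoring profiles as plain-text PSSM tables
(either the package's own dialect or PSI-BLAST ASCII output), alignment
survivors and profile matrices as TSV, and dendrograms as Newick.

All coordinates written to or read from files are 0-based, half-open
[start, end); every header comment written by this module repeats that
convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: The 20 canonical amino acids in the PSI-BLAST column order.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
#: Residues accepted in input sequences (canonical set plus the unknown X).
ALLOWED = set(ALPHABET) | {"X"}

#: Score used for the unknown residue X against a PSSM column that carries
#: no X information (a BLAST-like conservative default).
X_SCORE = -1


class SeqFormatError(ValueError):
    """Raised for malformed FASTA/PSSM/TSV inputs."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20-letter alphabet plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SeqFormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - ALLOWED
        if bad:
            raise SeqFormatError(
                f"sequence {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ScoringProfile:
    """A target profile: per-position 20-way score columns plus a consensus.

    ``scores`` has one row per consensus position, columns ordered as
    :data:`ALPHABET`.  The consensus residue string and the score table
    must have the same length.
    """

    id: str
    consensus: str
    scores: np.ndarray  # (n, 20) int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise SeqFormatError(
                f"profile {self.id!r}: score table must be n x 20, got "
                f"{self.scores.shape}"
            )
        if len(self.consensus) != self.scores.shape[0]:
            raise SeqFormatError(
                f"profile {self.id!r}: consensus length {len(self.consensus)} "
                f"!= {self.scores.shape[0]} score rows"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]

    def score(self, pos: int, residue: str) -> int:
        """Score of ``residue`` against column ``pos``; X falls back to -1."""
        if not 0 <= pos < len(self):
            raise IndexError(f"position {pos} outside profile of length {len(self)}")
        j = AA_INDEX.get(residue)
        if j is None:
            return X_SCORE
        return int(self.scores[pos, j])

    def score_matrix(self, residues: str) -> np.ndarray:
        """(n, m) table of column-vs-residue scores for a whole sequence."""
        idx = np.array([AA_INDEX.get(r, -1) for r in residues])
        out = np.where(
            idx >= 0, self.scores[:, np.clip(idx, 0, 19)], X_SCORE
        )
        return out.astype(np.int64)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file; residues are uppercased and validated."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqFormatError(f"{path}: no FASTA records found")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for i, rec in enumerate(records):
        if rec.id in seen:
            raise SeqFormatError(f"{path}: duplicate id {rec.id!r} (record {i})")
        seen.add(rec.id)
        try:
            out.append(ProteinSequence(rec.id, str(rec.seq).upper()))
        except SeqFormatError as e:
            raise SeqFormatError(f"{path}: record {i}: {e}") from e
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSSM

def read_pssm(path: str | Path, profile_id: str | None = None) -> ScoringProfile:
    """Read a plain-text PSSM.

    Two dialects are accepted and auto-detected:

    * the package's own dialect — a header row of the 20 residue letters,
      then one row per position: ``index  consensus_residue  20 integers``
      (0-based indices, ``#`` comments allowed);
    * PSI-BLAST ASCII output — banner line, header of 40 letters (two
      20-column blocks), rows of ``index residue`` followed by 40 numbers;
      the first 20 (the log-odds block) are used.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_cols: list[str] | None = None
    rows: list[tuple[str, list[int]]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if header_cols is None:
            letters = [t for t in toks if len(t) == 1 and t.isalpha()]
            if len(letters) in (20, 40) and len(letters) == len(toks):
                header_cols = letters[:20]
                if set(header_cols) != set(ALPHABET):
                    raise SeqFormatError(
                        f"{path}:{lineno}: header letters are not the 20 amino acids"
                    )
                continue
            # not a header line yet (PSI-BLAST banner text)
            continue
        # data row: index, consensus residue, scores
        if len(toks) < 22:
            raise SeqFormatError(
                f"{path}:{lineno}: row has {len(toks) - 2} score fields, expected 20"
            )
        res = toks[1].upper()
        if res not in ALLOWED:
            raise SeqFormatError(f"{path}:{lineno}: bad consensus residue {res!r}")
        try:
            scores = [int(t) for t in toks[2:22]]
        except ValueError as e:
            raise SeqFormatError(f"{path}:{lineno}: non-integer score ({e})") from e
        rows.append((res, scores))
    if header_cols is None or not rows:
        raise SeqFormatError(f"{path}: no PSSM header/rows found")
    # reorder score columns into canonical ALPHABET order
    order = [header_cols.index(a) for a in ALPHABET]
    consensus = "".join(r for r, _ in rows)
    table = np.array([[s[j] for j in order] for _, s in rows], dtype=np.int64)
    return ScoringProfile(profile_id or path.stem, consensus, table)


def write_pssm(profile: ScoringProfile, path: str | Path) -> None:
    """Write a profile in the package's plain dialect (0-based indices)."""
    with open(path, "w") as fh:
        fh.write(f"# PSSM {profile.id}; rows indexed 0-based\n")
        fh.write(" ".join(ALPHABET) + "\n")
        for i, res in enumerate(profile.consensus):
            row = " ".join(str(int(v)) for v in profile.scores[i])
            fh.write(f"{i} {res} {row}\n")


def write_psiblast_pssm(profile: ScoringProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII layout (two 20-column blocks)."""
    with open(path, "w") as fh:
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("   " + "  ".join(ALPHABET) + "   " + "  ".join(ALPHABET) + "\n")
        for i, res in enumerate(profile.consensus):
            block = " ".join(f"{int(v):3d}" for v in profile.scores[i])
            freq = " ".join("0" for _ in range(20))
            fh.write(f"{i + 1:5d} {res} {block}  {freq}  0.00 0.00\n")


# ---------------------------------------------------------------------------
# Profile matrix TSV

def write_profile_matrix(
    matrix: np.ndarray | pd.DataFrame,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write an N x M matrix as TSV: first row column ids, first column row ids.

    Values round-trip bit-exactly for integers and to 12 significant digits
    for reals.
    """
    arr = np.asarray(matrix, dtype=float)
    if len(row_ids) == 0 or len(col_ids) == 0:
        raise SeqFormatError("row and column id lists must be non-empty")
    if arr.shape != (len(row_ids), len(col_ids)):
        raise SeqFormatError(
            f"matrix shape {arr.shape} does not match ids "
            f"({len(row_ids)} x {len(col_ids)})"
        )
    df = pd.DataFrame(arr, index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", index_label="id", float_format="%.12g")


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# Alignment TSV and labels

ALIGNMENT_COLUMNS = [
    "query_id", "profile_id", "terminal", "q",
    "target_start", "target_end", "query_start", "query_end",
    "raw_score", "adjusted_score", "coverage_pct", "identity_pct",
    "aln_target", "aln_mid", "aln_query",
]


def write_alignments_tsv(rows: Iterable[dict], path: str | Path) -> None:
    """Write final-alignment records; spans are 0-based half-open."""
    df = pd.DataFrame(list(rows), columns=ALIGNMENT_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# coordinates 0-based, half-open [start, end)\n")
        df.to_csv(fh, sep="\t", index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sequence id -> fold-group label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "group"], comment="#")
    return dict(zip(df["id"].astype(str), df["group"].astype(str)))


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in labels.items():
            fh.write(f"{k}\t{v}\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode as Newick."""
    buf = io.StringIO()
    tree.write(buf)
    Path(path).write_text(buf.getvalue())
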