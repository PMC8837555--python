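"""Readers and writers for the external formats the pipeline touches.

Every coordinate inside the package is 0-based half-open on the forward
strand, which is BED/BEDPE's native convention, so conversion happens
nowhere.  The domain types defined here (:class:`GenomicInterval`,
:class:`Loop`, :class:`ContactMatrix`, :class:`PositionWeightMatrix`) are
the currency of every downstream module.

Supported formats: FASTA (via Bio.SeqIO), BED3/BED5+, BEDPE (with optional
trailing per-sample count columns), a minimal MEME motif text format, and a
plain-text COO contact-matrix format whose ``#``-prefixed header declares
``chrom  bin_size  n_bins``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
BASES = "ACGT"


class ParseError(ValueError):
    """A file violated its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomicInterval:
    """Half-open genomic interval, optionally carrying a ChIP signal value."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    signal: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.signal is not None and self.signal < 0:
            raise ValueError("signal must be non-negative")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass
class Loop:
    """Cis chromatin loop: ordered anchor pair with optional replicate counts.

    The 5' anchor is by convention the lower-coordinate anchor; the
    constructor swaps the anchors when they arrive reversed.  Trans
    (inter-chromosomal) pairs are rejected.
    """

    anchor5: GenomicInterval
    anchor3: GenomicInterval
    counts: tuple[int, ...] | None = None
    fdr: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.anchor5.chrom != self.anchor3.chrom:
            raise ValueError(
                "trans loop: anchors on "
                f"{self.anchor5.chrom} and {self.anchor3.chrom}"
            )
        if self.anchor5.start > self.anchor3.start:
            self.anchor5, self.anchor3 = self.anchor3, self.anchor5
        if self.counts is not None:
            self.counts = tuple(int(c) for c in self.counts)
            if any(c < 0 for c in self.counts):
                raise ValueError("counts must be non-negative")
        if self.fdr is not None and not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must lie in [0, 1]")

    @property
    def chrom(self) -> str:
        return self.anchor5.chrom

    @property
    def distance(self) -> float:
        """Distance in bp between anchor midpoints."""
        return self.anchor3.midpoint - self.anchor5.midpoint


@dataclass
class ContactMatrix:
    """Symmetric binned per-chromosome contact matrix.

    ``counts`` is the raw layer; ``balanced`` and ``biases`` appear after
    :func:`loopgrammar.contact_tools.ice_balance`.  ``masked`` marks bins
    excluded from normalization and downstream means.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    balanced: np.ndarray | None = None
    biases: np.ndarray | None = None
    masked: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def mask(self) -> np.ndarray:
        """Effective bin mask: stored mask, else zero-coverage bins."""
        if self.masked is not None:
            return self.masked
        return self.counts.sum(axis=1) == 0


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities (A, C, G, T order) plus background."""

    name: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (K, 4)")
        if self.probs.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(self.probs <= 0) or np.any(self.background <= 0):
            raise ValueError("probabilities must be positive (apply a pseudocount)")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            name=self.name + "_rc",
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}`` preserving order.

    Sequences are restricted to the {A, C, G, T, N} alphabet; anything else
    is a :class:`ParseError`.
    """
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: line 1 does not start with '>'")
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty record '{record.id}'")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"{path}: record '{record.id}' contains invalid characters "
                f"{sorted(bad)}"
            )
        if record.id in genome:
            raise ParseError(f"{path}: duplicate record '{record.id}'")
        genome[record.id] = seq
    if not genome:
        raise ParseError(f"{path}: no FASTA records found")
    return genome


def write_fasta(path, genome: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path, signal_column: int | None = None) -> list[GenomicInterval]:
    """Read BED into intervals sorted by (chrom, start).

    ``signal_column`` is a 0-based column index holding a non-negative
    enrichment value (e.g. column 4 of a BED5).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs >= 3 columns")
    out: list[GenomicInterval] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        start, end = int(row[1]), int(row[2])
        if end <= start:
            raise ParseError(f"{path}: line {lineno}: end <= start")
        name = str(row[3]) if df.shape[1] > 3 else None
        signal = None
        if signal_column is not None:
            if signal_column >= df.shape[1]:
                raise ParseError(
                    f"{path}: signal_column {signal_column} out of range"
                )
            signal = float(row[signal_column])
        out.append(GenomicInterval(str(row[0]), start, end, name, signal))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(path, intervals: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.signal is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.signal is not None:
                cols.append(format(iv.signal, "g"))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------


def read_bedpe(path) -> list[Loop]:
    """Read BEDPE into :class:`Loop` objects.

    Column 7, when present and non-numeric, is the loop name; any trailing
    all-integer columns are per-sample counts.  Inter-chromosomal records
    are skipped with a logged warning (trans loops are out of scope), and
    anchors arriving in reverse genomic order are normalized.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ParseError(f"{path}: BEDPE needs >= 6 columns")
    loops: list[Loop] = []
    n_trans = 0
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        if str(row[0]) != str(row[3]):
            n_trans += 1
            continue
        a = GenomicInterval(str(row[0]), int(row[1]), int(row[2]))
        b = GenomicInterval(str(row[3]), int(row[4]), int(row[5]))
        name = None
        counts: list[int] = []
        extra = [row[i] for i in range(6, df.shape[1])]
        if extra:
            first = str(extra[0])
            try:
                int(first)
            except ValueError:
                name = None if first == "." else first
                extra = extra[1:]
            for i, v in enumerate(extra):
                try:
                    counts.append(int(v))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer count '{v}'"
                    ) from exc
        loops.append(
            Loop(a, b, counts=tuple(counts) if counts else None, name=name)
        )
    if n_trans:
        logger.warning(
            "%s: skipped %d inter-chromosomal record(s)", path, n_trans
        )
    return loops


def write_bedpe(path, loops: list[Loop]) -> None:
    has_counts = any(lp.counts is not None for lp in loops)
    with open(path, "w") as fh:
        for lp in loops:
            cols = [
                lp.anchor5.chrom,
                str(lp.anchor5.start),
                str(lp.anchor5.end),
                lp.anchor3.chrom,
                str(lp.anchor3.start),
                str(lp.anchor3.end),
            ]
            if lp.name is not None or has_counts:
                cols.append(lp.name if lp.name is not None else ".")
            if lp.counts is not None:
                cols.extend(str(c) for c in lp.counts)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# COO contact matrix
# ---------------------------------------------------------------------------


def read_matrix_coo(path) -> ContactMatrix:
    """Read the text COO contact format.

    Header: ``# chrom<TAB>bin_size<TAB>n_bins``.  Body lines are
    ``bin_i<TAB>bin_j<TAB>count``; each record is mirrored and duplicate
    pairs accumulate.
    """
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ParseError(f"{path}: missing '#' header line")
    fields = header.lstrip("#").split()
    if len(fields) != 3:
        raise ParseError(f"{path}: header must be '# chrom bin_size n_bins'")
    chrom, bin_size, n_bins = fields[0], int(fields[1]), int(fields[2])
    mat = np.zeros((n_bins, n_bins))
    try:
        body = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["i", "j", "count"], dtype={"i": int, "j": int, "count": float},
        )
    except pd.errors.EmptyDataError:
        body = pd.DataFrame(columns=["i", "j", "count"])
    if len(body):
        ii = body["i"].to_numpy()
        jj = body["j"].to_numpy()
        cc = body["count"].to_numpy()
        if ii.min() < 0 or jj.min() < 0 or ii.max() >= n_bins or jj.max() >= n_bins:
            raise ParseError(f"{path}: bin index out of range [0, {n_bins})")
        np.add.at(mat, (ii, jj), cc)
        off = ii != jj
        np.add.at(mat, (jj[off], ii[off]), cc[off])
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=mat)


def write_matrix_coo(path, matrix: ContactMatrix) -> None:
    """Write the upper triangle (incl. diagonal) of the raw layer."""
    iu, ju = np.nonzero(np.triu(matrix.counts))
    vals = matrix.counts[iu, ju]
    with open(path, "w") as fh:
        fh.write(f"#\t{matrix.chrom}\t{matrix.bin_size}\t{matrix.n_bins}\n")
    pd.DataFrame({"i": iu, "j": ju, "count": vals.astype(int)}).to_csv(
        path, sep="\t", header=False, index=False, mode="a"
    )


# ---------------------------------------------------------------------------
# minimal MEME motif text
# ---------------------------------------------------------------------------


def read_meme_motif(
    path, pseudocount: float = 0.001, name: str | None = None
) -> PositionWeightMatrix:
    """Read one motif from a minimal MEME text file.

    The first motif is returned unless ``name`` selects another.  A
    pseudocount is added to every cell and rows renormalized, so the
    resulting PWM has no zero probabilities.  Background defaults to
    uniform 0.25 when the file has no background line.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    background = np.full(4, 0.25)
    motifs: dict[str, list[list[float]]] = {}
    order: list[str] = []
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.lower().startswith("background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[k]: float(toks[k + 1]) for k in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in BASES])
            background = background / background.sum()
        elif ln.startswith("MOTIF"):
            parts = ln.split()
            motif_name = parts[1] if len(parts) > 1 else f"motif_{len(order) + 1}"
            rows: list[list[float]] = []
            i += 1
            while i < len(lines):
                s = lines[i].strip()
                if s.lower().startswith("letter-probability"):
                    i += 1
                    continue
                toks = s.split()
                if len(toks) == 4:
                    try:
                        rows.append([float(t) for t in toks])
                        i += 1
                        continue
                    except ValueError:
                        pass
                break
            if not rows:
                raise ParseError(f"{path}: motif '{motif_name}' has no matrix")
            motifs[motif_name] = rows
            order.append(motif_name)
            continue
        i += 1
    if not order:
        raise ParseError(f"{path}: no MOTIF block found")
    key = name if name is not None else order[0]
    if key not in motifs:
        raise ParseError(f"{path}: motif '{key}' not found (have {order})")
    probs = np.array(motifs[key])
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ParseError(
            f"{path}: motif '{key}' row {bad} sums to {sums[bad]:.4f}, not 1"
        )
    probs = (probs + pseudocount) / (1.0 + 4.0 * pseudocount)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(name=key, probs=probs, background=background)


def write_meme_motif(path, pwms: list[PositionWeightMatrix]) -> None:
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {p:.6f}" for b, p in zip(BASES, bg)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)}\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
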