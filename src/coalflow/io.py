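"""Multi-locus sequence I/O: bpp-dialect sequential PHYLIP, per-locus FASTA,
the two-column Imap species map, and TSV result tables.

Sequence labels resolve to a species either through an Imap (individual ->
species) or through the ``species^individual`` naming convention.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Iterable, Optional, TextIO, Union

import numpy as np

# IUPAC nucleotide codes as 4-bit masks over (A, C, G, T).
_CODE = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 15, "X": 15, "?": 15, "-": 15,
}
_DECODE = {v: k for k, v in _CODE.items() if k not in "UX?-"}
_DECODE[15] = "N"

_ENC_TABLE = np.zeros(256, dtype=np.uint8)
for _ch, _m in _CODE.items():
    _ENC_TABLE[ord(_ch)] = _m
    _ENC_TABLE[ord(_ch.lower())] = _m

BASES = "ACGT"


def encode_seq(s: str) -> np.ndarray:
    """Encode a nucleotide string as an array of IUPAC bitmasks (A=1, C=2,
    G=4, T=8; ambiguity/gap codes set several bits)."""
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    out = _ENC_TABLE[raw]
    if np.any(out == 0):
        bad = int(np.argmax(out == 0))
        raise ValueError(f"unrecognized nucleotide {s[bad]!r} at position {bad}")
    return out


def decode_seq(mask: np.ndarray) -> str:
    return "".join(_DECODE[int(m)] for m in mask)


@dataclass
class LocusAlignment:
    """Nucleotide alignment for one locus.

    ``data`` holds IUPAC bitmasks, shape (n_seqs, n_sites).  ``species`` and
    ``individuals`` run parallel to ``labels``.
    """

    locus_id: str
    labels: list[str]
    species: list[str]
    individuals: list[str]
    data: np.ndarray

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"locus {self.locus_id}: duplicate sequence labels")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError(f"locus {self.locus_id}: data shape mismatch")

    @property
    def n_seqs(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        return decode_seq(self.data[self.labels.index(label)])

    def base_indices(self) -> np.ndarray:
        """Return 0..3 base indices with 255 marking ambiguity or gaps."""
        out = np.full(self.data.shape, 255, dtype=np.uint8)
        for i, m in enumerate((1, 2, 4, 8)):
            out[self.data == m] = i
        return out


# -- species maps ----------------------------------------------------------

def parse_imap(stream: Union[str, TextIO]) -> dict[str, str]:
    """Parse a bpp-style Imap: two whitespace-delimited columns, individual
    label then species."""
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    imap: dict[str, str] = {}
    for lineno, line in enumerate(stream, 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 2:
            raise ValueError(f"Imap line {lineno}: expected 2 columns")
        imap[parts[0]] = parts[1]
    return imap


def write_imap(imap: dict[str, str]) -> str:
    return "".join(f"{ind}\t{sp}\n" for ind, sp in imap.items())


def resolve_species(label: str, imap: Optional[dict[str, str]]) -> tuple[str, str]:
    """Map a sequence label to (species, individual).

    A ``species^individual`` label is split on the caret; otherwise the label
    (or its post-caret individual tag) is looked up in the Imap.
    """
    if "^" in label:
        sp, ind = label.split("^", 1)
        if imap is not None and ind in imap:
            return imap[ind], ind
        if sp:
            return sp, ind
        label = ind
    if imap is not None and label in imap:
        return imap[label], label
    raise ValueError(f"cannot resolve species for sequence label {label!r}")


# -- multi-locus readers/writers -------------------------------------------

def read_multilocus(
    stream: Union[str, TextIO],
    format: str = "phylip-bpp",
    imap: Optional[dict[str, str]] = None,
) -> list[LocusAlignment]:
    """Read a multi-locus file into a list of :class:`LocusAlignment`.

    ``phylip-bpp``: repeated sequential-PHYLIP blocks, each ``n_seq n_site``
    header followed by one line per sequence; blocks separated by blank
    lines.  ``fasta-per-locus``: FASTA records, loci delimited by comment
    lines starting with ``#`` (or a single locus if none).
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    text = stream.read().replace("\r\n", "\n").replace("\r", "\n")
    if format == "phylip-bpp":
        return _read_phylip(text, imap)
    if format == "fasta-per-locus":
        return _read_fasta(text, imap)
    raise ValueError(f"unknown format {format!r}")


def _make_locus(idx: int, labels: list[str], seqs: list[str], imap) -> LocusAlignment:
    lens = {len(s) for s in seqs}
    if len(lens) > 1:
        raise ValueError(f"locus {idx}: ragged alignment (lengths {sorted(lens)})")
    species, individuals = [], []
    for lab in labels:
        sp, ind = resolve_species(lab, imap)
        species.append(sp)
        individuals.append(ind)
    data = np.vstack([encode_seq(s) for s in seqs]) if seqs else np.zeros((0, 0), np.uint8)
    return LocusAlignment(f"L{idx}", labels, species, individuals, data)


def _read_phylip(text: str, imap) -> list[LocusAlignment]:
    lines = [ln.strip() for ln in text.split("\n")]
    loci: list[LocusAlignment] = []
    i = 0
    while i < len(lines):
        if not lines[i]:
            i += 1
            continue
        head = lines[i].split()
        if len(head) != 2:
            raise ValueError(f"locus {len(loci) + 1}: bad PHYLIP header {lines[i]!r}")
        nseq, nsite = int(head[0]), int(head[1])
        i += 1
        labels, seqs = [], []
        while len(labels) < nseq:
            if i >= len(lines):
                raise ValueError(f"locus {len(loci) + 1}: truncated block")
            if not lines[i]:
                i += 1
                continue
            parts = lines[i].split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"locus {len(loci) + 1}: bad sequence line {lines[i]!r}")
            labels.append(parts[0])
            seqs.append(parts[1].replace(" ", ""))
            i += 1
        for s in seqs:
            if len(s) != nsite:
                raise ValueError(f"locus {len(loci) + 1}: ragged alignment")
        loci.append(_make_locus(len(loci) + 1, labels, seqs, imap))
    return loci


def _read_fasta(text: str, imap) -> list[LocusAlignment]:
    loci: list[LocusAlignment] = []
    labels: list[str] = []
    seqs: list[str] = []

    def flush():
        nonlocal labels, seqs
        if labels:
            loci.append(_make_locus(len(loci) + 1, labels, seqs, imap))
        labels, seqs = [], []

    for line in text.split("\n"):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            flush()
        elif line.startswith(">"):
            labels.append(line[1:].split()[0])
            seqs.append("")
        else:
            if not labels:
                raise ValueError("FASTA sequence data before any header")
            seqs[-1] += line.replace(" ", "")
    flush()
    return loci


def write_multilocus(loci: Iterable[LocusAlignment], format: str = "phylip-bpp") -> str:
    out = []
    for aln in loci:
        if format == "phylip-bpp":
            out.append(f"{aln.n_seqs} {aln.n_sites}")
            for lab, row in zip(aln.labels, aln.data):
                out.append(f"{lab}  {decode_seq(row)}")
            out.append("")
        elif format == "fasta-per-locus":
            out.append(f"# locus {aln.locus_id}")
            for lab, row in zip(aln.labels, aln.data):
                out.append(f">{lab}")
                out.append(decode_seq(row))
        else:
            raise ValueError(f"unknown format {format!r}")
    return "\n".join(out) + "\n"
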