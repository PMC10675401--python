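"""Readers and writers for the formats the localization pipeline touches.

Sequences travel as FASTA, evolutionary profiles as PSI-BLAST ASCII
position-specific scoring matrices (PSSMs), images as 8-bit RGB PNG/TIFF/JPEG,
and labels / feature tables as tab-separated text.  The canonical amino-acid
order used everywhere in this package (compositions, dipeptides, PSSM columns)
is the PSI-BLAST header order ``ARNDCQEGHILKMFPSTWYV``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from PIL import Image

#: PSI-BLAST column order; fixed for every descriptor in the package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: The four compartments the classifier distinguishes, in fixed order.
CLASS_ORDER = ("ER", "Golgi", "Cytosol", "Nucleoplasm")

#: Ambiguous residue codes mapped to their nearest canonical residue.
AMBIGUOUS_MAP = {"B": "N", "Z": "Q", "X": "A", "U": "C", "O": "K", "J": "L"}


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the 20-letter alphabet."""


class PssmConsistencyError(ValueError):
    """A PSSM does not match its associated sequence."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional subcellular-location label."""

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AA_ORDER)
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r}"
            )
        if self.label is not None and self.label not in CLASS_ORDER:
            raise ValueError(
                f"record {self.id!r}: label {self.label!r} not in {CLASS_ORDER}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class Pssm:
    """An L x 20 position-specific scoring matrix aligned to a sequence.

    Columns follow :data:`AA_ORDER`.  ``residues`` keeps the per-row residue
    letters from the source file so the matrix can be cross-checked against
    the FASTA record it claims to describe.
    """

    protein_id: str
    scores: np.ndarray
    residues: Optional[str] = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.protein_id!r}: expected L x 20 matrix, "
                f"got shape {scores.shape}"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"PSSM for {self.protein_id!r}: non-finite scores")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.shape[0]

    def check_against(self, record: ProteinRecord) -> None:
        """Raise :class:`PssmConsistencyError` if this PSSM cannot belong to *record*."""
        if len(self) != len(record):
            raise PssmConsistencyError(
                f"PSSM for {self.protein_id!r} has {len(self)} rows but sequence "
                f"{record.id!r} has {len(record)} residues"
            )
        if self.residues is not None and self.residues != record.sequence:
            raise PssmConsistencyError(
                f"PSSM residue column for {self.protein_id!r} disagrees with "
                f"sequence {record.id!r}"
            )


@dataclasses.dataclass(frozen=True)
class IhcImage:
    """An 8-bit RGB immunohistochemistry micrograph tied to one protein."""

    pixels: np.ndarray
    protein_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"image for {self.protein_id!r}: expected H x W x 3, got {px.shape}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError(
                    f"image for {self.protein_id!r}: values outside [0, 255]"
                )
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """A named fixed-dimension descriptor with provenance."""

    protein_id: str
    operator_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError(
                f"{self.operator_name} for {self.protein_id!r}: non-finite values"
            )
        object.__setattr__(self, "values", v)

    @property
    def dimension(self) -> int:
        return self.values.size


def _clean_sequence(seq: str, record_id: str, map_ambiguous: bool = False) -> str:
    seq = "".join(seq.split()).upper()
    if map_ambiguous:
        seq = "".join(AMBIGUOUS_MAP.get(c, c) for c in seq)
    bad = set(seq) - set(AA_ORDER)
    if bad:
        raise SequenceValidationError(
            f"record {record_id!r}: invalid residue(s) {sorted(bad)!r} "
            "(ambiguous codes B/Z/X/U/O are rejected by default; "
            "pass map_ambiguous=True to fold them onto canonical residues)"
        )
    return seq


def read_fasta(path, map_ambiguous: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Sequences are uppercased and checked against the 20-letter alphabet;
    order is preserved.  With ``map_ambiguous`` the codes B/Z/X/U/O/J are
    folded onto their nearest canonical residue instead of raising.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FastaParseError(f"{path}: line 1 does not start with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(rec.id, _clean_sequence(str(rec.seq), rec.id, map_ambiguous))
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_pssm(path, record: Optional[ProteinRecord] = None) -> Pssm:
    """Parse a PSI-BLAST ASCII PSSM (first 20-column score block).

    The file format: a header line listing 20 amino-acid letters, then one
    row per residue of ``position residue s1 ... s20 [...]``.  Columns are
    re-ordered to :data:`AA_ORDER` if the header uses a different order.
    If *record* is given the matrix is cross-checked against it.
    """
    path = Path(path)
    header_order: Optional[list[str]] = None
    residues: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if header_order is None:
                letters = [t for t in tokens if len(t) == 1 and t.isalpha()]
                if len(letters) >= 20 and set(letters[:20]) == set(AA_ORDER):
                    header_order = letters[:20]
                continue
            if not tokens[0].isdigit():
                continue  # trailing K/lambda statistics block
            if len(tokens) < 22:
                raise FastaParseError(
                    f"{path}:{lineno}: expected position, residue and 20 scores"
                )
            residues.append(tokens[1])
            try:
                rows.append([float(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise FastaParseError(f"{path}:{lineno}: non-numeric score") from exc
    if header_order is None:
        raise FastaParseError(f"{path}: no 20-letter header line found")
    scores = np.asarray(rows, dtype=float)
    perm = [header_order.index(aa) for aa in AA_ORDER]
    scores = scores[:, perm]
    protein_id = record.id if record is not None else path.stem
    pssm = Pssm(protein_id, scores, residues="".join(residues).upper())
    if record is not None:
        pssm.check_against(record)
    return pssm


def write_pssm(pssm: Pssm, path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout that :func:`read_pssm` accepts."""
    residues = pssm.residues or "A" * len(pssm)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(AA_ORDER) + "\n")
        for i, (res, row) in enumerate(zip(residues, pssm.scores), start=1):
            cells = " ".join(f"{v:6.1f}" if v % 1 else f"{int(v):4d}" for v in row)
            fh.write(f"{i:5d} {res} {cells}\n")


def read_image(path, protein_id: Optional[str] = None) -> IhcImage:
    """Load an 8-bit RGB image (PNG/TIFF/JPEG)."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode != "RGB":
            im = im.convert("RGB")
        pixels = np.asarray(im, dtype=np.uint8)
    return IhcImage(pixels, protein_id or path.stem)


def write_image(image: IhcImage, path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(str(path))


def read_labels(path) -> dict[str, str]:
    """Read a two-column tab-separated ``protein_id<TAB>label`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein_id", "label"])
    bad = set(df["label"]) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown location label(s): {sorted(bad)}")
    return dict(zip(df["protein_id"].astype(str), df["label"]))


def write_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(sorted(labels.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack per-protein feature vectors of one operator into a DataFrame.

    Columns are named ``operator:index``; the row index is the protein id.
    """
    if not vectors:
        raise ValueError("no feature vectors given")
    op = vectors[0].operator_name
    dim = vectors[0].dimension
    for v in vectors:
        if v.operator_name != op or v.dimension != dim:
            raise ValueError(
                f"mixed operators/dimensions: {op}:{dim} vs "
                f"{v.operator_name}:{v.dimension}"
            )
    data = np.vstack([v.values for v in vectors])
    cols = [f"{op}:{i}" for i in range(dim)]
    return pd.DataFrame(data, index=[v.protein_id for v in vectors], columns=cols)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="protein_id")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")
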