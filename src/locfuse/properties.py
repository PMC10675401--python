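"""The packaged 50-scale amino-acid physicochemical property table.

Fifty classical amino-acid index scales (hydropathy, volume, polarity,
secondary-structure propensities, ...) tabulated over the 20 canonical
residues in the package's fixed alphabet order.  Each scale is available raw
and z-normalized across the 20 residues; the correlation descriptor consumes
the z-normalized form.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd

from .io import AA_ORDER

N_PROPERTIES = 50


@dataclasses.dataclass(frozen=True)
class PropertyTable:
    """50 named property scales over the 20 amino acids.

    ``raw`` and ``znorm`` are 50 x 20 arrays with columns in :data:`~locfuse.io.AA_ORDER`;
    z-normalization is across the 20 residues of each scale.
    """

    names: tuple[str, ...]
    raw: np.ndarray
    znorm: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != N_PROPERTIES or self.raw.shape != (N_PROPERTIES, 20):
            raise ValueError(
                f"property table must be {N_PROPERTIES} x 20, got {self.raw.shape}"
            )

    def profile(self, sequence: str, normalized: bool = True) -> np.ndarray:
        """Per-residue property profiles, shape (L, 50)."""
        idx = np.fromiter((AA_ORDER.index(c) for c in sequence), dtype=np.int64)
        table = self.znorm if normalized else self.raw
        return table[:, idx].T


def _from_frame(df: pd.DataFrame) -> PropertyTable:
    missing = set(AA_ORDER) - set(df.columns)
    if missing:
        raise ValueError(f"property table missing residue column(s) {sorted(missing)}")
    raw = df[list(AA_ORDER)].to_numpy(dtype=float)
    sd = raw.std(axis=1, keepdims=True, ddof=0)
    if np.any(sd == 0):
        raise ValueError("a property scale is constant across the 20 residues")
    znorm = (raw - raw.mean(axis=1, keepdims=True)) / sd
    return PropertyTable(tuple(df.index), raw, znorm)


def load_property_table(path=None) -> PropertyTable:
    """Load the packaged table, or a user table in the same TSV layout."""
    if path is None:
        source = resources.files("locfuse.data").joinpath("aa_properties.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", index_col="property")
    else:
        df = pd.read_csv(path, sep="\t", index_col="property")
    return _from_frame(df)
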