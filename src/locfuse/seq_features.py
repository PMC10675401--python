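"""Sequence-signal quantitation.

Redundancy clustering (greedy, longest-first, shared-word prefilter plus
global-alignment identity), length filtering, and the sequence descriptors:

* ``pseaac_dipeptide`` -- 20 amino-acid composition fractions + 400 dipeptide
  fractions (420 dims);
* ``pc_correlation`` -- lagged Pearson correlations between the per-residue
  profiles of 50 physicochemical property scales: 1225 unordered property
  pairs x 3 lags = 3675 dims;
* ``dp_pssm`` / ``aac_pssm`` / ``pssm_composition`` -- descriptors of the
  L x 20 evolutionary scoring matrix (240 / 20 / 400 dims).

The descriptor registry maps operator names to (callable, dimension) and is
extensible with further PSSM transforms.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional

import numpy as np
from Bio import Align

from .io import AA_ORDER, FeatureVector, ProteinRecord, Pssm
from .properties import PropertyTable, load_property_table

PSEAAC_DIM = 420
PC_DIM = 3675
DP_PSSM_ALPHA = 5
DP_PSSM_DIM = 40 + 40 * DP_PSSM_ALPHA

CLUSTER_WORD_SIZE = 5


class InputTooShortError(ValueError):
    """Sequence shorter than the descriptor requires."""


# ---------------------------------------------------------------------------
# redundancy clustering and length filtering


def _kmers(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def _word_filter_passes(a: str, b: str, cutoff: float, k: int) -> bool:
    """Necessary condition on shared k-mers for identity >= cutoff.

    Each of the at most ``ceil((1-cutoff)*n)`` mismatches on the shorter
    sequence (length n) can destroy at most k of its n-k+1 words, so a pair
    at the cutoff still shares at least ``n-k+1 - k*ceil((1-cutoff)*n)``
    words.  Fewer shared words than that rules the pair out without aligning.
    """
    n = min(len(a), len(b))
    if n < k:
        return True  # too short for word statistics; align directly
    shared = sum((_kmers(a, k) & _kmers(b, k)).values())
    needed = (n - k + 1) - k * int(np.ceil((1.0 - cutoff) * n))
    return shared >= max(needed, 1)


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched identical pairs / shorter length."""
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=-0.5,
        extend_gap_score=-0.1,
    )
    alignment = aligner.align(a, b)[0]
    matches = sum(
        (sa == sb)
        for block_a, block_b in zip(*alignment.aligned)
        for sa, sb in zip(a[block_a[0] : block_a[1]], b[block_b[0] : block_b[1]])
    )
    return matches / min(len(a), len(b))


def greedy_cluster(
    records: list[ProteinRecord],
    identity_cutoff: float = 0.9,
    word_size: int = CLUSTER_WORD_SIZE,
) -> list[ProteinRecord]:
    """Greedy longest-first redundancy removal at an identity cutoff.

    Records are visited by descending length (stable for ties); each joins
    the first existing cluster whose representative it matches at
    ``identity >= identity_cutoff`` (shared-word prefilter, confirmed by
    global alignment; identity = matches / shorter length), otherwise it
    founds a new cluster.  Returns the representatives in input order.
    """
    if not records:
        return []
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError("identity_cutoff must be in (0, 1]")
    order = sorted(range(len(records)), key=lambda i: -len(records[i]))
    representatives: list[int] = []
    for i in order:
        seq = records[i].sequence
        merged = False
        for j in representatives:
            rep = records[j].sequence
            if not _word_filter_passes(seq, rep, identity_cutoff, word_size):
                continue
            if alignment_identity(seq, rep) >= identity_cutoff:
                merged = True
                break
        if not merged:
            representatives.append(i)
    return [records[i] for i in sorted(representatives)]


def length_filter(
    records: list[ProteinRecord], min_len: int = 50, max_len: int = 5000
) -> list[ProteinRecord]:
    """Keep records with ``min_len <= L <= max_len`` (inclusive bounds)."""
    return [r for r in records if min_len <= len(r) <= max_len]


# ---------------------------------------------------------------------------
# sequence descriptors


def _residue_indices(sequence: str) -> np.ndarray:
    return np.fromiter((AA_ORDER.index(c) for c in sequence), dtype=np.int64)


def pseaac_dipeptide(record: ProteinRecord) -> FeatureVector:
    """Amino-acid composition (20) + dipeptide fractions (400), 420 dims.

    Components 1-20 are residue counts / L in alphabet order; components
    21-420 are dipeptide counts / (L-1) over the 400 ordered dipeptides in
    row-major alphabet order (AA, AR, AN, ...).
    """
    L = len(record)
    if L < 2:
        raise InputTooShortError(f"{record.id!r}: need L >= 2 for dipeptides, got {L}")
    idx = _residue_indices(record.sequence)
    comp = np.bincount(idx, minlength=20) / L
    dipep = np.bincount(idx[:-1] * 20 + idx[1:], minlength=400) / (L - 1)
    return FeatureVector(record.id, "pseaac", np.concatenate([comp, dipep]))


def pc_correlation(
    record: ProteinRecord,
    props: Optional[PropertyTable] = None,
    n_lags: int = 3,
) -> FeatureVector:
    """Lagged cross-property Pearson correlations, 1225 pairs x 3 lags = 3675 dims.

    For property pair (p < q) and lag d, the Pearson correlation between
    ``profile_p[1..L-d]`` and ``profile_q[1+d..L]``, where ``profile_p`` is
    the z-normalized per-residue value of scale p along the sequence.  Output
    order: pairs in lexicographic order, lags 1..n_lags within each pair.
    Correlations with a zero-variance segment are defined as 0.
    """
    if props is None:
        props = load_property_table()
    L = len(record)
    if L < n_lags + 2:
        raise InputTooShortError(
            f"{record.id!r}: need L >= {n_lags + 2} for {n_lags} lags, got {L}"
        )
    profiles = props.profile(record.sequence)  # (L, 50)
    n_props = profiles.shape[1]
    iu, ju = np.triu_indices(n_props, k=1)
    out = np.empty((iu.size, n_lags))
    for d in range(1, n_lags + 1):
        a = profiles[: L - d]
        b = profiles[d:]
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        sa = np.sqrt((ac**2).sum(axis=0))
        sb = np.sqrt((bc**2).sum(axis=0))
        # z-normalized scales are O(1); kill centering round-off on constant
        # profile segments so their correlations are exactly 0
        sa[sa < 1e-8] = 0.0
        sb[sb < 1e-8] = 0.0
        denom = np.outer(sa, sb)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, (ac.T @ bc) / np.where(denom > 0, denom, 1), 0.0)
        out[:, d - 1] = corr[iu, ju]
    return FeatureVector(record.id, "pc", out.ravel())


def dp_pssm(pssm: Pssm, alpha: int = DP_PSSM_ALPHA) -> FeatureVector:
    """Sign-split means and lagged score differences of the PSSM, 40 + 40*alpha dims.

    Per column j: the mean of positive entries and the mean of negative
    entries of E[.,j] (an empty set contributes 0); then for each lag
    k = 1..alpha and column j, the mean of positive and the mean of negative
    differences ``E[i,j] - E[i+k,j]`` over valid positions i.
    """
    E = pssm.scores
    L = E.shape[0]
    if L <= alpha:
        raise InputTooShortError(
            f"PSSM {pssm.protein_id!r}: need L > alpha={alpha}, got L={L}"
        )

    def signed_means(M: np.ndarray) -> np.ndarray:
        pos = M > 0
        neg = M < 0
        npos = pos.sum(axis=0)
        nneg = neg.sum(axis=0)
        mean_pos = np.where(npos > 0, (M * pos).sum(axis=0) / np.maximum(npos, 1), 0.0)
        mean_neg = np.where(nneg > 0, (M * neg).sum(axis=0) / np.maximum(nneg, 1), 0.0)
        return np.concatenate([mean_pos, mean_neg])

    parts = [signed_means(E)]
    for k in range(1, alpha + 1):
        parts.append(signed_means(E[: L - k] - E[k:]))
    return FeatureVector(pssm.protein_id, "dp_pssm", np.concatenate(parts))


def aac_pssm(pssm: Pssm) -> FeatureVector:
    """Column means of the scoring matrix, 20 dims."""
    return FeatureVector(pssm.protein_id, "aac_pssm", pssm.scores.mean(axis=0))


def pssm_composition(
    pssm: Pssm, record: Optional[ProteinRecord] = None
) -> FeatureVector:
    """Residue-conditioned column means, flattened 20 x 20 = 400 dims.

    Entry (a, j) is the mean of E[i, j] over positions i whose sequence
    residue is a (0 when residue a is absent).  The sequence is taken from
    *record* or from the PSSM's own residue column.
    """
    sequence = record.sequence if record is not None else pssm.residues
    if sequence is None:
        raise ValueError(
            f"PSSM {pssm.protein_id!r} carries no residue column; pass the record"
        )
    if record is not None:
        pssm.check_against(record)
    elif len(sequence) != len(pssm):
        raise ValueError(f"PSSM {pssm.protein_id!r}: residue column length mismatch")
    idx = _residue_indices(sequence)
    out = np.zeros((20, 20))
    for a in range(20):
        mask = idx == a
        if mask.any():
            out[a] = pssm.scores[mask].mean(axis=0)
    return FeatureVector(pssm.protein_id, "pssm_composition", out.ravel())


#: name -> (expected dimension, needs) for the shipped sequence-side operators.
DESCRIPTOR_REGISTRY: dict[str, dict] = {
    "pseaac": {"dim": PSEAAC_DIM, "needs": "record", "fn": pseaac_dipeptide},
    "pc": {"dim": PC_DIM, "needs": "record", "fn": pc_correlation},
    "dp_pssm": {"dim": DP_PSSM_DIM, "needs": "pssm", "fn": dp_pssm},
    "aac_pssm": {"dim": 20, "needs": "pssm", "fn": aac_pssm},
    "pssm_composition": {"dim": 400, "needs": "pssm", "fn": pssm_composition},
}


def register_descriptor(name: str, fn, dim: int, needs: str = "pssm") -> None:
    """Hook for additional PSSM-family descriptors (registry is extensible)."""
    if needs not in {"record", "pssm"}:
        raise ValueError("needs must be 'record' or 'pssm'")
    DESCRIPTOR_REGISTRY[name] = {"dim": dim, "needs": needs, "fn": fn}
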