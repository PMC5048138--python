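"""Threonine-centered windows and clustering-based class balancing.

A candidate site is represented as a 31-residue window with the
threonine at its center (signed offsets -15..+15).  Positions that fall
outside the protein are padded with the neutral symbol X (secondary
structure X, accessibility 0) so that near-terminus sites remain usable.

Phosphosite datasets are heavily imbalanced (few confirmed sites among
many candidate threonines), so the benchmark set is balanced by
clustering each class into ``k`` groups on the encoded feature vectors
and keeping one representative per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .errors import ParameterError
from .readwrite import ProteinRecord, SiteTable

#: Default flank width: 15 residues per side, 31-mer windows.
DEFAULT_FLANK = 15


@dataclass
class ResidueWindow:
    """A fixed-length peptide centered on a threonine.

    ``residues`` and ``ss`` are strings of length ``2*flank + 1``;
    ``acc`` is the matching accessibility vector.  The center residue
    (offset 0) is always T; padded positions carry residue X,
    structure X and accessibility 0.
    """

    protein_id: str
    center_pos: int  # 1-based position of the central threonine
    residues: str
    ss: str
    acc: np.ndarray
    label: str = "negative"

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        n = len(self.residues)
        if len(self.ss) != n or len(self.acc) != n:
            raise ParameterError(
                f"window {self.protein_id}:{self.center_pos}: residues/ss/acc "
                f"lengths differ ({n}/{len(self.ss)}/{len(self.acc)})"
            )
        if n % 2 == 0:
            raise ParameterError("window length must be odd (center + equal flanks)")
        if self.residues[n // 2] != "T":
            raise ParameterError(
                f"window {self.protein_id}:{self.center_pos}: center residue "
                f"{self.residues[n // 2]!r} is not threonine"
            )

    @property
    def flank(self) -> int:
        return len(self.residues) // 2

    def residue_at(self, offset: int) -> str:
        return self.residues[self.flank + offset]


@dataclass
class BenchmarkDataset:
    """A balanced benchmark: k positives + k negatives with provenance."""

    positives: list[ResidueWindow]
    negatives: list[ResidueWindow]
    provenance: dict = field(default_factory=dict)


def extract_window(
    protein: ProteinRecord,
    center_pos: int,
    flank: int = DEFAULT_FLANK,
    label: str = "negative",
) -> ResidueWindow:
    """Cut the ``2*flank + 1``-mer centered at ``center_pos`` (1-based).

    The center must be a threonine.  Out-of-sequence positions are
    padded with X/X/0.  Proteins without structure annotation default to
    all-coil, zero accessibility (matching the I/O fallback).
    """
    if not 1 <= center_pos <= len(protein):
        raise ParameterError(
            f"{protein.id}: center {center_pos} outside sequence (length {len(protein)})"
        )
    if protein.sequence[center_pos - 1] != "T":
        raise ParameterError(
            f"{protein.id}:{center_pos}: center residue "
            f"{protein.sequence[center_pos - 1]!r} is not threonine"
        )
    ss = protein.ss if protein.ss is not None else "C" * len(protein)
    acc = protein.acc if protein.acc is not None else np.zeros(len(protein))

    res_chars, ss_chars, acc_vals = [], [], []
    for off in range(-flank, flank + 1):
        i = center_pos - 1 + off
        if 0 <= i < len(protein):
            res_chars.append(protein.sequence[i])
            ss_chars.append(ss[i])
            acc_vals.append(float(acc[i]))
        else:
            res_chars.append("X")
            ss_chars.append("X")
            acc_vals.append(0.0)
    return ResidueWindow(
        protein_id=protein.id,
        center_pos=center_pos,
        residues="".join(res_chars),
        ss="".join(ss_chars),
        acc=np.array(acc_vals),
        label=label,
    )


def build_dataset(
    proteins: Sequence[ProteinRecord],
    site_table: SiteTable,
    flank: int = DEFAULT_FLANK,
) -> tuple[list[ResidueWindow], list[ResidueWindow]]:
    """Build positive and negative windows from proteins + site table.

    One positive window per listed phosphothreonine; one negative window
    per remaining threonine in every protein that carries at least one
    positive.  Returns ``(positives, negatives)``.
    """
    site_table.validate(proteins)
    pos_keys = {(e.protein_id, e.position) for e in site_table.positives()}
    pos_proteins = {pid for pid, _ in pos_keys}

    positives: list[ResidueWindow] = []
    negatives: list[ResidueWindow] = []
    for p in proteins:
        if p.id not in pos_proteins:
            continue
        for i, aa in enumerate(p.sequence, start=1):
            if aa != "T":
                continue
            if (p.id, i) in pos_keys:
                positives.append(extract_window(p, i, flank, label="positive"))
            else:
                negatives.append(extract_window(p, i, flank, label="negative"))
    return positives, negatives


def cluster_undersample(
    windows: Sequence[ResidueWindow],
    k: int,
    seed: int,
    encoder: Callable[[Sequence[ResidueWindow]], np.ndarray],
) -> list[ResidueWindow]:
    """Keep ``k`` representative windows via centroid-based clustering.

    The windows are encoded with ``encoder`` and partitioned into ``k``
    clusters (k-means, fixed seed).  From each cluster the member
    closest to the centroid (Euclidean; ties broken by lowest input
    index) is retained; output order follows cluster index.  With
    ``k == len(windows)`` the input is returned unchanged (each point is
    its own cluster).
    """
    n = len(windows)
    if k < 1:
        raise ParameterError(f"cluster count k={k} must be >= 1")
    if k > n:
        raise ParameterError(f"cannot select k={k} representatives from {n} windows")
    if k == n:
        return list(windows)

    X = np.asarray(encoder(windows), dtype=float)
    if X.shape[0] != n:
        raise ParameterError("encoder returned a matrix with the wrong row count")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)

    reps: list[ResidueWindow] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:  # k-means relocates empty clusters; guard anyway
            raise RuntimeError(f"clustering produced an empty cluster ({c})")
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        reps.append(windows[int(members[int(np.argmin(d))])])
    return reps


def balance(
    positives: Sequence[ResidueWindow],
    negatives: Sequence[ResidueWindow],
    k: int,
    seed: int,
    encoder: Callable[[Sequence[ResidueWindow]], np.ndarray],
) -> BenchmarkDataset:
    """Cluster-undersample both classes symmetrically to ``k`` + ``k``."""
    return BenchmarkDataset(
        positives=cluster_undersample(positives, k, seed, encoder),
        negatives=cluster_undersample(negatives, k, seed, encoder),
        provenance={"k": k, "seed": seed, "method": "kmeans-nearest-centroid"},
    )
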