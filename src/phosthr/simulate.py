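"""Synthetic proteins, annotations and site tables with planted class structure.

The generator emulates the statistical signatures that distinguish
phosphothreonine contexts from other threonine contexts:

* residue composition effects at chosen offsets in positive windows —
  by default a strong proline enrichment immediately downstream of the
  site (+1) and milder leucine/lysine/glycine preferences at a few
  flanking offsets;
* enrichment of loop (coil) secondary structure around positive
  centers, decaying with distance from the site;
* elevated solvent accessibility around positive centers.

Every threonine in the output is a planted site center: flank residues
are drawn from a threonine-free background, so the site table
enumerates the candidate threonines exactly and positive/negative
counts are controlled by construction.  Each protein is a concatenation
of 31-residue site blocks and always contains at least one positive
site.  Output is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .readwrite import (
    AA20,
    ProteinRecord,
    SiteEntry,
    SiteTable,
    write_annotations,
    write_fasta,
    write_site_table,
)

BLOCK = 31  # one site block: 15 + T + 15
CENTER = 15  # 0-based center within a block


def _default_motif_effects() -> list[tuple[int, str, float]]:
    # the dominant +1 proline preference plus milder enrichments at the
    # secondary conserved offsets
    return [
        (1, "P", 0.30),
        (-13, "L", 0.12),
        (-11, "K", 0.12),
        (-4, "G", 0.12),
        (3, "L", 0.12),
        (8, "K", 0.12),
    ]


@dataclass
class GeneratorParams:
    """Knobs of the synthetic generator.

    ``signal`` scales every planted effect: ``strong`` uses the values
    as given, ``weak`` halves them, ``null`` removes them entirely
    (positives and negatives become exchangeable).
    ``effect_halfwidth`` switches the distance profile of the structure
    and accessibility effects from a smooth exponential decay
    (scale ``decay_scale`` residues) to a hard cutoff at ``|offset| <=
    effect_halfwidth`` — useful for planting signal confined to a known
    window.
    """

    n_pos: int = 100
    n_neg: int = 100
    seed: int = 0
    background_freqs: np.ndarray | None = None  # over AA20; default uniform 0.05
    motif_effects: list[tuple[int, str, float]] = field(
        default_factory=_default_motif_effects
    )
    loop_prob_center_pos: float = 0.7
    loop_prob_background: float = 0.4
    acc_shift: float = 30.0  # accessibility elevation at positive centers
    acc_base_mean: float = 30.0  # mean of the background accessibility noise
    decay_scale: float = 5.0  # residues; e-folding of the center effects
    effect_halfwidth: int | None = None
    signal: str = "strong"  # strong | weak | null
    sites_per_protein: int = 20

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 0:
            raise ParameterError("need n_pos >= 1 and n_neg >= 0")
        if self.signal not in ("strong", "weak", "null"):
            raise ParameterError(f"unknown signal mode {self.signal!r}")
        if not 0 <= self.loop_prob_background <= 1:
            raise ParameterError("loop_prob_background outside [0, 1]")
        if not 0 <= self.loop_prob_center_pos <= 1:
            raise ParameterError("loop_prob_center_pos outside [0, 1]")
        for off, res, p in self.motif_effects:
            if not -CENTER <= off <= CENTER or off == 0:
                raise ParameterError(f"motif offset {off} outside the flanks")
            if res not in AA20 or res == "T":
                raise ParameterError(f"motif residue {res!r} not allowed")
            if not 0 <= p <= 1:
                raise ParameterError(f"motif probability {p} outside [0, 1]")


def _effective(params: GeneratorParams) -> GeneratorParams:
    """Resolve the signal mode into concrete effect sizes."""
    if params.signal == "strong":
        return params
    if params.signal == "null":
        return replace(
            params,
            motif_effects=[],
            loop_prob_center_pos=params.loop_prob_background,
            acc_shift=0.0,
        )
    # weak: halve every planted effect
    lp_bg = params.loop_prob_background
    return replace(
        params,
        motif_effects=[(o, r, p / 2) for o, r, p in params.motif_effects],
        loop_prob_center_pos=lp_bg + (params.loop_prob_center_pos - lp_bg) / 2,
        acc_shift=params.acc_shift / 2,
    )


def _background_probs(params: GeneratorParams) -> np.ndarray:
    """Flank-residue distribution over AA20 with threonine excluded."""
    if params.background_freqs is None:
        probs = np.full(20, 0.05)
    else:
        probs = np.asarray(params.background_freqs, dtype=float)
        if probs.shape != (20,) or np.any(probs < 0):
            raise ParameterError("background_freqs must be 20 non-negative values")
    probs = probs.copy()
    probs[AA20.index("T")] = 0.0
    total = probs.sum()
    if total <= 0:
        raise ParameterError("background frequencies sum to zero without T")
    return probs / total


def _decay(offset: int, params: GeneratorParams) -> float:
    if params.effect_halfwidth is not None:
        return 1.0 if abs(offset) <= params.effect_halfwidth else 0.0
    return math.exp(-abs(offset) / params.decay_scale)


def generate(params: GeneratorParams) -> tuple[list[ProteinRecord], SiteTable]:
    """Sample proteins and their site table; deterministic per seed."""
    eff = _effective(params)
    rng = np.random.default_rng(params.seed)
    bg = _background_probs(eff)
    aa = np.array(list(AA20))
    motif = {off: (res, p) for off, res, p in eff.motif_effects}

    n_sites = eff.n_pos + eff.n_neg
    n_prot = max(1, min(math.ceil(n_sites / eff.sites_per_protein), eff.n_pos))
    # every protein gets one positive; spread the rest uniformly at random
    pos_counts = np.ones(n_prot, dtype=int)
    for p in rng.integers(0, n_prot, size=eff.n_pos - n_prot):
        pos_counts[p] += 1
    neg_counts = np.zeros(n_prot, dtype=int)
    for p in rng.integers(0, n_prot, size=eff.n_neg):
        neg_counts[p] += 1

    proteins: list[ProteinRecord] = []
    entries: list[SiteEntry] = []
    for pi in range(n_prot):
        labels = ["positive"] * int(pos_counts[pi]) + ["negative"] * int(neg_counts[pi])
        rng.shuffle(labels)
        seq_parts: list[str] = []
        ss_parts: list[str] = []
        acc_parts: list[np.ndarray] = []
        pid = f"syn{pi:04d}"
        for bi, label in enumerate(labels):
            positive = label == "positive"
            chars = []
            for off in range(-CENTER, CENTER + 1):
                if off == 0:
                    chars.append("T")
                    continue
                if positive and off in motif and rng.random() < motif[off][1]:
                    chars.append(motif[off][0])
                else:
                    chars.append(str(rng.choice(aa, p=bg)))
            ss_chars = []
            for off in range(-CENTER, CENTER + 1):
                lp = eff.loop_prob_background
                if positive:
                    lp += (eff.loop_prob_center_pos - eff.loop_prob_background) * _decay(
                        off, eff
                    )
                if rng.random() < lp:
                    ss_chars.append("C")
                else:
                    ss_chars.append("H" if rng.random() < 0.5 else "E")
            acc = rng.gamma(2.0, eff.acc_base_mean / 2.0, size=BLOCK)
            if positive and eff.acc_shift:
                acc += eff.acc_shift * np.array(
                    [_decay(off, eff) for off in range(-CENTER, CENTER + 1)]
                )
            seq_parts.append("".join(chars))
            ss_parts.append("".join(ss_chars))
            acc_parts.append(np.round(acc, 2))
            entries.append(
                SiteEntry(protein_id=pid, position=bi * BLOCK + CENTER + 1, label=label)
            )
        proteins.append(
            ProteinRecord(
                id=pid,
                sequence="".join(seq_parts),
                ss="".join(ss_parts),
                acc=np.concatenate(acc_parts),
            )
        )
    return proteins, SiteTable(entries=entries)


def write_outputs(
    proteins: Sequence[ProteinRecord], sites: SiteTable, outdir: str | Path
) -> dict[str, Path]:
    """Write FASTA + annotation TSV + site table; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "annotations": outdir / "annotations.tsv",
        "sites": outdir / "sites.tsv",
    }
    write_fasta(paths["fasta"], proteins)
    write_annotations(paths["annotations"], proteins)
    write_site_table(paths["sites"], sites)
    return paths


def paper_scale_preset(seed: int = 2016) -> GeneratorParams:
    """Study-scale conditions: 151 positive and 2158 negative sites."""
    return GeneratorParams(n_pos=151, n_neg=2158, seed=seed, signal="strong")


def small_preset(seed: int = 7) -> GeneratorParams:
    """A fast desk-scale set: 30 positive and 90 negative sites."""
    return GeneratorParams(n_pos=30, n_neg=90, seed=seed, signal="strong")
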