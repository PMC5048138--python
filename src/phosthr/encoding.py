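"""Feature encoding: four groups, per-group window sizes, 216-dim default.

Each window contributes four feature groups:

* **F1** — PWM-difference position scores F(l) (one value per flank
  offset);
* **F2** — structure: a secondary-structure scalar (H -> 0.0, E -> 0.5,
  C -> 1.0, X -> 0.5) and an accessibility value scaled to [0, 1] by the
  dataset-wide maximum (X -> 0), two values per offset;
* **F3** — physical properties: rigidity, flexibility, irreplaceability
  (three values per offset);
* **F4** — chemical properties: hydrophobicity, hydrophilicity, mass,
  pk1, pk2, pi (six values per offset).

Property values are min-max scaled per property over the 20 residues;
X maps to 0.5 after scaling.  A group's window size ``w`` counts
flanking residues (w/2 per side, center threonine excluded), so the
total dimension is ``w1 + 2*w2 + 3*w3 + 6*w4`` — 216 at the default
(12, 12, 24, 18).  Offsets are laid out center-outward (-1, +1, -2,
+2, ...), so widening a group appends features without renaming or
moving the inner ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset import ResidueWindow
from .errors import ParameterError
from .profiles import (
    PWMPair,
    center_out_offsets,
    residue_index_matrix,
    score_peptide,
)

#: Secondary-structure scalar encoding; X (padding) sits mid-scale.
SS_VALUES = {"H": 0.0, "E": 0.5, "C": 1.0, "X": 0.5}

#: Scaled property value assigned to X/padding residues.
X_PROPERTY_VALUE = 0.5

PHYSICAL_PROPERTIES = ("rigidity", "flexibility", "irreplaceability")
CHEMICAL_PROPERTIES = ("hydrophobicity", "hydrophilicity", "mass", "pk1", "pk2", "pi")

GROUPS = ("F1", "F2", "F3", "F4")


class PropertyTable:
    """20 residues x 9 physicochemical properties, with min-max scaling."""

    def __init__(self, values: pd.DataFrame, source: str = "packaged"):
        from .readwrite import AA20

        missing = set(AA20) - set(values.index)
        if missing:
            raise ParameterError(f"property table missing residues {sorted(missing)}")
        self.values = values.loc[list(AA20)].astype(float)
        self.source = source
        span = self.values.max() - self.values.min()
        if (span == 0).any():
            raise ParameterError("property with zero range cannot be min-max scaled")
        self.scaled = (self.values - self.values.min()) / span

    @property
    def properties(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def raw_vector(self, prop: str) -> np.ndarray:
        if prop not in self.values.columns:
            raise ParameterError(f"unknown property {prop!r}")
        return self.values[prop].to_numpy()

    def scaled_vector(self, prop: str) -> np.ndarray:
        if prop not in self.scaled.columns:
            raise ParameterError(f"unknown property {prop!r}")
        return self.scaled[prop].to_numpy()

    def raw_value(self, residue: str, prop: str) -> float:
        """Raw table value; X maps to the per-property mean."""
        if prop not in self.values.columns:
            raise ParameterError(f"unknown property {prop!r}")
        if residue == "X":
            return float(self.values[prop].mean())
        return float(self.values.at[residue, prop])

    def scaled_value(self, residue: str, prop: str) -> float:
        """Min-max scaled value; X maps to 0.5."""
        if prop not in self.scaled.columns:
            raise ParameterError(f"unknown property {prop!r}")
        if residue == "X":
            return X_PROPERTY_VALUE
        return float(self.scaled.at[residue, prop])

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PropertyTable":
        if path is None:
            ref = resources.files("phosthr.data").joinpath("aa_properties.tsv")
            with resources.as_file(ref) as p:
                df = pd.read_csv(p, sep="\t", comment="#", index_col="residue")
            return cls(df, source="packaged aa_properties.tsv")
        df = pd.read_csv(path, sep="\t", comment="#", index_col="residue")
        return cls(df, source=str(path))


@dataclass
class WindowConfig:
    """Per-group window sizes (flanking residue counts, center excluded)."""

    w1: int = 12  # F1 position scores
    w2: int = 12  # F2 structure (ss + accessibility)
    w3: int = 24  # F3 physical properties
    w4: int = 18  # F4 chemical properties

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "w4"):
            w = getattr(self, name)
            if w % 2 != 0 or not 2 <= w <= 30:
                raise ParameterError(
                    f"{name}={w}: window sizes must be even and within 2..30"
                )

    @property
    def n_features(self) -> int:
        return self.w1 + 2 * self.w2 + 3 * self.w3 + 6 * self.w4

    def group_size(self, group: str) -> int:
        return {"F1": self.w1, "F2": self.w2, "F3": self.w3, "F4": self.w4}[group]


@dataclass
class FeatureMatrix:
    """Samples x named features with binary labels.

    Feature names follow ``group:property:offset`` (e.g. ``F2:acc:+1``),
    so each column carries its group and signed position.
    """

    X: np.ndarray
    names: list[str]
    y: np.ndarray
    config: WindowConfig | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[1] != len(self.names):
            raise ParameterError("feature count does not match name count")
        if self.X.shape[0] != len(self.y):
            raise ParameterError("sample count does not match label count")
        if len(set(self.names)) != len(self.names):
            raise ParameterError("feature names must be unique")
        if self.config is not None and self.X.shape[1] != self.config.n_features:
            raise ParameterError(
                f"matrix has {self.X.shape[1]} columns but the window config "
                f"implies {self.config.n_features}"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df["label"] = self.y
        return df

    def subset(self, column_indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(column_indices)
        return FeatureMatrix(
            X=self.X[:, idx], names=[self.names[i] for i in idx], y=self.y
        )


def feature_names(group: str, properties: Sequence[str], w: int) -> list[str]:
    return [
        f"{group}:{prop}:{off:+d}"
        for off in center_out_offsets(w)
        for prop in properties
    ]


def encode_scores(window: ResidueWindow, pwm_pair: PWMPair, w: int) -> np.ndarray:
    """F1: PWM-difference scores at flank w/2; w values."""
    if w // 2 > pwm_pair.flank:
        raise ParameterError(
            f"w={w} requires flank {w // 2} but the PWM covers {pwm_pair.flank}"
        )
    return score_peptide(window, pwm_pair, flank=w // 2).F


def encode_structure(window: ResidueWindow, w: int, max_acc: float = 1.0) -> np.ndarray:
    """F2: per offset one ss scalar and one scaled accessibility; 2*w values."""
    if max_acc <= 0:
        max_acc = 1.0
    vals: list[float] = []
    flank = window.flank
    for off in center_out_offsets(w):
        i = flank + off
        vals.append(SS_VALUES[window.ss[i]])
        if window.residues[i] == "X":
            vals.append(0.0)
        else:
            vals.append(min(float(window.acc[i]) / max_acc, 1.0))
    return np.array(vals)


def encode_physchem(
    window: ResidueWindow,
    w: int,
    properties: Sequence[str],
    table: PropertyTable,
) -> np.ndarray:
    """F3/F4: per offset, per property the scaled table value; len(props)*w."""
    vals: list[float] = []
    flank = window.flank
    for off in center_out_offsets(w):
        res = window.residues[flank + off]
        for prop in properties:
            vals.append(table.scaled_value(res, prop))
    return np.array(vals)


def _labels_of(windows: Sequence[ResidueWindow]) -> np.ndarray:
    return np.array([1 if w.label == "positive" else 0 for w in windows])


def dataset_max_acc(windows: Sequence[ResidueWindow]) -> float:
    """Dataset-wide accessibility maximum used to scale F2."""
    m = max((float(np.max(w.acc)) for w in windows), default=0.0)
    return m if m > 0 else 1.0


def assemble_features(
    windows: Sequence[ResidueWindow],
    config: WindowConfig,
    pwm_pair: PWMPair,
    table: PropertyTable | None = None,
    max_acc: float | None = None,
) -> FeatureMatrix:
    """Concatenate F1 | F2 | F3 | F4 for every window (vectorized).

    ``max_acc`` defaults to the dataset-wide accessibility maximum of
    ``windows``; pass it explicitly to scale against a training set.
    """
    if not windows:
        raise ParameterError("cannot encode an empty window set")
    if table is None:
        table = PropertyTable.load()
    if max_acc is None:
        max_acc = dataset_max_acc(windows)
    if max_acc <= 0:
        max_acc = 1.0
    flank = windows[0].flank
    for grp in GROUPS:
        if config.group_size(grp) // 2 > flank:
            raise ParameterError(
                f"{grp} window {config.group_size(grp)} exceeds the "
                f"{2 * flank + 1}-mer flank"
            )
    if config.w1 // 2 > pwm_pair.flank:
        raise ParameterError("F1 window exceeds the PWM width")

    R = residue_index_matrix(windows)  # (n, 2*flank+1), X -> -1
    n = R.shape[0]

    # F1: gather PWM-difference weights of the observed residues
    offs1 = np.array(center_out_offsets(config.w1))
    cols1 = flank + offs1
    D = pwm_pair.diff
    pcols = pwm_pair.flank + offs1
    R1 = R[:, cols1]
    F1 = np.where(R1 >= 0, D[np.clip(R1, 0, 19), pcols[None, :]], 0.0)

    # F2: ss scalar + scaled accessibility, interleaved per offset
    offs2 = np.array(center_out_offsets(config.w2))
    cols2 = flank + offs2
    ss = np.array([[SS_VALUES[c] for c in w.ss] for w in windows])
    acc = np.stack([w.acc for w in windows])
    ss2 = ss[:, cols2]
    acc2 = np.minimum(acc[:, cols2] / max_acc, 1.0)
    acc2 = np.where(R[:, cols2] >= 0, acc2, 0.0)
    F2 = np.empty((n, 2 * len(offs2)))
    F2[:, 0::2] = ss2
    F2[:, 1::2] = acc2

    def physchem_block(w: int, props: Sequence[str]) -> np.ndarray:
        offs = np.array(center_out_offsets(w))
        cols = flank + offs
        Rg = R[:, cols]
        # columns ordered offset-major, property-minor (matches feature_names)
        block = np.empty((n, len(props) * len(offs)))
        for j, prop in enumerate(props):
            vec = table.scaled_vector(prop)
            block[:, j :: len(props)] = np.where(
                Rg >= 0, vec[np.clip(Rg, 0, 19)], X_PROPERTY_VALUE
            )
        return block

    F3 = physchem_block(config.w3, PHYSICAL_PROPERTIES)
    F4 = physchem_block(config.w4, CHEMICAL_PROPERTIES)

    X = np.hstack([F1, F2, F3, F4])
    names = (
        feature_names("F1", ("score",), config.w1)
        + feature_names("F2", ("ss", "acc"), config.w2)
        + feature_names("F3", PHYSICAL_PROPERTIES, config.w3)
        + feature_names("F4", CHEMICAL_PROPERTIES, config.w4)
    )
    return FeatureMatrix(X=X, names=names, y=_labels_of(windows), config=config)


def assemble_features_loo(
    windows: Sequence[ResidueWindow],
    config: WindowConfig,
    table: PropertyTable | None = None,
    p0: float = 0.05,
    alpha: float = 1.0,
    max_acc: float | None = None,
) -> FeatureMatrix:
    """Assemble features with leave-one-out F1 encoding.

    The F1 group is derived from class-specific PWMs, so encoding a
    window against a PWM that contains the window itself leaks its own
    label into its features.  Here each window's F1 scores are computed
    against its own class's PWM rebuilt *without* that window, making
    every sample's features a function of the other samples only and
    keeping train and held-out F1 distributions identical under
    jackknife evaluation.  F2-F4 do not depend on labels and are
    assembled as usual.
    """
    from .profiles import count_matrix, pwm_from_counts

    if table is None:
        table = PropertyTable.load()
    labels = _labels_of(windows)
    if labels.min() == labels.max():
        raise ParameterError("leave-one-out encoding needs both classes")
    if max_acc is None:
        max_acc = dataset_max_acc(windows)

    per = np.stack([count_matrix([w]) for w in windows])  # (n, 20, L)
    tot_pos = per[labels == 1].sum(axis=0)
    tot_neg = per[labels == 0].sum(axis=0)

    # static blocks (F2-F4) once, against an arbitrary valid pair
    base_pair = PWMPair(
        pos=pwm_from_counts(tot_pos, p0=p0, alpha=alpha),
        neg=pwm_from_counts(tot_neg, p0=p0, alpha=alpha),
        p0=p0,
        alpha=alpha,
    )
    fm = assemble_features(windows, config, base_pair, table, max_acc=max_acc)

    flank = windows[0].flank
    offs1 = np.array(center_out_offsets(config.w1))
    cols1 = flank + offs1
    R = residue_index_matrix(windows)
    R1 = np.clip(R[:, cols1], 0, 19)
    known1 = R[:, cols1] >= 0
    for i in range(len(windows)):
        cpos = tot_pos - (per[i] if labels[i] == 1 else 0)
        cneg = tot_neg - (per[i] if labels[i] == 0 else 0)
        D = pwm_from_counts(cpos, p0=p0, alpha=alpha) - pwm_from_counts(
            cneg, p0=p0, alpha=alpha
        )
        fm.X[i, : config.w1] = np.where(known1[i], D[R1[i], cols1], 0.0)
    return fm


def encode_group(
    windows: Sequence[ResidueWindow],
    group: str,
    w: int,
    pwm_pair: PWMPair | None = None,
    table: PropertyTable | None = None,
    max_acc: float | None = None,
) -> FeatureMatrix:
    """Encode a single feature group at window size ``w``."""
    if group not in GROUPS:
        raise ParameterError(f"unknown feature group {group!r}")
    if group == "F1":
        if pwm_pair is None:
            raise ParameterError("F1 encoding requires a PWM pair")
        X = np.stack([encode_scores(win, pwm_pair, w) for win in windows])
        names = feature_names("F1", ("score",), w)
    elif group == "F2":
        if max_acc is None:
            max_acc = dataset_max_acc(windows)
        X = np.stack([encode_structure(win, w, max_acc) for win in windows])
        names = feature_names("F2", ("ss", "acc"), w)
    else:
        if table is None:
            table = PropertyTable.load()
        props = PHYSICAL_PROPERTIES if group == "F3" else CHEMICAL_PROPERTIES
        X = np.stack([encode_physchem(win, w, props, table) for win in windows])
        names = feature_names("F3" if group == "F3" else "F4", props, w)
    return FeatureMatrix(X=X, names=names, y=_labels_of(windows))


def optimize_window_size(
    windows: Sequence[ResidueWindow],
    group: str,
    sizes: Sequence[int],
    evaluator: Callable[[np.ndarray, np.ndarray], float],
    pwm_pair: PWMPair | None = None,
    table: PropertyTable | None = None,
) -> tuple[int, dict[int, float]]:
    """Sweep window sizes for one group; return (best size, auROC per size).

    ``evaluator`` maps (X, y) to a score (jackknife auROC in the full
    pipeline).  The best size maximizes the score; ties break toward the
    smaller size (sizes are evaluated in ascending order).
    """
    if not sizes:
        raise ParameterError("no candidate sizes given")
    curve: dict[int, float] = {}
    best_size, best_score = None, -np.inf
    for w in sorted(set(int(s) for s in sizes)):
        fm = encode_group(windows, group, w, pwm_pair=pwm_pair, table=table)
        try:
            score = float(evaluator(fm.X, fm.y))
        except Exception as exc:  # noqa: BLE001 - annotate the offending size
            raise RuntimeError(f"evaluator failed at window size {w}: {exc}") from exc
        curve[w] = score
        if score > best_score:
            best_size, best_score = w, score
    assert best_size is not None
    return best_size, curve
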