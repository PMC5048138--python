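"""Shared fixtures: tiny hand-made windows and generated datasets."""

import numpy as np
import pytest

from phosthr.dataset import ResidueWindow
from phosthr.encoding import PropertyTable


def make_window(
    residues: str,
    ss: str | None = None,
    acc=None,
    label: str = "negative",
    protein_id: str = "w",
    center_pos: int | None = None,
) -> ResidueWindow:
    """Build a window, defaulting ss to all-coil and acc to zeros."""
    n = len(residues)
    if ss is None:
        ss = "".join("X" if r == "X" else "C" for r in residues)
    if acc is None:
        acc = np.zeros(n)
    if center_pos is None:
        center_pos = n // 2 + 1
    return ResidueWindow(
        protein_id=protein_id,
        center_pos=center_pos,
        residues=residues,
        ss=ss,
        acc=np.asarray(acc, dtype=float),
        label=label,
    )


def t_window(flank_left: str, flank_right: str, **kw) -> ResidueWindow:
    """A window assembled from explicit flanks around the central T."""
    return make_window(flank_left + "T" + flank_right, **kw)


@pytest.fixture(scope="session")
def property_table() -> PropertyTable:
    return PropertyTable.load()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20160817 % 2**31)


def random_windows(rng, n: int, flank: int = 15, label: str = "negative"):
    """Random 31-mer windows over the 20-letter alphabet, center T."""
    from phosthr.readwrite import AA20

    aa = np.array(list(AA20))
    out = []
    for i in range(n):
        left = "".join(rng.choice(aa, size=flank))
        right = "".join(rng.choice(aa, size=flank))
        ss = "".join(rng.choice(list("HEC"), size=2 * flank + 1))
        acc = rng.gamma(2.0, 15.0, size=2 * flank + 1)
        out.append(
            make_window(left + "T" + right, ss=ss, acc=acc, label=label,
                        protein_id=f"r{i}")
        )
    return out
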