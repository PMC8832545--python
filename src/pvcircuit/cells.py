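"""Transcript-count cell typing, per-animal summaries, and laminar geometry.

Implements the in situ hybridisation analysis conventions: a cell is
positive for a gene when it contains strictly more than 4 transcripts;
excitatory/inhibitory identity follows Slc17a6 vs GAD1 expression; summary
proportions are computed per animal with the SEM taken over per-animal
percentages; laminar boundaries are derived from the dorsal white matter
and the dorsal edge of the PV plexus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reporting import round_half_up

__all__ = [
    "CellTypeCall",
    "AnimalSummary",
    "LaminarBoundaries",
    "call_positive",
    "classify_ei",
    "classify_table",
    "summarize_per_animal",
    "pooled_proportion",
    "laminar_boundaries",
    "assign_lamina",
]

POSITIVE_THRESHOLD = 4  # strictly greater than 4 transcripts


@dataclass
class CellTypeCall:
    positives: set
    ei_class: str  # excitatory | inhibitory | ambiguous | neither


@dataclass
class AnimalSummary:
    per_animal: pd.Series  # animal -> proportion (fraction)
    mean_pct: float
    sem_pct: float
    flags: list = field(default_factory=list)


@dataclass
class LaminarBoundaries:
    wm_depth: float  # µm; dorsal white matter reference (0 by convention)
    lamina_I_IIo_border: float
    IIo_IIi_border: float
    IIi_III_border: float
    III_ventral: float

    def __post_init__(self) -> None:
        seq = (
            self.wm_depth,
            self.lamina_I_IIo_border,
            self.IIo_IIi_border,
            self.IIi_III_border,
            self.III_ventral,
        )
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("boundaries must be strictly increasing")


def call_positive(count: int, threshold: int = POSITIVE_THRESHOLD) -> bool:
    """Positive iff the cell contains strictly more than ``threshold``
    transcripts (4 transcripts is negative; 5 is positive)."""
    if count < 0:
        raise ValueError("transcript count must be >= 0")
    return count > threshold


def classify_ei(counts: dict, threshold: int = POSITIVE_THRESHOLD) -> CellTypeCall:
    """Excitatory/inhibitory call from Slc17a6 and GAD1 counts.

    Double positives are flagged "ambiguous" and double negatives
    "neither"; they are reported, never merged into the main classes.
    """
    for gene in ("Slc17a6", "GAD1"):
        if gene not in counts:
            raise KeyError(f"missing required gene {gene!r}")
    positives = {g for g, c in counts.items() if call_positive(c, threshold)}
    exc = "Slc17a6" in positives
    inh = "GAD1" in positives
    if exc and inh:
        ei = "ambiguous"
    elif exc:
        ei = "excitatory"
    elif inh:
        ei = "inhibitory"
    else:
        ei = "neither"
    return CellTypeCall(positives=positives, ei_class=ei)


def classify_table(table: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Apply :func:`classify_ei` to a wide per-cell count table; returns the
    table with an ``ei_class`` column and per-gene boolean positivity."""
    genes = genes or [
        c for c in table.columns
        if c not in ("cell_id", "animal", "true_class", "ei_class")
    ]
    out = table.copy()
    for g in genes:
        out[f"{g}_pos"] = out[g].map(call_positive)
    out["ei_class"] = [
        classify_ei({g: row[g] for g in genes}).ei_class
        for _, row in table.iterrows()
    ]
    return out


def summarize_per_animal(
    counts: pd.DataFrame,
    animal_col: str = "animal",
    numerator_col: str = "numerator",
    denominator_col: str = "denominator",
) -> AnimalSummary:
    """Mean and SEM of per-animal percentages.

    ``counts`` holds one row per animal with numerator and denominator
    counts (or per-cell rows with boolean flags, which are summed). The SEM
    convention is SD/sqrt(n_animals) over the per-animal percentages.
    Animals with a zero denominator are excluded with a warning.
    """
    g = counts.groupby(animal_col)[[numerator_col, denominator_col]].sum()
    flags = []
    zero = g[g[denominator_col] == 0]
    if len(zero):
        warnings.warn(
            f"excluding animals with zero denominator: {list(zero.index)}",
            stacklevel=2,
        )
        flags.append("animals_excluded")
        g = g[g[denominator_col] > 0]
    if g.empty:
        raise ValueError("no animal with a positive denominator")
    props = g[numerator_col] / g[denominator_col]
    pcts = 100.0 * props
    mean_pct = round_half_up(float(np.mean(pcts)), 1)
    if len(pcts) > 1:
        sem = float(np.std(pcts, ddof=1) / np.sqrt(len(pcts)))
        sem_pct = round_half_up(sem, 1)
    else:
        sem_pct = 0.0
        flags.append("single_animal_sem_undefined")
    return AnimalSummary(
        per_animal=props, mean_pct=mean_pct, sem_pct=sem_pct, flags=flags
    )


def pooled_proportion(numerator: int, denominator: int, precision: int = 1) -> float:
    """Pooled percentage with half-up rounding at ``precision`` decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, precision)


def laminar_boundaries(
    wm_depth: float, plexus_dorsal_edge: float
) -> LaminarBoundaries:
    """Dorsal-horn laminar borders from two landmarks.

    The lamina I/IIo border sits 20 µm below the dorsal white matter; the
    IIo/IIi border is the dorsal edge of the PV plexus; lamina IIi has the
    same dorsoventral extent as IIo, and lamina III the extent of IIo and
    IIi combined. Depths increase ventrally from the white matter (0).
    """
    i_iio = wm_depth + 20.0
    if plexus_dorsal_edge <= i_iio:
        raise ValueError("plexus edge must lie below the lamina I/IIo border")
    extent = plexus_dorsal_edge - i_iio
    iii_border = plexus_dorsal_edge + extent
    return LaminarBoundaries(
        wm_depth=wm_depth,
        lamina_I_IIo_border=i_iio,
        IIo_IIi_border=plexus_dorsal_edge,
        IIi_III_border=iii_border,
        III_ventral=iii_border + 2.0 * extent,
    )


def assign_lamina(depth: float, b: LaminarBoundaries) -> str:
    """Half-open interval lookup [lower, upper); deeper than lamina III's
    ventral limit returns "deeper"."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth < b.lamina_I_IIo_border:
        return "I"
    if depth < b.IIo_IIi_border:
        return "IIo"
    if depth < b.IIi_III_border:
        return "IIi"
    if depth < b.III_ventral:
        return "III"
    return "deeper"
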