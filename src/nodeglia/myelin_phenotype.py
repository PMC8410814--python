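"""Remyelination and microglial-phenotype quantification.

Myelination index: area of the myelin mask restricted to the axon mask,
divided by the axon mask area (both within an optional ROI excluding
somas and white-matter tracts).  Lesion unremyelinated fraction: lesion
area without myelin signal over total lesion area.  Marker-positive
fractions (e.g. IGF1+ pro-regenerative or iNOS+ pro-inflammatory
microglia among Iba1+ cells) use an explicit, recorded positivity rule —
per-cell mean marker intensity above k x the field background median —
because the original scoring was visual and no threshold is otherwise
defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default positivity multiplier over field background median
DEFAULT_K = 2.0


def myelination_index(axon_mask: np.ndarray, myelin_mask: np.ndarray, roi=None) -> float:
    """Myelinated fraction of the axonal area: |myelin ∩ axon| / |axon|.

    ``roi`` (optional boolean mask, same shape) restricts both masks,
    e.g. to exclude somas and white-matter tracts.  Zero axon area
    inside the ROI raises — the ratio is undefined.
    """
    axon = np.asarray(axon_mask, dtype=bool)
    myelin = np.asarray(myelin_mask, dtype=bool)
    if axon.shape != myelin.shape:
        raise ValueError("axon and myelin masks must share shape")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != axon.shape:
            raise ValueError("roi must match mask shape")
        axon = axon & roi
        myelin = myelin & roi
    denom = int(axon.sum())
    if denom == 0:
        raise ValueError("zero axon area: myelination index undefined")
    return float((myelin & axon).sum() / denom)


def lesion_unremyelinated_fraction(lesion_mask: np.ndarray, myelin_mask: np.ndarray) -> float:
    """Fraction of the lesion area lacking myelin signal."""
    lesion = np.asarray(lesion_mask, dtype=bool)
    myelin = np.asarray(myelin_mask, dtype=bool)
    if lesion.shape != myelin.shape:
        raise ValueError("lesion and myelin masks must share shape")
    area = int(lesion.sum())
    if area == 0:
        raise ValueError("empty lesion: fraction undefined")
    return float((lesion & ~myelin).sum() / area)


@dataclass
class CellPhenotype:
    """Marker measurements for one cell."""

    cell_id: int
    microglia_positive: bool
    marker_means: dict[str, float] = field(default_factory=dict)

    def is_positive(self, marker: str, background_median: float, k: float = DEFAULT_K) -> bool:
        if not self.microglia_positive:
            raise ValueError("marker calls are defined only for microglia-positive cells")
        return self.marker_means[marker] > k * background_median


def measure_phenotypes(
    cell_labels: np.ndarray,
    marker_channels: dict[str, np.ndarray],
    microglia_positive=None,
) -> list[CellPhenotype]:
    """Per-cell mean intensity of each marker channel.

    ``cell_labels`` is an integer label image (0 = background);
    ``microglia_positive`` optionally maps cell id -> bool (all cells
    are treated as microglia by default, as with Iba1-segmented cells).
    """
    labels = np.asarray(cell_labels)
    cells = []
    for lab in range(1, labels.max() + 1):
        sel = labels == lab
        if not sel.any():
            continue
        means = {m: float(np.asarray(ch)[sel].mean()) for m, ch in marker_channels.items()}
        mg = True if microglia_positive is None else bool(microglia_positive[lab])
        cells.append(CellPhenotype(cell_id=lab, microglia_positive=mg, marker_means=means))
    return cells


def marker_positive_fraction(
    cells: list[CellPhenotype],
    marker: str,
    background_median: float,
    k: float = DEFAULT_K,
) -> float:
    """Percent of microglia-positive cells positive for ``marker``.

    Positivity: per-cell mean marker intensity > k x field background
    median (k and the rule are deliberately explicit — record them with
    any reported number).  Raises if no microglia-positive cell exists.
    """
    microglia = [c for c in cells if c.microglia_positive]
    if not microglia:
        raise ValueError("no microglia-positive cells: fraction undefined")
    positive = sum(c.is_positive(marker, background_median, k) for c in microglia)
    return 100.0 * positive / len(microglia)


def phenotype_by_contact(
    contacting: "pd.Series | dict",
    marker_positive: "pd.Series | dict",
    animal: "pd.Series | dict | None" = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame] | None]:
    """Cross-tabulate contacting status against marker positivity.

    Inputs map cell id -> bool.  Returns the pooled 2x2 count table
    (rows: contacting True/False; columns: marker-positive True/False)
    and, when ``animal`` is given, per-animal stratified tables for
    downstream conditional-independence testing (the testing itself is
    delegated to standard statistics tooling).  A missing stratum (e.g.
    no contacting cell at all) yields a reduced table and a warning.
    """
    contacting = pd.Series(contacting, name="contacting")
    marker_positive = pd.Series(marker_positive, name="marker_positive")
    df = pd.concat([contacting, marker_positive], axis=1).dropna()
    table = pd.crosstab(df["contacting"], df["marker_positive"])
    if len(table.index) < 2:
        warnings.warn(
            "only one contacting stratum present; table is degenerate", stacklevel=2
        )
    strata = None
    if animal is not None:
        df = df.assign(animal=pd.Series(animal))
        strata = {
            a: pd.crosstab(g["contacting"], g["marker_positive"])
            for a, g in df.groupby("animal")
        }
    return table, strata
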