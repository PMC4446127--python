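"""Expression and antisense-level gene bins, and per-bin footprints.

Genes are ranked by a tag count and split into four contiguous rank blocks
of near-equal size (ties broken by stable gene-id order), so heavy ties can
never empty a bin. Antisense binning first sets aside genes with exactly
zero antisense tags as the 'None' group.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .footprints import FootprintProfile, SignalMatrix, mean_footprint

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ["Lowest", "Mid-low", "Mid-high", "Highest"]


def _rank_quartiles(counts: pd.Series) -> pd.Series:
    """Split genes into four near-equal rank blocks by (count, gene_id)."""
    order = counts.sort_values(kind="stable").index  # stable: id order on ties
    labels = pd.Series(index=counts.index, dtype=object)
    for lab, block in zip(QUARTILE_LABELS, np.array_split(np.asarray(order), 4)):
        labels.loc[block] = lab
    return labels


def expression_bins(sense_tag_counts: Mapping[str, int]) -> pd.Series:
    """Quartile labels from sense-strand tag counts at the TSS."""
    counts = pd.Series(sense_tag_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative tag count")
    if len(counts) < 4:
        raise ValueError("need at least 4 genes to form quartiles")
    return _rank_quartiles(counts)


def antisense_bins(antisense_tag_counts: Mapping[str, int]) -> pd.Series:
    """'None' for zero antisense tags, else quartiles of the nonzero genes."""
    counts = pd.Series(antisense_tag_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative tag count")
    labels = pd.Series("None", index=counts.index, dtype=object)
    nonzero = counts[counts > 0]
    if len(nonzero) >= 4:
        labels.loc[nonzero.index] = _rank_quartiles(nonzero)
    elif len(nonzero) > 0:
        labels.loc[nonzero.index] = QUARTILE_LABELS[-1]
    return labels


def per_bin_footprints(
    bins: pd.Series,
    annotation: pd.DataFrame,
    matrices: Mapping[str, SignalMatrix],
    classes: Sequence[str] = ("uni", "bi"),
    n_boot: int = 100,
    seed: int = 0,
) -> dict[tuple[str, str, str], FootprintProfile]:
    """One footprint per (mark, combined class, bin label).

    The directionality annotation is intersected with each bin, i.e. the
    class composition is re-derived within every bin. Empty (class, bin)
    cells are omitted with a warning.
    """
    out: dict[tuple[str, str, str], FootprintProfile] = {}
    for mark, matrix in matrices.items():
        in_matrix = pd.Index(matrix.gene_ids)
        for cls in classes:
            cls_ids = annotation.index[annotation["class_combined"] == cls]
            for lab in pd.unique(bins):
                ids = [g for g in bins.index[bins == lab]
                       if g in cls_ids and g in in_matrix]
                if not ids:
                    logger.warning("empty cell (%s, %s, %s): omitted",
                                   mark, cls, lab)
                    continue
                out[(mark, cls, lab)] = mean_footprint(
                    matrix.subset(ids), n_boot=n_boot, seed=seed)
    return out


def bins_table(assignments: Mapping[str, pd.Series],
               values: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Long-format table: gene_id, bin_variable, bin_label, value."""
    rows = []
    for variable, bins in assignments.items():
        vals = values.get(variable, {})
        for gid, lab in bins.items():
            rows.append({"gene_id": gid, "bin_variable": variable,
                         "bin_label": lab, "value": vals.get(gid, np.nan)})
    return pd.DataFrame(rows)
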