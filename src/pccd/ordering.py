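"""Coordinate normalization and distance-based birth ordering.

Within a lineage, birth order correlates with distance from the neuroblast:
in third-instar larvae, recently born motoneurons lie close to the stem cell
and the oldest lie furthest away.  The pipeline exploits this by ranking each
specimen's motoneurons by descending Euclidean distance from the neuroblast —
rank 1 is the furthest, i.e. the oldest on average — which turns each
specimen into an ordered boolean sequence per transcription factor.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    CellClass,
    CellRecord,
    OrderedSequence,
    Specimen,
    SpecimenSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_to_reference",
    "distance_to_reference",
    "order_sequence",
    "cohort_sequences",
    "sequences_to_frame",
]


def normalize_to_reference(specimen: Specimen) -> Specimen:
    """Translate all coordinates so the reference cell sits at the origin.

    The reference is the neuroblast when present; otherwise a designated
    ventral reference cell stands in.  Classes and calls are untouched; the
    translation is an isometry, so inter-cell distances are preserved.
    Returns a new Specimen (input unchanged).
    """
    ref = specimen.reference_cell
    ox, oy, oz = ref.x, ref.y, ref.z
    cells = [
        dataclasses.replace(
            c, x=c.x - ox, y=c.y - oy, z=c.z - oz, tf_calls=dict(c.tf_calls)
        )
        for c in specimen.cells
    ]
    return dataclasses.replace(specimen, cells=cells)


def distance_to_reference(cell: CellRecord) -> float:
    """Euclidean distance (µm) of a cell from the origin.

    Assumes the specimen has been normalized so the reference cell is at
    (0, 0, 0).
    """
    return float(np.linalg.norm(cell.coords))


def order_sequence(
    specimen: Specimen,
    tf: str,
    include_apoptotic: bool = False,
) -> OrderedSequence:
    """Rank one specimen's motoneurons for one TF by descending distance.

    Only MN-class cells with a non-missing call for ``tf`` enter the
    sequence (apoptotic cells are excluded unless ``include_apoptotic``).
    Ties at equal distance are broken by ascending cell_id, then input
    order, so the ranking is deterministic.
    """
    if tf not in specimen.stained_tfs:
        raise ValidationError(
            f"TF {tf!r} not in the stained panel of specimen {specimen.specimen_id}"
        )
    classes = {CellClass.MN}
    if include_apoptotic:
        classes.add(CellClass.APOPTOTIC)
    eligible = [
        c
        for c in specimen.cells
        if c.cell_class in classes and tf in c.tf_calls
    ]
    if not eligible:
        logger.warning(
            "specimen %s: no eligible cells for TF %s; empty sequence",
            specimen.specimen_id,
            tf,
        )
        return OrderedSequence(specimen.specimen_id, tf, [], [], [])
    dist = {c.cell_id: distance_to_reference(c) for c in eligible}
    # stable sort on (-distance, cell_id); residual ties keep input order
    ordered = sorted(eligible, key=lambda c: (-dist[c.cell_id], c.cell_id))
    return OrderedSequence(
        specimen_id=specimen.specimen_id,
        tf=tf,
        calls=[bool(c.tf_calls[tf]) for c in ordered],
        distances=[dist[c.cell_id] for c in ordered],
        cell_ids=[c.cell_id for c in ordered],
    )


def cohort_sequences(
    sset: SpecimenSet,
    tf: str,
    include_apoptotic: bool = False,
) -> list[OrderedSequence]:
    """Ordered sequences for every specimen in the cohort staining ``tf``.

    Specimens not staining the TF are skipped (their cells must never enter
    the at-risk counts).  Empty sequences are dropped.
    """
    seqs = []
    for s in sset:
        if tf not in s.stained_tfs:
            continue
        seq = order_sequence(normalize_to_reference(s), tf, include_apoptotic)
        if len(seq):
            seqs.append(seq)
    return seqs


def sequences_to_frame(sequences: Iterable[OrderedSequence]) -> pd.DataFrame:
    """Export sequences as a tidy table (specimen, tf, rank, call, distance_um)."""
    rows = [
        {
            "specimen_id": s.specimen_id,
            "tf": s.tf,
            "rank": i + 1,
            "call": int(c),
            "distance_um": d,
        }
        for s in sequences
        for i, (c, d) in enumerate(zip(s.calls, s.distances))
    ]
    return pd.DataFrame(rows, columns=["specimen_id", "tf", "rank", "call", "distance_um"])
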