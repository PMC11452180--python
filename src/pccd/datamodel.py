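"""Domain types and table I/O for the positive-cell-cluster-detection pipeline.

The pipeline starts from segmented, immunostained lineages: each specimen is
one imaged stem-cell lineage whose cells carry 3D coordinates (µm), a cell
class, and per-transcription-factor (TF) binary staining calls.  A call may be
*missing*, meaning the TF was not assessed in that specimen — missingness is
explicit and never collapsed to "off".

Canonical on-disk representation is a long-format table with columns
``specimen_id, cell_id, class, x_um, y_um, z_um, tf, call`` plus a per-specimen
metadata JSON (genotype, stage, reference cell).  Wide tables (one boolean
column per TF) are accepted on input only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellClass",
    "CellRecord",
    "Specimen",
    "SpecimenSet",
    "OrderedSequence",
    "SmoothingConfig",
    "PeakConfig",
    "FrequencyProfile",
    "Peak",
    "ClusterCall",
    "TFCodeMap",
    "ValidationError",
    "load_specimens",
    "write_specimens",
    "write_codemap",
    "read_codemap_report",
]

LONG_COLUMNS = ["specimen_id", "cell_id", "class", "x_um", "y_um", "z_um", "tf", "call"]


class ValidationError(ValueError):
    """A cell table or domain object violates a structural invariant."""


class CellClass(str, Enum):
    """Cell identity classes found in an imaged lineage."""

    NB = "NB"            # neuroblast (the stem cell)
    GMC = "GMC"          # ganglion mother cell
    MN = "MN"            # (immature) motoneuron — the cells the pipeline orders
    GLIA = "glia"
    APOPTOTIC = "apoptotic"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "CellClass":
        try:
            return cls(label)
        except ValueError:
            try:
                return cls[str(label).upper()]
            except KeyError:
                raise ValidationError(f"unknown cell class label {label!r}") from None


@dataclass
class CellRecord:
    """One segmented cell: id, class, µm coordinates, per-TF binary calls.

    ``tf_calls`` maps TF name -> bool; a TF absent from the mapping was not
    assessed for this cell (distinct from ``False``).
    """

    cell_id: str
    cell_class: CellClass
    x: float
    y: float
    z: float
    tf_calls: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x, self.y, self.z = (float(v) for v in (self.x, self.y, self.z))
        coords = (self.x, self.y, self.z)
        if not all(np.isfinite(c) for c in coords):
            raise ValidationError(
                f"cell {self.cell_id!r}: non-finite coordinate {coords}"
            )

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Specimen:
    """One imaged lineage: its cells plus metadata.

    ``reference_cell_id`` names the cell used as the spatial origin — the
    neuroblast when present, otherwise a designated ventral reference cell.
    ``stained_tfs`` is the TF panel actually assessed in this specimen; panels
    differ between specimens and that asymmetry is first-class.
    """

    specimen_id: str
    cells: list[CellRecord]
    reference_cell_id: str
    stained_tfs: set[str] = field(default_factory=set)
    genotype: str = "control"
    stage: str = "L3"

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate cell_id {sorted(dupes)[0]} in {self.specimen_id}"
            )
        n_nb = sum(1 for c in self.cells if c.cell_class is CellClass.NB)
        if n_nb > 1:
            raise ValidationError(
                f"specimen {self.specimen_id}: {n_nb} neuroblasts (at most 1 allowed)"
            )
        if self.reference_cell_id not in ids:
            raise ValidationError(
                f"specimen {self.specimen_id}: reference cell "
                f"{self.reference_cell_id!r} not found; designate a ventral "
                f"reference cell when no neuroblast is present"
            )
        for c in self.cells:
            extra = set(c.tf_calls) - self.stained_tfs
            if extra:
                raise ValidationError(
                    f"specimen {self.specimen_id} cell {c.cell_id}: calls for "
                    f"unstained TFs {sorted(extra)}"
                )

    @property
    def reference_cell(self) -> CellRecord:
        return next(c for c in self.cells if c.cell_id == self.reference_cell_id)

    def cells_of_class(self, cls: CellClass) -> list[CellRecord]:
        return [c for c in self.cells if c.cell_class is cls]


@dataclass
class SpecimenSet:
    """A cohort of specimens, e.g. all lineages immunostained for a study."""

    specimens: list[Specimen]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate specimen_ids in SpecimenSet")

    @property
    def tf_panel(self) -> set[str]:
        return set().union(*(s.stained_tfs for s in self.specimens)) if self.specimens else set()

    def n_specimens_per_tf(self) -> dict[str, int]:
        """Number of specimens staining each TF (the cohort size N per TF)."""
        out: dict[str, int] = {}
        for s in self.specimens:
            for tf in s.stained_tfs:
                out[tf] = out.get(tf, 0) + 1
        return out

    def __iter__(self):
        return iter(self.specimens)

    def __len__(self) -> int:
        return len(self.specimens)


@dataclass
class OrderedSequence:
    """One specimen's motoneurons for one TF, ranked by distance from the origin.

    Rank 1 is the cell *furthest* from the neuroblast — the oldest on average.
    ``calls[i]`` and ``distances[i]`` describe the cell at rank ``i + 1``.
    Length equals the number of MN-class cells with a non-missing call.
    """

    specimen_id: str
    tf: str
    calls: list[bool]
    distances: list[float]
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.distances):
            raise ValidationError("calls and distances must be parallel")

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class SmoothingConfig:
    """Savitzky–Golay smoothing parameters (defaults: window 11, order 3)."""

    window: int = 11
    polyorder: int = 3
    edge_mode: str = "polynomial_interp"  # or "mirror"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2 == 0:
            raise ValidationError(f"window must be odd and positive, got {self.window}")
        if not 0 <= self.polyorder < self.window:
            raise ValidationError(
                f"polyorder must satisfy 0 <= polyorder < window, got {self.polyorder}"
            )
        if self.edge_mode not in ("polynomial_interp", "mirror"):
            raise ValidationError(f"unknown edge_mode {self.edge_mode!r}")


@dataclass
class PeakConfig:
    """Peak acceptance thresholds: minimal height, rank separation, prominence."""

    h_min: float = 0.2
    d_min: int = 8
    p_min: float = 0.07

    def __post_init__(self) -> None:
        if not (0 <= self.h_min <= 1 and 0 <= self.p_min <= 1):
            raise ValidationError("h_min and p_min must lie in [0, 1]")
        if self.d_min < 0:
            raise ValidationError("d_min must be non-negative")


@dataclass
class FrequencyProfile:
    """Per-rank expression frequency of one TF across a cohort.

    ``P[i]`` counts positive cells at rank ``i + 1``; ``Nseq[i]`` counts the
    sequences long enough to reach that rank (the at-risk count).  Relative
    mode divides by ``Nseq`` (censoring-aware); global mode divides by the
    total sequence count ``N_total``.
    """

    tf: str
    P: np.ndarray
    Nseq: np.ndarray
    N_total: int
    mode: str = "relative"
    f: np.ndarray = None  # type: ignore[assignment]
    f_smooth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.Nseq = np.asarray(self.Nseq, dtype=float)
        if self.mode not in ("relative", "global"):
            raise ValidationError(f"unknown frequency mode {self.mode!r}")
        if np.any(self.P < 0) or np.any(self.P > self.Nseq) or np.any(
            self.Nseq > self.N_total
        ):
            raise ValidationError("need 0 <= Pi <= Ni <= N_total at every rank")
        if np.any(np.diff(self.Nseq) > 0):
            raise ValidationError("at-risk counts Ni must be non-increasing in rank")
        if self.f is None:
            denom = self.Nseq if self.mode == "relative" else float(self.N_total)
            with np.errstate(invalid="ignore", divide="ignore"):
                self.f = np.where(self.Nseq > 0, self.P / denom, np.nan)

    @property
    def L_max(self) -> int:
        return len(self.P)


@dataclass
class Peak:
    """A detected local maximum of a smoothed frequency profile.

    ``position`` is a 1-based rank.  ``region`` is the closed rank interval
    ``[ip, jp]`` in which this peak prevails once the axis has been
    partitioned between peaks; it is filled by ``partition_regions``.
    """

    position: int
    height: float
    prominence: float
    region: Optional[tuple[int, int]] = None


@dataclass
class ClusterCall:
    """A positive-cell cluster: the contiguous run of ranks expressing a TF.

    ``n`` is the cohort-mean number of positive cells under the peak; it is
    real-valued.  ``core_span`` holds the integer ranks with full coverage
    (None when n < 1).  ``coverage`` maps every covered rank to its coverage
    index in (0, 1]; border ranks may be fractional so that the coverages sum
    to exactly ``n``.  When ``n`` exceeds the capacity of the peak's region
    the cluster saturates: every rank in the region gets coverage 1 and
    ``saturated`` is set.
    """

    tf: str
    peak: Peak
    n: float
    core_span: Optional[tuple[int, int]]
    coverage: dict[int, float]
    saturated: bool = False

    def __post_init__(self) -> None:
        total = sum(self.coverage.values())
        if self.saturated:
            if total > self.n + 1e-9:
                raise ValidationError("saturated cluster cannot exceed n")
        elif abs(total - self.n) > 1e-9:
            raise ValidationError(
                f"coverage sums to {total}, expected n = {self.n}"
            )
        if any(not 0 <= v <= 1 + 1e-12 for v in self.coverage.values()):
            raise ValidationError("coverage indices must lie in [0, 1]")

    @property
    def span(self) -> Optional[tuple[int, int]]:
        """Full extent including fractional border ranks."""
        if not self.coverage:
            return None
        ranks = sorted(self.coverage)
        return ranks[0], ranks[-1]

    @property
    def called_span(self) -> Optional[tuple[int, int]]:
        """Integer extent of the cluster as rendered: majority-covered ranks.

        Border ranks with coverage < 0.5 are dropped; this is the horizontal
        bar drawn for the cluster, while ``coverage`` keeps the fractional
        border detail.
        """
        ranks = sorted(r for r, v in self.coverage.items() if v >= 0.5)
        if not ranks:
            return None
        return ranks[0], ranks[-1]


@dataclass
class TFCodeMap:
    """The combinatorial TF code: per birth-order rank, per TF, a membership.

    Membership is the cluster coverage index in [0, 1] (0 outside clusters).
    Ranks beyond ``max_birth_order`` (supernumerary larval cells destined for
    programmed cell death) are retained in ``annex`` rather than rescaled.
    """

    condition: str
    max_birth_order: int = 29
    entries: dict[str, dict[int, float]] = field(default_factory=dict)
    annex: dict[str, dict[int, float]] = field(default_factory=dict)
    calls: list[ClusterCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        for tf, col in list(self.entries.items()) + list(self.annex.items()):
            for rank, v in col.items():
                if not 0 <= v <= 1 + 1e-12:
                    raise ValidationError(
                        f"membership {v} for {tf} rank {rank} outside [0, 1]"
                    )

    @property
    def tfs(self) -> list[str]:
        return sorted(set(self.entries) | set(self.annex))

    def membership(self, tf: str, rank: int) -> float:
        if rank <= self.max_birth_order:
            return self.entries.get(tf, {}).get(rank, 0.0)
        return self.annex.get(tf, {}).get(rank, 0.0)

    def code_at(self, rank: int, threshold: float = 0.0) -> set[str]:
        """TFs with membership above ``threshold`` at a given rank."""
        return {tf for tf in self.tfs if self.membership(tf, rank) > threshold}


# ---------------------------------------------------------------------------
# table parsing


def _parse_call(value) -> Optional[bool]:
    """Interpret a table cell as on/off/missing. Empty or NaN means missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "none"):
        return None
    if s in ("1", "1.0", "True", "true"):
        return True
    if s in ("0", "0.0", "False", "false"):
        return False
    raise ValidationError(f"cannot interpret TF call {value!r} (expected 0/1/empty)")


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    fixed = ["specimen_id", "cell_id", "class", "x_um", "y_um", "z_um"]
    tf_cols = [c for c in df.columns if c not in fixed]
    long = df.melt(id_vars=fixed, value_vars=tf_cols, var_name="tf", value_name="call")
    return long


def load_specimens(
    path: str | Path,
    metadata: Optional[str | Path | Mapping] = None,
    schema: str = "auto",
) -> SpecimenSet:
    """Read a cell table (long or wide dialect) into a validated SpecimenSet.

    Parameters
    ----------
    path
        TSV/CSV cell table.  Long format has columns
        ``specimen_id, cell_id, class, x_um, y_um, z_um, tf, call``; wide
        format replaces the last two with one column per TF.
    metadata
        Optional per-specimen metadata: a JSON file or mapping
        ``{specimen_id: {"genotype": ..., "stage": ..., "reference_cell_id": ...}}``.
        When absent, the neuroblast is used as reference.
    schema
        ``"long"``, ``"wide"`` or ``"auto"`` (sniff from the header).

    An empty ``call`` cell means the TF was not assessed for that cell; a TF
    with no non-missing calls in a specimen is recorded as not stained there.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)

    required_fixed = ["specimen_id", "cell_id", "class", "x_um", "y_um", "z_um"]
    missing = [c for c in required_fixed if c not in df.columns]
    if missing:
        raise ValidationError(f"cell table missing required columns {missing}")
    if schema == "auto":
        schema = "long" if {"tf", "call"} <= set(df.columns) else "wide"
    if schema == "wide":
        df = _wide_to_long(df)
    elif not {"tf", "call"} <= set(df.columns):
        raise ValidationError("long-format table requires 'tf' and 'call' columns")

    meta: dict = {}
    if metadata is not None:
        if isinstance(metadata, (str, Path)):
            meta = json.loads(Path(metadata).read_text())
        else:
            meta = dict(metadata)

    specimens: list[Specimen] = []
    for sid, g in df.groupby("specimen_id", sort=True):
        cells: dict[str, CellRecord] = {}
        stained: set[str] = set()
        for _, row in g.iterrows():
            cid = row["cell_id"]
            if cid not in cells:
                try:
                    x, y, z = (float(row[c]) for c in ("x_um", "y_um", "z_um"))
                except ValueError:
                    raise ValidationError(
                        f"non-numeric coordinate in specimen {sid}, cell {cid} "
                        f"(table row {row.name + 2})"
                    ) from None
                cells[cid] = CellRecord(
                    cell_id=cid, cell_class=CellClass.parse(row["class"]), x=x, y=y, z=z
                )
            cell = cells[cid]
            call = _parse_call(row["call"])
            if call is not None:
                tf = row["tf"]
                if tf in cell.tf_calls:
                    raise ValidationError(
                        f"duplicate cell_id {cid} in {sid} (repeated call for {tf})"
                    )
                cell.tf_calls[tf] = call
                stained.add(tf)
        m = meta.get(sid, {})
        ref = m.get("reference_cell_id")
        if ref is None:
            nbs = [c for c in cells.values() if c.cell_class is CellClass.NB]
            if not nbs:
                raise ValidationError(
                    f"specimen {sid}: no neuroblast and no reference_cell_id in "
                    f"metadata; designate a ventral reference cell"
                )
            ref = nbs[0].cell_id
        specimens.append(
            Specimen(
                specimen_id=str(sid),
                cells=list(cells.values()),
                reference_cell_id=ref,
                stained_tfs=stained | set(m.get("stained_tfs", [])),
                genotype=m.get("genotype", "control"),
                stage=m.get("stage", "L3"),
            )
        )
    return SpecimenSet(specimens=specimens, provenance={"source": str(path)})


def write_specimens(sset: SpecimenSet, path: str | Path, metadata_path: Optional[str | Path] = None) -> None:
    """Write a SpecimenSet as the canonical long-format TSV (+ metadata JSON).

    Calls serialize as 0/1; a stained-but-unassessed cell gets an empty cell,
    and TFs never stained in a specimen are simply absent from its rows unless
    recorded in the metadata JSON.
    """
    rows = []
    meta = {}
    for s in sset.specimens:
        meta[s.specimen_id] = {
            "genotype": s.genotype,
            "stage": s.stage,
            "reference_cell_id": s.reference_cell_id,
            "stained_tfs": sorted(s.stained_tfs),
        }
        for c in s.cells:
            tfs = sorted(s.stained_tfs) or [None]
            for tf in tfs:
                call = c.tf_calls.get(tf) if tf is not None else None
                rows.append(
                    {
                        "specimen_id": s.specimen_id,
                        "cell_id": c.cell_id,
                        "class": c.cell_class.value,
                        "x_um": repr(c.x),
                        "y_um": repr(c.y),
                        "z_um": repr(c.z),
                        "tf": tf if tf is not None else "",
                        "call": "" if call is None else int(call),
                    }
                )
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    if metadata_path is not None:
        Path(metadata_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# code-map serialization


def _codemap_report(codemap: TFCodeMap) -> dict:
    return {
        "condition": codemap.condition,
        "max_birth_order": codemap.max_birth_order,
        "clusters": [
            {
                "tf": c.tf,
                "peak_position": c.peak.position,
                "peak_height": c.peak.height,
                "peak_prominence": c.peak.prominence,
                "region": list(c.peak.region) if c.peak.region else None,
                "n": c.n,
                "core_span": list(c.core_span) if c.core_span else None,
                "called_span": list(c.called_span) if c.called_span else None,
                "coverage": {str(k): v for k, v in sorted(c.coverage.items())},
            }
            for c in codemap.calls
        ],
    }


def write_codemap(codemap: TFCodeMap, path: str | Path) -> None:
    """Emit a rank × TF membership matrix (TSV) and a structured JSON report.

    ``path`` is the TSV path; the JSON report goes next to it with suffix
    ``.json``.  The matrix covers ranks 1..max_birth_order; annex ranks
    (supernumerary cells) appear as extra rows flagged in a ``supernumerary``
    column.
    """
    path = Path(path)
    tfs = codemap.tfs
    annex_ranks = sorted({r for col in codemap.annex.values() for r in col})
    rows = []
    for rank in list(range(1, codemap.max_birth_order + 1)) + annex_ranks:
        row: dict = {"rank": rank, "supernumerary": int(rank > codemap.max_birth_order)}
        for tf in tfs:
            row[tf] = codemap.membership(tf, rank)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["rank", "supernumerary"] + tfs)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    path.with_suffix(".json").write_text(
        json.dumps(_codemap_report(codemap), indent=2, sort_keys=True)
    )


def read_codemap_report(json_path: str | Path) -> dict:
    """Read back the structured JSON report written by :func:`write_codemap`."""
    return json.loads(Path(json_path).read_text())
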