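"""Synthetic stem-cell lineages with known ground truth.

The generator emulates the statistical structure the cluster-detection
pipeline assumes, so every stage can be tested without imaging data:

* one neuroblast (NB) at the origin and ``n_mn`` motoneurons whose distance
  from the NB increases with age — the k-th born of ``n_mn`` cells sits at
  radius ``d0 + step * (n_mn - k)`` plus Gaussian positional noise, in a
  random direction within a hemisphere;
* per-specimen motoneuron counts drawn around stage presets (larval ~39,
  24 h-after-pupa-formation ~32, adult 29);
* transcription-factor expression planted in one or two contiguous
  birth-order intervals, with per-cell dropout inside (``p_in < 1``) and
  ectopic calls outside (``p_out > 0``), and per-specimen integer jitter of
  the interval boundaries;
* optional right-truncation of the observed sequence (the NB-proximal cells
  dropped), giving cohorts of unequal length;
* genotype presets reproducing the qualitative contrasts between a control
  lineage, Imp overexpression, and Syp knockdown: the perturbations extend
  the mid-lineage Jim cluster into the last-born (NB-proximal) ranks, delete
  the NB-proximal RunxA cluster, and attenuate the NB-proximal Nvy cluster.

Randomness derives from ``(seed, specimen index)`` so cohorts are
reproducible and independent of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CellClass,
    CellRecord,
    Specimen,
    SpecimenSet,
    ValidationError,
)

__all__ = [
    "TFSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate_specimen",
    "generate_cohort",
    "census",
    "STAGE_PRESETS",
    "genotype_preset",
]

#: per-stage motoneuron census (mean count, SD) the generator emulates
STAGE_PRESETS: dict[str, tuple[int, float]] = {
    "larval": (39, 2.0),
    "24h_apf": (32, 1.0),
    "adult": (29, 1.0),
}


@dataclass
class TFSpec:
    """Planted expression pattern of one TF: intervals on the birth-rank axis.

    ``intervals`` are closed 1-based rank intervals on the *ordering* axis
    (rank 1 = furthest from the NB = first-born).  Each carries its own
    positive-call probability inside (``p_in``); ``p_out`` is the ectopic
    rate outside all intervals, and ``boundary_jitter`` shifts every interval
    endpoint independently by an integer uniform on [-j, +j] per specimen.
    """

    intervals: list[tuple[int, int]]
    p_in: float | list[float] = 0.9
    p_out: float = 0.02
    boundary_jitter: int = 1

    def p_in_list(self) -> list[float]:
        if isinstance(self.p_in, (int, float)):
            return [float(self.p_in)] * len(self.intervals)
        if len(self.p_in) != len(self.intervals):
            raise ValidationError("p_in list must match intervals")
        return [float(p) for p in self.p_in]

    def validate(self, n_mn: int) -> None:
        for (lo, hi), p in zip(self.intervals, self.p_in_list()):
            if not (1 <= lo <= hi):
                raise ValidationError(f"invalid planted interval ({lo}, {hi})")
            if not 0 <= self.p_out <= p <= 1:
                raise ValidationError("need 0 <= p_out <= p_in <= 1")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-lineage generator.

    Distances are in µm.  ``step`` > 0 makes later-born cells sit closer to
    the NB, the geometry the ordering step relies on; ``pos_noise_sd``
    blurs it so neighbouring ranks occasionally swap, as in real imaging.
    ``truncation`` (lo, hi) draws the observed sequence length uniformly and
    drops the NB-proximal remainder; None observes every cell.
    """

    n_mn: int = 39
    count_sd: float = 2.0
    d0: float = 10.0
    step: float = 2.5
    pos_noise_sd: float = 0.75
    tf_specs: dict[str, TFSpec] = field(default_factory=dict)
    truncation: Optional[tuple[int, int]] = None
    genotype: str = "control"
    stage: str = "larval"
    seed: int = 0

    def validate(self) -> None:
        if self.n_mn < 1 or self.count_sd < 0 or self.step <= 0:
            raise ValidationError("need n_mn >= 1, count_sd >= 0, step > 0")
        for tf, spec in self.tf_specs.items():
            spec.validate(self.n_mn)


@dataclass
class GroundTruth:
    """What was planted: true birth index per cell, jittered intervals per TF."""

    specimen_id: str
    birth_index: dict[str, int]  # cell_id -> birth index (1 = first-born)
    intervals: dict[str, list[tuple[int, int]]]  # TF -> jittered rank intervals
    observed_length: int = 0


def genotype_preset(name: str, **overrides) -> GeneratorConfig:
    """Generator configurations for the three study conditions.

    The control lineage expresses Jim in a single mid-lineage cluster and
    RunxA and Nvy each in two clusters, one early (NB-distal) and one in the
    last-born (NB-proximal) cells.  Imp overexpression and Syp knockdown
    share one qualitative signature: Jim extends into the last-born ranks,
    the NB-proximal RunxA cluster disappears, and the NB-proximal Nvy
    cluster is attenuated.  Interval ranks are illustrative defaults chosen
    to be consistent with a mid-lineage code around ranks 16–24 and a
    last-born code just before the lineage's supernumerary tail.
    """
    common = dict(p_out=0.02, boundary_jitter=1)
    if name == "control":
        specs = {
            "Jim": TFSpec(intervals=[(16, 23)], p_in=0.9, **common),
            "RunxA": TFSpec(intervals=[(5, 12), (28, 36)], p_in=0.9, **common),
            "Nvy": TFSpec(intervals=[(5, 12), (29, 36)], p_in=0.9, **common),
        }
    elif name in ("imp_oe", "syp_rnai"):
        jim_hi = 30 if name == "imp_oe" else 29
        specs = {
            "Jim": TFSpec(intervals=[(16, jim_hi)], p_in=0.9, **common),
            "RunxA": TFSpec(intervals=[(5, 12)], p_in=0.9, **common),
            "Nvy": TFSpec(intervals=[(5, 12), (29, 36)], p_in=[0.9, 0.4], **common),
        }
    else:
        raise ValidationError(
            f"unknown genotype preset {name!r} (use control, imp_oe or syp_rnai)"
        )
    cfg = GeneratorConfig(genotype=name, tf_specs=specs)
    return dataclasses.replace(cfg, **overrides)


def _rng_for(cfg: GeneratorConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))


def generate_specimen(cfg: GeneratorConfig, index: int) -> tuple[Specimen, GroundTruth]:
    """Generate one specimen; deterministic given (cfg.seed, index)."""
    cfg.validate()
    rng = _rng_for(cfg, index)
    sid = f"syn{index:04d}"

    n_mn = max(1, int(round(rng.normal(cfg.n_mn, cfg.count_sd)))) if cfg.count_sd > 0 else cfg.n_mn

    # jittered planted intervals and per-rank positive probability, on the
    # ordering axis (rank 1 = first-born = furthest)
    intervals: dict[str, list[tuple[int, int]]] = {}
    q: dict[str, np.ndarray] = {}
    for tf, spec in cfg.tf_specs.items():
        qs = np.full(n_mn, spec.p_out)
        jittered = []
        for (lo, hi), p in zip(spec.intervals, spec.p_in_list()):
            j = spec.boundary_jitter
            if j > 0:
                lo = lo + int(rng.integers(-j, j + 1))
                hi = hi + int(rng.integers(-j, j + 1))
            lo, hi = max(1, lo), min(n_mn, max(hi, lo))
            jittered.append((lo, hi))
            qs[lo - 1 : hi] = p
        intervals[tf] = jittered
        q[tf] = qs

    cells = [CellRecord(cell_id="NB", cell_class=CellClass.NB, x=0.0, y=0.0, z=0.0)]
    birth_index: dict[str, int] = {}
    for k in range(1, n_mn + 1):  # birth index k; first-born lies furthest out
        radius = cfg.d0 + cfg.step * (n_mn - k)
        if cfg.pos_noise_sd > 0:
            radius = max(0.0, radius + rng.normal(0.0, cfg.pos_noise_sd))
        u = rng.normal(size=3)
        u[2] = abs(u[2])  # hemisphere away from the NB's apical side
        u /= np.linalg.norm(u)
        calls = {tf: bool(rng.random() < q[tf][k - 1]) for tf in cfg.tf_specs}
        cid = f"mn{k:03d}"
        birth_index[cid] = k
        cells.append(
            CellRecord(
                cell_id=cid,
                cell_class=CellClass.MN,
                x=radius * u[0],
                y=radius * u[1],
                z=radius * u[2],
                tf_calls=calls,
            )
        )

    observed = n_mn
    if cfg.truncation is not None:
        lo, hi = cfg.truncation
        observed = int(rng.integers(lo, hi + 1))
        observed = min(observed, n_mn)
        # drop the NB-proximal (latest-born) remainder: ranks observed+1..n_mn
        drop = {f"mn{k:03d}" for k in range(observed + 1, n_mn + 1)}
        cells = [c for c in cells if c.cell_id not in drop]
        birth_index = {cid: k for cid, k in birth_index.items() if cid not in drop}

    specimen = Specimen(
        specimen_id=sid,
        cells=cells,
        reference_cell_id="NB",
        stained_tfs=set(cfg.tf_specs),
        genotype=cfg.genotype,
        stage=cfg.stage,
    )
    truth = GroundTruth(
        specimen_id=sid,
        birth_index=birth_index,
        intervals=intervals,
        observed_length=observed,
    )
    return specimen, truth


def generate_cohort(
    cfg: GeneratorConfig, n_specimens: int
) -> tuple[SpecimenSet, list[GroundTruth]]:
    """Generate an independent cohort of specimens."""
    if n_specimens < 1:
        raise ValidationError("n_specimens must be >= 1")
    pairs = [generate_specimen(cfg, i) for i in range(n_specimens)]
    sset = SpecimenSet(
        specimens=[p[0] for p in pairs],
        provenance={
            "generator": "pccd.synthetic",
            "seed": cfg.seed,
            "genotype": cfg.genotype,
            "stage": cfg.stage,
            "n_mn": cfg.n_mn,
            "count_sd": cfg.count_sd,
        },
    )
    return sset, [p[1] for p in pairs]


def census(sset: SpecimenSet) -> pd.DataFrame:
    """Per-specimen cell counts by class, with cohort mean and SD rows.

    Mirrors the census figures reported for imaged lineages (e.g. motoneuron
    counts per stage, mean ± SD).
    """
    classes = [c.value for c in CellClass]
    rows = []
    for s in sset:
        row = {"specimen_id": s.specimen_id}
        for cls in CellClass:
            row[cls.value] = sum(1 for c in s.cells if c.cell_class is cls)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["specimen_id"] + classes)
    if len(df):
        stats = pd.DataFrame(
            [
                {"specimen_id": "mean", **df[classes].mean().to_dict()},
                {"specimen_id": "sd", **df[classes].std(ddof=1).fillna(0.0).to_dict()},
            ]
        )
        df = pd.concat([df, stats], ignore_index=True)
    return df
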