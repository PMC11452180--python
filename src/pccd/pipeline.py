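"""End-to-end orchestration: cell table in, code map and reports out.

`run_pccd` chains the whole method for every TF in a cohort — normalize to
the reference cell, order by distance, build the censoring-aware frequency
histogram, smooth, detect peaks, partition the rank axis, and place one
positive-cell cluster per peak — then assembles the combinatorial TF code
map.  All numbers land in TSV/JSON; a YAML run log echoes every parameter
actually used so a run is reproducible from (input table, config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .clusters import assemble_code_map, compare_code_maps, mean_positive_count, place_cluster
from .datamodel import (
    PeakConfig,
    SmoothingConfig,
    SpecimenSet,
    TFCodeMap,
    ValidationError,
    load_specimens,
    read_codemap_report,
    write_codemap,
)
from .frequency import frequency_profile, profile_to_frame, smooth_profile
from .ordering import cohort_sequences, sequences_to_frame
from .peaks import find_peaks, partition_regions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pccd", "run_pccd_on_set", "compare_runs"]

#: cohort sizes below this are flagged; the method is designed for N > 15
MIN_RECOMMENDED_N = 15


@dataclasses.dataclass
class PipelineConfig:
    """Bundled tunables for one run."""

    smoothing: SmoothingConfig = dataclasses.field(default_factory=SmoothingConfig)
    peaks: PeakConfig = dataclasses.field(default_factory=PeakConfig)
    mode: str = "relative"
    max_birth_order: int = 29
    tfs: Optional[list[str]] = None  # None = every TF stained in the cohort
    include_apoptotic: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sm = raw.get("smoothing", {})
        pk = raw.get("peaks", {})
        cl = raw.get("clusters", {})
        return cls(
            smoothing=SmoothingConfig(
                window=int(sm.get("window", 11)),
                polyorder=int(sm.get("polyorder", 3)),
                edge_mode=sm.get("edge_mode", "polynomial_interp"),
            ),
            peaks=PeakConfig(
                h_min=float(pk.get("h_min", 0.2)),
                d_min=int(pk.get("d_min", 8)),
                p_min=float(pk.get("p_min", 0.07)),
            ),
            mode=cl.get("mode", raw.get("mode", "relative")),
            max_birth_order=int(cl.get("max_birth_order", 29)),
            tfs=raw.get("tfs"),
            include_apoptotic=bool(raw.get("include_apoptotic", False)),
        )

    def to_dict(self) -> dict:
        return {
            "smoothing": dataclasses.asdict(self.smoothing),
            "peaks": dataclasses.asdict(self.peaks),
            "clusters": {"mode": self.mode, "max_birth_order": self.max_birth_order},
            "tfs": self.tfs,
            "include_apoptotic": self.include_apoptotic,
        }


def run_pccd_on_set(
    sset: SpecimenSet,
    cfg: PipelineConfig | None = None,
    out_dir: Optional[str | Path] = None,
    condition: Optional[str] = None,
    plots: bool = False,
) -> TFCodeMap:
    """Run the full pipeline on an in-memory cohort.

    Writes, when ``out_dir`` is given: per-TF frequency tables
    (``freq_<TF>.tsv``), ordered sequences (``sequences.tsv``), the cluster
    report (``clusters.json``), the code-map matrix (``codemap.tsv`` +
    ``codemap.json``) and the run log (``run_log.yaml``).
    """
    cfg = cfg or PipelineConfig()
    tfs = cfg.tfs if cfg.tfs is not None else sorted(sset.tf_panel)
    missing = [tf for tf in tfs if tf not in sset.tf_panel]
    if missing:
        raise ValidationError(
            f"requested TF(s) not stained anywhere in the cohort: {missing}"
        )
    if condition is None:
        genotypes = {s.genotype for s in sset}
        condition = genotypes.pop() if len(genotypes) == 1 else "mixed"

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    n_per_tf = sset.n_specimens_per_tf()
    all_calls = []
    tf_summaries = []
    all_seq_frames = []
    for tf in tfs:
        n_spec = n_per_tf.get(tf, 0)
        if n_spec < MIN_RECOMMENDED_N:
            logger.warning(
                "TF %s stained in only %d specimens; the method is designed "
                "for cohorts of more than %d — results may be unstable",
                tf,
                n_spec,
                MIN_RECOMMENDED_N,
            )
        seqs = cohort_sequences(sset, tf, include_apoptotic=cfg.include_apoptotic)
        prof = smooth_profile(frequency_profile(seqs, tf, mode=cfg.mode), cfg.smoothing)
        found = find_peaks(prof.f_smooth, cfg.peaks)
        regions = partition_regions(found, prof.f_smooth)
        calls = []
        for pk in regions:
            n = mean_positive_count(seqs, pk.region)
            calls.append(place_cluster(prof.f_smooth, pk, n, tf=tf))
        all_calls.extend(calls)
        logger.info(
            "TF %s: N=%d, L_max=%d, %d peak(s), n per region: %s",
            tf,
            n_spec,
            prof.L_max,
            len(calls),
            [round(c.n, 3) for c in calls],
        )
        tf_summaries.append(
            {
                "tf": tf,
                "n_specimens": n_spec,
                "L_max": prof.L_max,
                "n_peaks": len(calls),
                "peaks": [
                    {
                        "position": c.peak.position,
                        "height": c.peak.height,
                        "prominence": c.peak.prominence,
                        "region": list(c.peak.region),
                        "n": c.n,
                        "core_span": list(c.core_span) if c.core_span else None,
                        "span": list(c.span) if c.span else None,
                        "called_span": list(c.called_span) if c.called_span else None,
                        "coverage": {str(k): v for k, v in sorted(c.coverage.items())},
                        "saturated": c.saturated,
                    }
                    for c in calls
                ],
                "note": "no positive cell cluster detected" if not calls else "",
            }
        )
        if out is not None:
            profile_to_frame(prof).to_csv(out / f"freq_{tf}.tsv", sep="\t", index=False)
            all_seq_frames.append(sequences_to_frame(seqs))
            if plots:
                from .plotting import plot_tf_profile

                ax = plot_tf_profile(prof, calls)
                ax.figure.savefig(out / f"profile_{tf}.png", dpi=150, bbox_inches="tight")
                import matplotlib.pyplot as plt

                plt.close(ax.figure)

    codemap = assemble_code_map(
        all_calls, max_birth_order=cfg.max_birth_order, condition=condition
    )
    if out is not None:
        if all_seq_frames:
            pd.concat(all_seq_frames, ignore_index=True).to_csv(
                out / "sequences.tsv", sep="\t", index=False
            )
        (out / "clusters.json").write_text(
            json.dumps({"condition": condition, "tfs": tf_summaries}, indent=2)
        )
        write_codemap(codemap, out / "codemap.tsv")
        run_log = {
            "pccd_version": __version__,
            "condition": condition,
            "n_specimens": len(sset),
            "n_specimens_per_tf": n_per_tf,
            "parameters": cfg.to_dict(),
            "provenance": {k: str(v) for k, v in sset.provenance.items()},
        }
        (out / "run_log.yaml").write_text(yaml.safe_dump(run_log, sort_keys=True))
    return codemap


def run_pccd(
    cell_table: str | Path,
    config: Optional[str | Path] = None,
    out_dir: Optional[str | Path] = None,
    metadata: Optional[str | Path] = None,
    plots: bool = False,
) -> TFCodeMap:
    """File-level entry point: load a cell table, run the pipeline, write reports."""
    cfg = PipelineConfig.from_yaml(config) if config else PipelineConfig()
    sset = load_specimens(cell_table, metadata=metadata)
    return run_pccd_on_set(sset, cfg, out_dir=out_dir, plots=plots)


def _load_run(run_dir: str | Path) -> tuple[dict, dict]:
    run_dir = Path(run_dir)
    report = read_codemap_report(run_dir / "codemap.json")
    log = yaml.safe_load((run_dir / "run_log.yaml").read_text())
    return report, log


def compare_runs(run_a: str | Path, run_b: str | Path) -> dict:
    """Shift report between two completed run directories.

    Rebuilds the code maps from the JSON reports and delegates to
    :func:`pccd.clusters.compare_code_maps`.  Runs with differing parameters
    are still compared, with a warning recorded in the report.
    """
    from .datamodel import ClusterCall, Peak  # local to avoid clutter above

    def rebuild(report: dict) -> TFCodeMap:
        calls = []
        for c in report["clusters"]:
            peak = Peak(
                position=c["peak_position"],
                height=c["peak_height"],
                prominence=c["peak_prominence"],
                region=tuple(c["region"]) if c["region"] else None,
            )
            cov = {int(k): v for k, v in c["coverage"].items()}
            calls.append(
                ClusterCall(
                    tf=c["tf"],
                    peak=peak,
                    n=c["n"],
                    core_span=tuple(c["core_span"]) if c["core_span"] else None,
                    coverage=cov,
                    saturated=abs(sum(cov.values()) - c["n"]) > 1e-9,
                )
            )
        return assemble_code_map(
            calls,
            max_birth_order=report["max_birth_order"],
            condition=report["condition"],
        )

    rep_a, log_a = _load_run(run_a)
    rep_b, log_b = _load_run(run_b)
    result = compare_code_maps(rebuild(rep_a), rebuild(rep_b))
    if log_a.get("parameters") != log_b.get("parameters"):
        logger.warning("runs used different parameters; comparison still emitted")
        result["parameter_mismatch"] = True
    else:
        result["parameter_mismatch"] = False
    return result
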